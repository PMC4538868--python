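"""Seeded synthetic GC-MS peak tables with known ground truth.

The generator reproduces the structure of a two-carbon-source bacterial
metal-toxicity metabolomics study: cultures grown on biphenyl or succinate,
exposed to nothing (control), Al or Cu, sampled as cell pellets and spent
media with five biological replicates each, plus extraction/derivatization
blanks. 269 analytes are quantified through 1-5 quantifier ions apiece;
89 metabolites are "identified" (library-matched, pathway-mappable).

The measurement model, all on the natural-log scale:

* each metabolite has a latent base abundance ``N(base_log_mean, base_log_sd)``,
  fixed per-carbon-source and per-sample-type offsets (these create the
  dominant carbon-source / sample-type separation real profiles show),
  per-replicate biological noise ``N(0, sigma_bio)``, and — for metabolites
  affected in a given condition — a shift of ``effect_size * sigma_bio``
  with a known sign;
* each quantifier ion reads its analyte's latent abundance through a fixed
  response factor with multiplicative log-normal measurement noise
  ``N(0, sigma_meas)`` — this proportional structure is what the r >= 0.8
  ion-correlation filter assumes;
* *corrupted* ions (simulating co-eluting contaminants) ignore the latent
  profile and fluctuate independently with ``sigma_corrupt``;
* whole samples are multiplied by a dilution factor drawn log-uniformly
  from [0.5, 2] — the signal probabilistic quotient normalization must
  recover;
* blanks carry only a tiny baseline plus the *artifact analytes*, which
  appear at sample-like levels in every sample and every blank.

Common contaminant fragments (m/z 73, 147, 121, 266, 285, 299) are never
assigned as quantifier ions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ions import AlkaneLadder, IonPeakTable, CONTAMINANT_MZ
from .sus_enrichment import PathwayAnnotation

__all__ = [
    "StudyDesign",
    "TruthConfig",
    "GroundTruth",
    "generate_design",
    "generate_peak_table",
    "generate_pathway_annotation",
    "generate_alkane_ladder",
]

CONTROL = "control"


@dataclass(frozen=True)
class StudyDesign:
    carbon_sources: tuple[str, ...] = ("biphenyl", "succinate")
    treatments: tuple[str, ...] = (CONTROL, "Al", "Cu")
    sample_types: tuple[str, ...] = ("cells", "media")
    n_replicates: int = 5
    n_blanks: int = 5
    n_analytes: int = 269
    n_identified: int = 89
    n_derivative_pairs: int = 20
    n_artifacts: int = 8

    def __post_init__(self) -> None:
        for name in ("n_replicates", "n_analytes", "n_identified"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_blanks < 0 or self.n_artifacts < 0 or self.n_derivative_pairs < 0:
            raise ValueError("counts must be non-negative")
        if not (self.carbon_sources and self.treatments and self.sample_types):
            raise ValueError("label sets must be non-empty")
        if self.n_identified > self.n_metabolites:
            raise ValueError("n_identified exceeds the number of metabolites")
        if self.n_derivative_pairs > self.n_identified:
            raise ValueError("derivative pairs only occur among identified metabolites")

    @property
    def n_metabolites(self) -> int:
        # derivative pairs merge two analytes into one metabolite
        return self.n_analytes - self.n_derivative_pairs

    @property
    def n_study_samples(self) -> int:
        return (
            len(self.carbon_sources)
            * len(self.treatments)
            * len(self.sample_types)
            * self.n_replicates
        )

    def sample_table(self) -> pd.DataFrame:
        """Enumerate every sample with a unique id and full metadata."""
        rows = []
        for carbon in self.carbon_sources:
            for treatment in self.treatments:
                for stype in self.sample_types:
                    for rep in range(1, self.n_replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"{carbon}_{treatment}_{stype}_r{rep}",
                                "carbon_source": carbon,
                                "treatment": treatment,
                                "sample_type": stype,
                                "replicate": rep,
                                "is_blank": False,
                            }
                        )
        for b in range(1, self.n_blanks + 1):
            rows.append(
                {
                    "sample_id": f"blank_r{b}",
                    "carbon_source": "none",
                    "treatment": "none",
                    "sample_type": "blank",
                    "replicate": b,
                    "is_blank": True,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def condition_pairs(self) -> list[tuple[str, str, str]]:
        """(carbon source, metal, sample type) triples, control excluded."""
        return [
            (c, t, s)
            for c in self.carbon_sources
            for t in self.treatments
            if t != CONTROL
            for s in self.sample_types
        ]


def generate_design(**overrides) -> StudyDesign:
    """Build a :class:`StudyDesign`; defaults mirror the full study layout."""
    return StudyDesign(**overrides)


@dataclass(frozen=True)
class TruthConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    effect_size: float = 2.0  # in units of sigma_bio, log scale
    n_affected: int = 20  # metabolites shifted per condition pair
    frac_identified_affected: float = 0.75
    n_corrupted_ions: int = 40
    sigma_bio: float = 0.4  # replicate-to-replicate log-SD
    sigma_meas: float = 0.15  # per-ion multiplicative noise, log-SD
    sigma_carbon: float = 1.0  # carbon-source fingerprint, log-SD
    sigma_type: float = 0.7  # cells vs media fingerprint, log-SD
    sigma_analyte: float = 0.3  # derivative-yield offset, log-SD
    sigma_corrupt: float = 0.6  # corrupted-ion independent variation, log-SD
    corrupt_rf_scale: float = 0.2  # corrupted ions respond weakly
    base_log_mean: float = 11.5
    base_log_sd: float = 1.5
    rf_range: tuple[float, float] = (0.2, 1.0)
    max_ions: int = 5
    dilution_range: tuple[float, float] = (0.5, 2.0)
    blank_log_mean: float = math.log(50.0)
    blank_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.frac_identified_affected <= 1.0:
            raise ValueError("frac_identified_affected must be in [0, 1]")
        if self.dilution_range[0] <= 0:
            raise ValueError("dilution factors must be positive")


@dataclass
class GroundTruth:
    """What the pipeline is supposed to recover from a synthetic table."""

    #: (carbon, metal, sample_type) -> list of (metabolite, direction, effect size in SD)
    affected: dict[tuple[str, str, str], list[tuple[str, str, float]]]
    corrupted_ions: set[str]
    artifact_analytes: set[str]
    dilution: dict[str, float]
    config: TruthConfig
    enriched_pathway: str | None = None

    def affected_ids(self, pair: tuple[str, str, str]) -> set[str]:
        return {m for m, _, _ in self.affected[pair]}


def generate_peak_table(
    design: StudyDesign,
    config: TruthConfig | None = None,
    seed: int | None = None,
) -> tuple[IonPeakTable, GroundTruth]:
    """Simulate an ion-level peak table plus the ground truth behind it.

    A single pseudo-random stream drives the whole call; the seed is part
    of the public interface and equal seeds give identical tables.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)

    n_mets = design.n_metabolites
    mets = [f"m{i + 1:04d}" for i in range(n_mets)]
    identified = set(mets[: design.n_identified])

    # analytes: the first n_derivative_pairs identified metabolites occur as
    # two TMS-derivative forms, everything else as a single analyte
    analyte_rows = []
    for i, met in enumerate(mets):
        if i < design.n_derivative_pairs:
            analyte_rows.append((f"{met}_2TMS", met, met in identified))
            analyte_rows.append((f"{met}_3TMS", met, met in identified))
        else:
            analyte_rows.append((f"{met}_TMS", met, met in identified))
    for a in range(1, design.n_artifacts + 1):
        analyte_rows.append((f"artifact{a:02d}", f"artifact{a:02d}", False))
    analyte_meta = pd.DataFrame(
        analyte_rows, columns=["analyte", "metabolite", "identified"]
    ).set_index("analyte")
    analyte_meta["rt"] = rng.uniform(4.5, 26.5, len(analyte_meta))
    artifact_analytes = {a for a in analyte_meta.index if a.startswith("artifact")}

    # quantifier ions: 1..max_ions per analyte, m/z unique within an analyte
    # and never one of the excluded contaminant fragments
    allowed_mz = np.array(sorted(set(range(70, 620)) - set(CONTAMINANT_MZ)))
    ion_rows = []
    for analyte in analyte_meta.index:
        k = int(rng.integers(1, cfg.max_ions + 1))
        mzs = rng.choice(allowed_mz, size=k, replace=False)
        for mz in sorted(int(m) for m in mzs):
            ion_rows.append((f"{analyte}:mz{mz}", analyte, mz))
    ion_meta = pd.DataFrame(ion_rows, columns=["ion_id", "analyte", "mz"]).set_index(
        "ion_id"
    )
    ion_meta["rt"] = analyte_meta.loc[ion_meta["analyte"], "rt"].to_numpy()

    # fixed per-ion response factors (the proportional structure the r >= 0.8
    # filter assumes)
    rf = np.exp(
        rng.uniform(math.log(cfg.rf_range[0]), math.log(cfg.rf_range[1]), len(ion_meta))
    )
    rf_by_ion = pd.Series(rf, index=ion_meta.index)

    # corrupted ions: one per chosen multi-ion (non-artifact) analyte — the
    # weakest-responding fragment, the one a co-eluting contaminant of
    # comparable intensity can masquerade through
    ion_counts = ion_meta.groupby("analyte").size()
    eligible = [
        a
        for a in analyte_meta.index
        if ion_counts[a] >= 2 and a not in artifact_analytes
    ]
    n_corr = min(cfg.n_corrupted_ions, len(eligible))
    corrupted: set[str] = set()
    for analyte in rng.choice(eligible, size=n_corr, replace=False):
        ions = ion_meta.index[ion_meta["analyte"] == analyte]
        corrupted.add(rf_by_ion[ions].idxmin())

    sample_meta = design.sample_table()
    samples = sample_meta.index
    n_samples = len(samples)
    is_blank = sample_meta["is_blank"].to_numpy(dtype=bool)

    # condition effects
    id_pool = sorted(identified)
    unk_pool = sorted(set(mets) - identified)
    affected: dict[tuple[str, str, str], list[tuple[str, str, float]]] = {}
    for pair in design.condition_pairs():
        n_id = min(round(cfg.frac_identified_affected * cfg.n_affected), len(id_pool))
        n_unk = min(cfg.n_affected - n_id, len(unk_pool))
        chosen = list(rng.choice(id_pool, n_id, replace=False)) + list(
            rng.choice(unk_pool, n_unk, replace=False)
        )
        affected[pair] = [
            (m, "up" if rng.random() < 0.5 else "down", cfg.effect_size) for m in chosen
        ]

    # latent metabolite log-abundance per sample
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, n_mets)
    carbon_off = {
        c: rng.normal(0.0, cfg.sigma_carbon, n_mets) for c in design.carbon_sources
    }
    type_off = {
        s: rng.normal(0.0, cfg.sigma_type, n_mets) for s in design.sample_types
    }
    met_index = {m: i for i, m in enumerate(mets)}
    latent = np.zeros((n_samples, n_mets))
    for si, sid in enumerate(samples):
        row = sample_meta.loc[sid]
        if row["is_blank"]:
            continue
        mu = base + carbon_off[row["carbon_source"]] + type_off[row["sample_type"]]
        key = (row["carbon_source"], row["treatment"], row["sample_type"])
        if key in affected:
            for met, direction, eff in affected[key]:
                shift = eff * cfg.sigma_bio
                mu[met_index[met]] += shift if direction == "up" else -shift
        latent[si] = mu + rng.normal(0.0, cfg.sigma_bio, n_mets)

    # artifact analytes: latent abundance shared across *all* samples and blanks
    art_base = {a: rng.normal(cfg.base_log_mean, cfg.base_log_sd) for a in sorted(artifact_analytes)}

    lo, hi = cfg.dilution_range
    dilution = np.exp(rng.uniform(math.log(lo), math.log(hi), n_samples))

    analyte_off = {a: rng.normal(0.0, cfg.sigma_analyte) for a in analyte_meta.index}

    X = np.empty((n_samples, len(ion_meta)))
    baseline = np.exp(
        rng.normal(cfg.blank_log_mean, cfg.blank_log_sd, size=X.shape)
    )
    for j, ion in enumerate(ion_meta.index):
        analyte = ion_meta.iloc[j]["analyte"]
        met = analyte_meta.loc[analyte, "metabolite"]
        if analyte in artifact_analytes:
            log_sig = (
                art_base[analyte]
                + analyte_off[analyte]
                + rng.normal(0.0, cfg.sigma_bio, n_samples)
                + rng.normal(0.0, cfg.sigma_meas, n_samples)
            )
            X[:, j] = rf[j] * np.exp(log_sig)
        elif ion in corrupted:
            # magnitude matched to the analyte (that is how a contaminant ion
            # gets mis-selected as a quantifier), variation independent of it
            log_sig = base[met_index[met]] + rng.normal(0.0, cfg.sigma_corrupt, n_samples)
            X[:, j] = cfg.corrupt_rf_scale * rf[j] * np.exp(log_sig)
            X[is_blank, j] = 0.0
        else:
            noise = rng.normal(0.0, cfg.sigma_meas, n_samples)
            log_sig = latent[:, met_index[met]] + analyte_off[analyte] + noise
            X[:, j] = rf[j] * np.exp(log_sig)
            X[is_blank, j] = 0.0
    X = (X + baseline) * dilution[:, None]

    intensities = pd.DataFrame(X, index=samples, columns=ion_meta.index)
    table = IonPeakTable(intensities, ion_meta, sample_meta, analyte_meta)
    truth = GroundTruth(
        affected=affected,
        corrupted_ions=corrupted,
        artifact_analytes=artifact_analytes,
        dilution=dict(zip(samples, dilution)),
        config=cfg,
    )
    return table, truth


#: condition pair whose affected metabolites seed the enriched pathway
FOCAL_PAIR = ("biphenyl", "Al", "cells")


def generate_pathway_annotation(
    truth: GroundTruth,
    design: StudyDesign,
    seed: int,
    n_pathways: int = 20,
    size_range: tuple[int, int] = (5, 20),
    enrichment_fraction: float = 1.0,
) -> PathwayAnnotation:
    """Random pathway sets over the identified metabolites, one spiked.

    The spiked pathway draws ``enrichment_fraction`` of its members from
    the identified metabolites affected in the focal condition pair
    (biphenyl + Al, cells), the rest at random; remaining pathways are
    uniform random subsets with sizes in ``size_range``. The spiked
    pathway's id is recorded on ``truth.enriched_pathway``.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(
        f"m{i + 1:04d}" for i in range(design.n_identified)
    )
    if n_pathways == 0:
        return PathwayAnnotation(pathways={}, universe=set(universe))
    if size_range[0] < 2:
        raise ValueError("pathway sizes must be >= 2")
    if size_range[1] > len(universe):
        raise ValueError("pathway size exceeds the metabolite universe")
    pathways: dict[str, set[str]] = {}
    affected_id = sorted(truth.affected_ids(FOCAL_PAIR) & set(universe))
    n_spike = max(2, round(enrichment_fraction * len(affected_id)))
    members = set(rng.choice(affected_id, min(n_spike, len(affected_id)), replace=False))
    if enrichment_fraction < 1.0:
        rest = sorted(set(universe) - set(affected_id))
        extra = len(affected_id) - len(members)
        if extra > 0:
            members |= set(rng.choice(rest, extra, replace=False))
    pathways["pw_spiked"] = members
    for p in range(1, n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        pathways[f"pw{p:03d}"] = set(rng.choice(universe, size, replace=False))
    truth.enriched_pathway = "pw_spiked"
    return PathwayAnnotation(pathways=pathways, universe=set(universe))


def generate_alkane_ladder(
    c_min: int = 10,
    c_max: int = 30,
    rt_start: float = 4.0,
    rt_per_carbon: float = 1.15,
) -> AlkaneLadder:
    """Retention times of the C10..C30 n-alkane calibration series.

    Under a linear oven-temperature ramp alkanes elute at nearly equal
    spacing; a fixed increment per carbon number is used.
    """
    if c_min >= c_max:
        raise ValueError("c_min must be < c_max")
    carbons = np.arange(c_min, c_max + 1)
    rts = rt_start + rt_per_carbon * (carbons - c_min)
    return AlkaneLadder(carbons=carbons, retention_times=rts)
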