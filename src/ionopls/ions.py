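"""Ion-level quality control for GC-MS peak tables.

A GC-MS run quantifies each chromatographic *analyte* (one derivatized form
of a metabolite) through a handful of selected fragment *quantifier ions*.
If those ions truly derive from the analyte their intensities must covary
across samples; an ion that tracks a co-eluting contaminant instead will
not. This module turns a raw sample x ion intensity matrix into a sample x
metabolite abundance matrix via four steps:

1. artifact exclusion against extraction/derivatization blanks,
2. the ion-correlation validity filter (Pearson r of each ion against the
   sum of its analyte's ions; ions below ``r_min`` are discarded),
3. summation of surviving ions per analyte and merging of derivative
   analytes (e.g. 2TMS and 3TMS forms) into single metabolites,
4. Kovats retention-index assignment from an n-alkane ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IonPeakTable",
    "AnalyteTable",
    "MetaboliteTable",
    "AlkaneLadder",
    "remove_artifacts",
    "validate_ions",
    "merge_derivatives",
    "compute_kovats_ri",
]

#: Fragment m/z values never used as quantifier ions: the ubiquitous
#: trimethylsilyl fragments 73 and 147 and high-background ions.
CONTAMINANT_MZ = frozenset({73, 147, 121, 266, 285, 299})

SAMPLE_META_COLUMNS = ["carbon_source", "treatment", "sample_type", "replicate", "is_blank"]
ION_META_COLUMNS = ["analyte", "mz", "rt"]
ANALYTE_META_COLUMNS = ["metabolite", "identified", "rt"]


@dataclass
class IonPeakTable:
    """Raw unit of input: a sample x quantifier-ion intensity matrix.

    Attributes
    ----------
    intensities
        Non-negative detector intensities, rows indexed by sample id,
        columns by ion id.
    ion_meta
        Per-ion metadata (``analyte``, ``mz``, ``rt`` in minutes), indexed
        by ion id. Every ion maps to exactly one analyte.
    sample_meta
        Per-sample metadata (``carbon_source``, ``treatment``,
        ``sample_type``, ``replicate``, ``is_blank``), indexed by sample id.
    analyte_meta
        Per-analyte metadata (``metabolite``, ``identified``, ``rt``),
        indexed by analyte id.
    """

    intensities: pd.DataFrame
    ion_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    analyte_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)}")
        if self.intensities.columns.has_duplicates:
            dupes = self.intensities.columns[self.intensities.columns.duplicated()].unique()
            raise ValueError(f"duplicate ion ids: {list(dupes)}")
        unknown_samples = self.intensities.index.difference(self.sample_meta.index)
        if len(unknown_samples):
            raise ValueError(f"samples missing from sample_meta: {list(unknown_samples)}")
        unknown_ions = self.intensities.columns.difference(self.ion_meta.index)
        if len(unknown_ions):
            raise ValueError(f"ions missing from ion_meta: {list(unknown_ions)}")
        unknown_analytes = set(self.ion_meta["analyte"]) - set(self.analyte_meta.index)
        if unknown_analytes:
            raise ValueError(f"analytes missing from analyte_meta: {sorted(unknown_analytes)}")
        neg = self.intensities.lt(0)
        if neg.any().any():
            bad = self.intensities.columns[neg.any(axis=0)]
            raise ValueError(f"negative intensities in ions: {list(bad[:5])}")

    @property
    def blank_ids(self) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["is_blank"].astype(bool)]

    @property
    def study_ids(self) -> pd.Index:
        return self.sample_meta.index[~self.sample_meta["is_blank"].astype(bool)]

    def ions_of(self, analyte: str) -> pd.Index:
        return self.ion_meta.index[self.ion_meta["analyte"] == analyte]

    def subset_ions(self, keep_ions) -> "IonPeakTable":
        keep_ions = pd.Index(keep_ions)
        ion_meta = self.ion_meta.loc[keep_ions]
        keep_analytes = ion_meta["analyte"].unique()
        return IonPeakTable(
            intensities=self.intensities[keep_ions],
            ion_meta=ion_meta,
            sample_meta=self.sample_meta.copy(),
            analyte_meta=self.analyte_meta.loc[self.analyte_meta.index.isin(keep_analytes)],
        )


@dataclass
class AnalyteTable:
    """Sample x analyte abundances, each the sum of validated ion intensities."""

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    analyte_meta: pd.DataFrame
    #: analyte -> {"kept": [...ions], "dropped": {ion: reason}}
    provenance: dict = field(default_factory=dict)


@dataclass
class MetaboliteTable:
    """Sample x metabolite abundances after derivative merging; the analysis unit."""

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    identity: pd.Series  # metabolite -> bool (identified / unknown)
    ri: pd.Series | None = None  # metabolite -> Kovats retention index

    @property
    def blank_ids(self) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["is_blank"].astype(bool)]

    @property
    def study_ids(self) -> pd.Index:
        return self.sample_meta.index[~self.sample_meta["is_blank"].astype(bool)]

    def copy_with(self, abundances: pd.DataFrame, sample_meta: pd.DataFrame | None = None) -> "MetaboliteTable":
        sm = self.sample_meta if sample_meta is None else sample_meta
        cols = abundances.columns
        ri = None if self.ri is None else self.ri.reindex(cols)
        return MetaboliteTable(abundances, sm.loc[abundances.index], self.identity.reindex(cols), ri)


@dataclass
class AlkaneLadder:
    """Retention times of the n-alkane calibration series (C10..C30 by default)."""

    carbons: np.ndarray
    retention_times: np.ndarray

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        if len(self.carbons) != len(self.retention_times):
            raise ValueError("carbons and retention_times differ in length")
        if len(self.carbons) < 2:
            raise ValueError("ladder needs at least two alkane rungs")
        if not np.array_equal(np.diff(self.carbons), np.ones(len(self.carbons) - 1, int)):
            raise ValueError("carbon numbers must be consecutive integers")
        if not np.all(np.diff(self.retention_times) > 0):
            raise ValueError("alkane retention times must be strictly increasing")


def remove_artifacts(
    table: IonPeakTable,
    blank_floor: float = 1e3,
    blacklist: tuple[str, ...] = (),
) -> tuple[IonPeakTable, list[str]]:
    """Drop analytes detected in extraction/derivatization blanks.

    Any analyte whose intensity in *any* blank sample exceeds
    ``blank_floor`` (the blank noise floor, in detector units) is treated
    as a derivatization artifact — a compound formed from the reagents,
    vessel plastics or column bleed — and removed entirely. An explicit
    ``blacklist`` of analyte ids (for curated artifact lists) is removed
    unconditionally.

    Returns the filtered table and the sorted list of removed analytes.
    """
    blanks = table.blank_ids
    if len(blanks) == 0:
        raise ValueError("artifact removal requires at least one blank sample")
    blank_max = table.intensities.loc[blanks].max(axis=0)  # per ion
    flagged_ions = blank_max.index[blank_max > blank_floor]
    flagged = set(table.ion_meta.loc[flagged_ions, "analyte"]) | set(blacklist)
    keep_ions = table.ion_meta.index[~table.ion_meta["analyte"].isin(flagged)]
    kept = table.subset_ions(keep_ions)
    return kept, sorted(flagged)


def validate_ions(table: IonPeakTable, r_min: float = 0.8) -> AnalyteTable:
    """Filter quantifier ions by correlation with their analyte's ion sum.

    For each analyte, the Pearson correlation across non-blank samples
    between every ion and the sum of all of that analyte's quantified ions
    (the ion's own contribution included) is computed on raw intensities.
    Ions with r < ``r_min`` are dropped; so are ions whose intensity vector
    is constant (a flat ion carries no quantitative information, so the
    undefined correlation is treated as failing). Analytes left with no
    surviving ion are excluded from the output entirely. Surviving ions
    are summed per sample.
    """
    study = table.study_ids
    if len(study) < 3:
        raise ValueError("ion validation needs >=3 non-blank samples")
    provenance: dict[str, dict] = {}
    sums: dict[str, pd.Series] = {}
    for analyte, ions in table.ion_meta.groupby("analyte").groups.items():
        block = table.intensities.loc[study, list(ions)].to_numpy(dtype=float)
        total = block.sum(axis=1)
        kept, dropped = [], {}
        sd_total = total.std()
        for j, ion in enumerate(ions):
            x = block[:, j]
            if x.std() == 0.0 or sd_total == 0.0:
                dropped[ion] = "zero_variance"
                continue
            r = np.corrcoef(x, total)[0, 1]
            if r < r_min:
                dropped[ion] = f"r={r:.3f}<{r_min}"
            else:
                kept.append(ion)
        provenance[analyte] = {"kept": kept, "dropped": dropped}
        if kept:
            sums[analyte] = table.intensities[kept].sum(axis=1)
    abundances = pd.DataFrame(sums, index=table.intensities.index)
    abundances = abundances[[a for a in table.analyte_meta.index if a in abundances.columns]]
    return AnalyteTable(
        abundances=abundances,
        sample_meta=table.sample_meta.copy(),
        analyte_meta=table.analyte_meta.loc[abundances.columns].copy(),
        provenance=provenance,
    )


def merge_derivatives(
    analytes: AnalyteTable,
    mapping: pd.Series | None = None,
    ladder: AlkaneLadder | None = None,
) -> MetaboliteTable:
    """Sum analytes representing the same metabolite (TMS derivative forms).

    ``mapping`` maps analyte id -> metabolite id; analytes absent from the
    mapping map to themselves. By default the ``metabolite`` column of the
    analyte metadata is used. A metabolite is flagged identified if any of
    its constituent analytes is. When an alkane ``ladder`` is supplied the
    Kovats retention index of each metabolite is computed from the earliest
    constituent analyte's retention time (retention times outside the
    ladder yield a missing RI).
    """
    if mapping is None:
        mapping = analytes.analyte_meta["metabolite"]
    mapping = mapping.reindex(analytes.abundances.columns)
    mapping = mapping.fillna(pd.Series(mapping.index, index=mapping.index))
    merged = analytes.abundances.T.groupby(mapping).sum().T
    identity = analytes.analyte_meta["identified"].astype(bool).groupby(mapping).any()
    identity = identity.reindex(merged.columns)
    ri = None
    if ladder is not None:
        rt = analytes.analyte_meta["rt"].groupby(mapping).min().reindex(merged.columns)
        vals = {}
        for met, t in rt.items():
            try:
                vals[met] = compute_kovats_ri(float(t), ladder)
            except ValueError:
                vals[met] = np.nan
        ri = pd.Series(vals).reindex(merged.columns)
    return MetaboliteTable(merged, analytes.sample_meta.copy(), identity, ri)


def compute_kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index under the linear temperature-program convention.

    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)) with C_n, C_{n+1} the
    alkane rungs bracketing ``rt``. Retention times outside the ladder are
    an error: extrapolation beyond the calibrated range is not meaningful.
    """
    times = ladder.retention_times
    if rt < times[0] or rt > times[-1]:
        raise ValueError(
            f"retention time {rt} min outside alkane ladder range "
            f"[{times[0]}, {times[-1]}]"
        )
    i = int(np.searchsorted(times, rt, side="right") - 1)
    i = min(i, len(times) - 2)
    n = ladder.carbons[i]
    return 100.0 * (n + (rt - times[i]) / (times[i + 1] - times[i]))
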