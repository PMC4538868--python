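"""End-to-end workflow: ion QC -> preprocessing -> models -> SUS -> enrichment.

``run_pipeline`` chains the stages in the order the experimental design
dictates:

    remove_artifacts -> validate_ions -> merge_derivatives ->
    noise_threshold -> pqn_normalize -> log transform -> trim_outliers ->
    global PCA + hierarchical clustering ->
    pairwise OPLS-DA per (carbon source, metal, sample type) ->
    VIP / p(corr) -> SUS comparisons across carbon sources ->
    pathway over-representation per cells model

Every output file records the configuration hash and seed; two runs with
the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iomod
from .ions import merge_derivatives, remove_artifacts, validate_ions
from .multivariate import (
    cross_validate_q2,
    cv_anova,
    fit_opls_da,
    fit_pca,
    hierarchical_cluster,
    variable_stats,
)
from .preprocess import autoscale, log_autoscale, noise_threshold, pqn_normalize, trim_outliers
from .sus_enrichment import build_sus, enrich, select_hits

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline"]

_FLOAT = "%.10g"
CONTROL = "control"


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus input paths; flat, hashable, YAML-loadable."""

    ion_dir: str | None = None  # directory of ion-table CSVs
    gmt_path: str | None = None
    ladder_path: str | None = None
    out_dir: str = "results/pipeline"
    blank_floor: float = 1e3
    r_min: float = 0.8
    blank_rule: str = "per_metabolite"
    pqn_reference: str = "stratified_control"
    outlier_alpha: float = 0.05
    n_orth: int = 1
    n_folds: int = 7
    vip_threshold: float = 0.8
    fdr_cut: float = 0.05
    n_pca_components: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.vip_threshold:
            raise ValueError("vip_threshold must be >= 0")
        for name in ("fdr_cut", "outlier_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [-1, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def config_hash(self) -> str:
        # out_dir is where results land, not a scientific parameter
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineResult:
    config: PipelineConfig
    config_hash: str
    metabolites: object  # MetaboliteTable after noise threshold + PQN
    scaled: object  # global ScaledMatrix (retained samples)
    retained: pd.Index
    pca: object
    hcl_order: list
    models: dict  # model name -> OplsModel
    stats: dict  # model name -> VIP/p(corr) DataFrame
    model_table: pd.DataFrame
    sus: dict  # comparison name -> SUS DataFrame
    enrichment: dict  # model name -> enrichment DataFrame
    log: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    config: PipelineConfig,
    table=None,
    annotation=None,
    ladder=None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full workflow; inputs may come from files or in memory."""
    log: dict = {"stages": {}}

    if table is None:
        if config.ion_dir is None:
            raise PipelineError("stage 'load' failed: no ion table given (set ion_dir)")
        table = _stage("load")(iomod.read_ion_table)(config.ion_dir)
    if annotation is None and config.gmt_path:
        annotation = _stage("load")(iomod.read_gmt)(config.gmt_path)
    if ladder is None and config.ladder_path:
        ladder = _stage("load")(iomod.read_alkane_ladder)(config.ladder_path)

    n_ions0 = table.intensities.shape[1]
    table, artifacts = _stage("remove_artifacts")(remove_artifacts)(table, config.blank_floor)
    log["stages"]["remove_artifacts"] = {
        "removed_analytes": artifacts,
        "ions_in": n_ions0,
        "ions_out": table.intensities.shape[1],
    }

    analytes = _stage("validate_ions")(validate_ions)(table, config.r_min)
    dropped_ions = sorted(
        ion for prov in analytes.provenance.values() for ion in prov["dropped"]
    )
    log["stages"]["validate_ions"] = {
        "dropped_ions": dropped_ions,
        "analytes_out": analytes.abundances.shape[1],
    }

    mt = _stage("merge_derivatives")(merge_derivatives)(analytes, ladder=ladder)
    log["stages"]["merge_derivatives"] = {"metabolites": mt.abundances.shape[1]}

    mt = _stage("noise_threshold")(noise_threshold)(mt, config.blank_rule)
    norm = _stage("pqn_normalize")(pqn_normalize)(mt, config.pqn_reference)
    mt = norm.normalized
    log["stages"]["pqn_normalize"] = {
        "factors": {k: float(v) for k, v in norm.quotient_factors.items()}
    }

    scaled_all = _stage("log_autoscale")(log_autoscale)(mt, on_constant="drop")
    meta = mt.sample_meta
    classes = (
        meta["carbon_source"] + "/" + meta["treatment"] + "/" + meta["sample_type"]
    )
    trim = _stage("trim_outliers")(trim_outliers)(scaled_all, classes, config.outlier_alpha)
    retained = trim.retained
    log["stages"]["trim_outliers"] = {"flagged": list(trim.flagged)}

    # logged (unscaled) matrix: per-model scaling happens inside each subset
    logged = pd.DataFrame(
        np.log(mt.abundances.to_numpy(dtype=float) + scaled_all.log_offset),
        index=mt.abundances.index,
        columns=mt.abundances.columns,
    ).loc[retained]
    scaled = _stage("log_autoscale")(autoscale)(logged, on_constant="drop", log_offset=scaled_all.log_offset)

    pca = _stage("pca")(fit_pca)(scaled, config.n_pca_components)
    _, order = _stage("hcl")(hierarchical_cluster)(scaled)

    meta_r = meta.loc[retained]
    carbons = sorted(meta_r["carbon_source"].unique())
    metals = sorted(t for t in meta_r["treatment"].unique() if t != CONTROL)
    stypes = sorted(s for s in meta_r["sample_type"].unique())

    models: dict = {}
    stats: dict = {}
    rows = [
        {
            "Model": "All",
            "Type": "PCA",
            "Components": str(config.n_pca_components),
            "R2": round(float(pca.r2x_cum[-1]), 3),
            "Q2": "",
            "CV-ANOVA p": "",
        }
    ]

    def _fit_pair(carbon, metal, stype):
        sel = meta_r.index[
            (meta_r["carbon_source"] == carbon)
            & (meta_r["sample_type"] == stype)
            & (meta_r["treatment"].isin([CONTROL, metal]))
        ]
        sub = autoscale(logged.loc[sel], on_constant="zero")
        cls = meta_r.loc[sel, "treatment"]
        model = fit_opls_da(sub, cls, n_orth=config.n_orth, positive_class=metal)
        cv = cross_validate_q2(sub, cls, n_orth=config.n_orth, n_folds=config.n_folds,
                               positive_class=metal)
        model.q2 = cv.q2
        model.cv_anova = cv_anova(cv, model.n_components)
        return model, variable_stats(model, sub)

    for carbon in carbons:
        for metal in metals:
            for stype in stypes:
                name = f"{carbon} {metal} {stype}"
                model, vs = _stage(f"opls:{name}")(_fit_pair)(carbon, metal, stype)
                models[name] = model
                stats[name] = vs
                rows.append(
                    {
                        "Model": name,
                        "Type": "OPLS-DA",
                        "Components": f"1 + {model.n_orth}",
                        "R2": round(model.r2y, 3),
                        "Q2": round(model.q2, 3),
                        "CV-ANOVA p": round(model.cv_anova[1], 4),
                    }
                )
    model_table = pd.DataFrame(rows)

    sus: dict = {}
    if len(carbons) == 2:
        a, b = carbons
        for metal in metals:
            for stype in stypes:
                name = f"{metal} {stype} ({a} vs {b})"
                sus[name] = _stage(f"sus:{name}")(build_sus)(
                    stats[f"{a} {metal} {stype}"],
                    stats[f"{b} {metal} {stype}"],
                    config.vip_threshold,
                )

    enrichment: dict = {}
    if annotation is not None and "cells" in stypes:
        identity = mt.identity
        background = sorted(set(mt.abundances.columns[identity.fillna(False)])
                            & (annotation.universe or set(mt.abundances.columns)))
        for carbon in carbons:
            for metal in metals:
                name = f"{carbon} {metal} cells"
                hits = select_hits(stats[name], identity, config.vip_threshold, strict=True)
                hits = [h for h in hits if h in background]
                enrichment[name] = _stage(f"enrich:{name}")(enrich)(
                    hits, background, annotation, config.fdr_cut
                )

    result = PipelineResult(
        config=config,
        config_hash=config.config_hash(),
        metabolites=mt,
        scaled=scaled,
        retained=retained,
        pca=pca,
        hcl_order=order,
        models=models,
        stats=stats,
        model_table=model_table,
        sus=sus,
        enrichment=enrichment,
        log=log,
    )
    if write:
        _write_outputs(result)
    return result


def _header(result: PipelineResult) -> str:
    return f"# config_hash={result.config_hash} seed={result.config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, result: PipelineResult, index=True) -> None:
    with path.open("w") as fh:
        fh.write(_header(result))
        df.to_csv(fh, sep="\t", index=index, float_format=_FLOAT)


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.model_table, out / "model_statistics.tsv", result, index=False)
    for name, df in sorted(result.sus.items()):
        _write_tsv(df, out / f"sus_{_slug(name)}.tsv", result)
    for name, df in sorted(result.enrichment.items()):
        _write_tsv(df, out / f"enrichment_{_slug(name)}.tsv", result)
    for name, vs in sorted(result.stats.items()):
        _write_tsv(vs, out / f"variable_stats_{_slug(name)}.tsv", result)
    qc_rows = [
        {"item": a, "kind": "artifact_analyte", "reason": "detected in blanks"}
        for a in result.log["stages"]["remove_artifacts"]["removed_analytes"]
    ] + [
        {"item": i, "kind": "dropped_ion", "reason": "failed correlation filter"}
        for i in result.log["stages"]["validate_ions"]["dropped_ions"]
    ] + [
        {"item": s, "kind": "trimmed_sample", "reason": "Hotelling T2 outlier"}
        for s in result.log["stages"]["trim_outliers"]["flagged"]
    ]
    _write_tsv(pd.DataFrame(qc_rows, columns=["item", "kind", "reason"]),
               out / "qc_report.tsv", result, index=False)
    run_log = {
        # out_dir is run-specific and excluded so equal configs rerun byte-identically
        "config": {k: v for k, v in dataclasses.asdict(result.config).items()
                   if k != "out_dir"},
        "config_hash": result.config_hash,
        "seed": result.config.seed,
        "stages": result.log["stages"],
        "hcl_order": list(result.hcl_order),
        "models": {
            name: {
                "r2y": m.r2y,
                "q2": m.q2,
                "components": f"1 + {m.n_orth}",
                "cv_anova_F": m.cv_anova[0],
                "cv_anova_p": m.cv_anova[1],
                "positive_class": str(m.positive_class),
            }
            for name, m in sorted(result.models.items())
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))


def _slug(name: str) -> str:
    return (
        name.replace(" ", "_")
        .replace("(", "")
        .replace(")", "")
        .replace("/", "-")
    )
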