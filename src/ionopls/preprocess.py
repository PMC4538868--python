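"""Noise thresholding, PQN, log-autoscaling and PCA-based outlier trimming.

The preprocessing chain mirrors standard chemometric practice for GC-MS
peak tables: intensities below the blank-derived noise floor are zeroed,
each sample is divided by its probabilistic quotient (the median ratio of
its metabolite values to a reference spectrum, a robust estimate of the
sample's overall dilution), abundances are log transformed, and every
metabolite is mean-centered and scaled to unit variance. Samples that do
not resemble the rest of their class — judged by the Hotelling T2 of a
per-class two-component PCA — are trimmed before modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ions import MetaboliteTable

__all__ = [
    "NormalizationResult",
    "ScaledMatrix",
    "TrimResult",
    "noise_threshold",
    "pqn_normalize",
    "log_autoscale",
    "trim_outliers",
]


def noise_threshold(table: MetaboliteTable, rule: str = "per_metabolite") -> MetaboliteTable:
    """Zero study-sample values below the blank mean; drop the blanks.

    The noise floor is the mean intensity in the extraction-control blank
    samples, computed per metabolite by default (``rule="global"`` uses a
    single mean over all metabolites). Values *strictly* below the floor
    are set to zero; ties are retained. Blank samples are discarded from
    the returned table.
    """
    blanks = table.blank_ids
    if len(blanks) == 0:
        raise ValueError("noise thresholding requires at least one blank sample")
    blank_block = table.abundances.loc[blanks]
    if rule == "per_metabolite":
        floor = blank_block.mean(axis=0)
    elif rule == "global":
        floor = pd.Series(blank_block.to_numpy().mean(), index=table.abundances.columns)
    else:
        raise ValueError(f"unknown blank rule: {rule!r}")
    study = table.study_ids
    values = table.abundances.loc[study].copy()
    values = values.where(values.ge(floor, axis=1), 0.0)
    return table.copy_with(values, table.sample_meta.loc[study])


@dataclass
class NormalizationResult:
    normalized: MetaboliteTable
    quotient_factors: pd.Series  # sample -> divisor applied
    reference: pd.DataFrame  # per-stratum reference spectra (rows = stratum)


def _reference_spectrum(values: pd.DataFrame) -> pd.Series:
    ref = values.median(axis=0)
    return ref


def pqn_normalize(
    table: MetaboliteTable,
    reference_rule: str = "stratified_control",
    control_label: str = "control",
) -> NormalizationResult:
    """Probabilistic quotient normalization.

    Each sample is divided by the median of its quotients value/reference,
    taken over metabolites where both the sample and the reference are
    positive. Reference rules:

    ``stratified_control`` (default)
        per (carbon source, sample type) stratum, the per-metabolite
        median over that stratum's control (untreated) samples; each
        sample is normalized against its own stratum's reference. This
        avoids leaking treatment effects into the reference and never
        compares cells against spent media.
    ``control``
        median over all control samples.
    ``median``
        median over all samples (no metadata needed).
    """
    values = table.abundances
    meta = table.sample_meta
    factors = pd.Series(index=values.index, dtype=float)
    references: dict = {}

    def _factor(sample: pd.Series, ref: pd.Series, sid: str) -> float:
        both = (sample > 0) & (ref > 0)
        if not both.any():
            raise ValueError(f"sample {sid} shares no nonzero metabolites with the reference")
        return float(np.median(sample[both] / ref[both]))

    if reference_rule == "stratified_control":
        strata = meta.groupby(["carbon_source", "sample_type"], sort=True).groups
        for stratum, sids in strata.items():
            sub = meta.loc[sids]
            controls = sub.index[sub["treatment"] == control_label]
            if len(controls) == 0:
                raise ValueError(f"stratum {stratum} has no {control_label!r} samples")
            ref = _reference_spectrum(values.loc[controls])
            references[stratum] = ref
            for sid in sids:
                factors[sid] = _factor(values.loc[sid], ref, sid)
    elif reference_rule in ("control", "median"):
        if reference_rule == "control":
            controls = meta.index[meta["treatment"] == control_label]
            if len(controls) == 0:
                raise ValueError("no control samples for the PQN reference")
            ref = _reference_spectrum(values.loc[controls])
        else:
            ref = _reference_spectrum(values)
        references["all"] = ref
        for sid in values.index:
            factors[sid] = _factor(values.loc[sid], ref, sid)
    else:
        raise ValueError(f"unknown PQN reference rule: {reference_rule!r}")

    if (factors <= 0).any():
        bad = list(factors.index[factors <= 0])
        raise ValueError(f"non-positive quotient factors for samples: {bad}")
    normalized = values.div(factors, axis=0)
    return NormalizationResult(
        normalized=table.copy_with(normalized),
        quotient_factors=factors,
        reference=pd.DataFrame(references).T,
    )


@dataclass
class ScaledMatrix:
    """Column-wise z-scores of log abundances, with the inverse transform retained."""

    values: pd.DataFrame
    col_means: pd.Series
    col_sds: pd.Series
    log_offset: float
    dropped: list[str] = field(default_factory=list)


def autoscale(values: pd.DataFrame, on_constant: str = "drop", log_offset: float = 0.0) -> ScaledMatrix:
    """Mean-center and scale columns to unit variance (no log transform)."""
    arr = values.to_numpy(dtype=float)
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    constant = sds == 0
    z = np.zeros_like(arr)
    ok = ~constant
    z[:, ok] = (arr[:, ok] - means[ok]) / sds[ok]
    cols = values.columns
    dropped = list(cols[constant])
    if constant.any() and on_constant == "drop":
        warnings.warn(f"dropping constant metabolites: {dropped[:5]}...", stacklevel=2)
        z = z[:, ok]
        cols = cols[ok]
        means, sds = means[ok], sds[ok]
    elif constant.any() and on_constant != "zero":
        raise ValueError(f"unknown on_constant: {on_constant!r}")
    return ScaledMatrix(
        values=pd.DataFrame(z, index=values.index, columns=cols),
        col_means=pd.Series(means, index=cols),
        col_sds=pd.Series(sds, index=cols),
        log_offset=float(log_offset),
        dropped=dropped,
    )


def log_autoscale(
    table: MetaboliteTable | pd.DataFrame,
    on_constant: str = "drop",
) -> ScaledMatrix:
    """Natural log then unit-variance autoscaling of each metabolite.

    Zeros are handled by adding half the smallest nonzero value of the
    matrix before taking logs; the offset is recorded for provenance.
    Metabolites constant across samples (e.g. zero everywhere) have no
    defined variance and are dropped with a warning, or kept as all-zero
    columns with ``on_constant="zero"`` (useful when several models must
    share one metabolite universe).
    """
    values = table.abundances if isinstance(table, MetaboliteTable) else table
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundances cannot be log transformed")
    nonzero = arr[arr > 0]
    offset = 0.5 * nonzero.min() if len(nonzero) and (arr == 0).any() else 0.0
    logged = pd.DataFrame(np.log(arr + offset), index=values.index, columns=values.columns)
    return autoscale(logged, on_constant=on_constant, log_offset=offset)


@dataclass
class TrimResult:
    retained: pd.Index
    flagged: pd.Index
    report: pd.DataFrame  # sample, class, T2, threshold, flagged


def trim_outliers(
    scaled: ScaledMatrix,
    class_labels: pd.Series,
    alpha: float = 0.05,
    n_components: int = 2,
) -> TrimResult:
    """Per-class PCA outlier trimming by Hotelling T2.

    For each class a PCA is fit on that class's samples alone and each
    sample's T2 over the leading scores is compared against the in-model
    Hotelling limit at level ``alpha`` — the Beta-distribution form
    ``(n-1)^2/n * Beta_{1-alpha}(A/2, (n-A-1)/2)`` appropriate for samples
    that were part of the fit. Classes with fewer than 3 samples are
    skipped with a warning. Flagged samples are excluded from the retained
    set used by all downstream analyses.
    """
    X = scaled.values
    labels = class_labels.reindex(X.index)
    rows = []
    flagged_ids: list = []
    for cls, sids in labels.groupby(labels).groups.items():
        sub = X.loc[sids].to_numpy(dtype=float)
        n = sub.shape[0]
        if n < 3:
            warnings.warn(f"class {cls!r} has <3 samples; outlier trimming skipped", stacklevel=2)
            continue
        A = min(n_components, n - 2, sub.shape[1])
        if A < 1:
            warnings.warn(f"class {cls!r} too small for PCA trimming; skipped", stacklevel=2)
            continue
        centered = sub - sub.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        scores = (u * s)[:, :A]
        var = scores.var(axis=0, ddof=1)
        var[var == 0] = np.inf  # degenerate direction carries no distance
        t2 = (scores**2 / var).sum(axis=1)
        limit = (n - 1) ** 2 / n * stats.beta.ppf(1 - alpha, A / 2, (n - A - 1) / 2)
        for sid, val in zip(sids, t2):
            bad = bool(val > limit)
            rows.append({"sample_id": sid, "class": cls, "T2": val, "threshold": limit, "flagged": bad})
            if bad:
                flagged_ids.append(sid)
    report = pd.DataFrame(rows, columns=["sample_id", "class", "T2", "threshold", "flagged"])
    flagged = pd.Index(flagged_ids)
    retained = X.index.difference(flagged, sort=False)
    return TrimResult(retained=retained, flagged=flagged, report=report)
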