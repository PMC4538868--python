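"""Shared-and-unique-structures tables and pathway over-representation.

A SUS comparison takes the per-metabolite statistics of two pairwise
OPLS-DA models (VIP, the variable importance in projection, and p(corr),
the correlation of the metabolite with the predictive score) and plots
one model's VIP against the other's. Metabolites below the VIP threshold
in both models carry no signal and are omitted; the rest are categorized
by the signs of p(corr) into shared (up in both, down in both, opposite)
or model-specific (only_*) effects.

Over-representation of a hit list within annotated pathways is tested
with the upper-tail hypergeometric distribution and Benjamini-Hochberg
FDR control across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayAnnotation",
    "build_sus",
    "select_hits",
    "enrich",
    "plot_sus",
]

SUS_CATEGORIES = (
    "up_up",
    "up_down",
    "down_up",
    "down_down",
    "only_A_up",
    "only_A_down",
    "only_B_up",
    "only_B_down",
)


@dataclass
class PathwayAnnotation:
    """Pathway id -> member metabolite ids, over a declared universe."""

    pathways: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)
    descriptions: dict[str, str] = field(default_factory=dict)
    exclude: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.universe:
            for pw, members in self.pathways.items():
                stray = members - self.universe
                if stray:
                    raise ValueError(
                        f"pathway {pw} has members outside the universe: {sorted(stray)[:5]}"
                    )


def _check_stats(stats: pd.DataFrame) -> None:
    missing = {"vip", "pcorr"} - set(stats.columns)
    if missing:
        raise ValueError(f"variable stats lack columns: {sorted(missing)}")


def build_sus(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    vip_threshold: float = 0.8,
) -> pd.DataFrame:
    """Combine two models' VIP/p(corr) tables into a SUS table.

    Both inputs must be indexed by the same metabolite universe and carry
    ``vip`` and ``pcorr`` columns. Metabolites with VIP below the
    threshold in both models are omitted (inclusion uses >=, matching the
    dashed-line convention of SUS plots). The category encodes direction:
    ``up``/``down`` refer to the sign of p(corr) in model A then model B;
    metabolites significant in a single model get an ``only_*`` label. A
    p(corr) of exactly zero counts as up (fixed tie-break).
    """
    _check_stats(stats_a)
    _check_stats(stats_b)
    only_a = stats_a.index.difference(stats_b.index)
    only_b = stats_b.index.difference(stats_a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "metabolite universes differ between models: "
            f"only in A: {list(only_a[:5])}, only in B: {list(only_b[:5])}"
        )
    stats_b = stats_b.reindex(stats_a.index)
    rows = []
    for met in stats_a.index:
        va, pa = stats_a.loc[met, "vip"], stats_a.loc[met, "pcorr"]
        vb, pb = stats_b.loc[met, "vip"], stats_b.loc[met, "pcorr"]
        sig_a = va >= vip_threshold
        sig_b = vb >= vip_threshold
        if not (sig_a or sig_b):
            continue
        if sig_a and sig_b:
            cat = f"{'up' if pa >= 0 else 'down'}_{'up' if pb >= 0 else 'down'}"
        elif sig_a:
            cat = f"only_A_{'up' if pa >= 0 else 'down'}"
        else:
            cat = f"only_B_{'up' if pb >= 0 else 'down'}"
        rows.append((met, va, vb, pa, pb, cat))
    return pd.DataFrame(
        rows, columns=["metabolite", "vip_A", "vip_B", "pcorr_A", "pcorr_B", "category"]
    ).set_index("metabolite")


def select_hits(
    stats: pd.DataFrame,
    identified: pd.Series | None = None,
    vip_threshold: float = 0.8,
    strict: bool = True,
) -> list[str]:
    """Metabolites with VIP above the threshold, restricted to identified ones.

    Hit selection for enrichment uses a strict ``VIP > threshold`` by
    default (SUS inclusion, by contrast, uses >=). ``identified`` is a
    boolean series over the metabolite index; unidentified metabolites
    cannot be pathway-mapped and are excluded when it is given.
    """
    _check_stats(stats)
    vip = stats["vip"]
    mask = vip > vip_threshold if strict else vip >= vip_threshold
    if identified is not None:
        mask &= identified.reindex(stats.index).fillna(False).astype(bool)
    return list(stats.index[mask])


def enrich(
    hits,
    background,
    annotation: PathwayAnnotation,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each pathway.

    For a pathway with K members inside the background of size N and a
    hit list of size n overlapping it in k metabolites, the p-value is
    the upper tail P[X >= k] of Hypergeometric(N, K, n). P-values are
    Benjamini-Hochberg adjusted across the tested pathways (pathways on
    the annotation's exclusion list are dropped before testing) and the
    table is sorted by p, ties broken by pathway id.
    """
    background = set(background)
    hits = set(hits)
    if not background:
        raise ValueError("empty background")
    stray = hits - background
    if stray:
        raise ValueError(f"hits outside background: {sorted(stray)[:5]}")
    n = len(hits)
    N = len(background)
    rows = []
    for pw in sorted(annotation.pathways):
        if pw in annotation.exclude:
            continue
        members = annotation.pathways[pw] & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pw, K, k, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway", "K", "k", "n", "N", "p"])
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out.set_index("pathway")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] <= fdr_cut
    return out.sort_values(["p", "pathway"]).set_index("pathway")


def plot_sus(
    sus: pd.DataFrame,
    path,
    labels: tuple[str, str] = ("model A", "model B"),
    vip_threshold: float = 0.8,
) -> None:
    """Scatter of VIP_A vs VIP_B with dashed threshold lines and category glyphs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = {
        "up_up": "s",
        "down_down": "v",
        "up_down": "D",
        "down_up": "^",
        "only_A_up": "<",
        "only_A_down": "<",
        "only_B_up": ">",
        "only_B_down": ">",
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    for cat, group in sus.groupby("category"):
        ax.scatter(
            group["vip_A"],
            group["vip_B"],
            marker=markers.get(cat, "o"),
            label=cat,
            alpha=0.7,
            s=25,
        )
    ax.axvline(vip_threshold, ls="--", c="grey", lw=1)
    ax.axhline(vip_threshold, ls="--", c="grey", lw=1)
    ax.set_xlabel(f"VIP ({labels[0]})")
    ax.set_ylabel(f"VIP ({labels[1]})")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
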