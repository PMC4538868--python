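"""PCA, hierarchical clustering and two-class OPLS-DA with model statistics.

OPLS-DA splits the variation of a column-centered data matrix X facing a
binary class vector y (coded +/-1 and centered) into one *predictive*
component, whose score t carries the between-class difference, and k
*orthogonal* components capturing structured within-class variation that
is uncorrelated with y. The algorithm is the single-response orthogonal
projections scheme:

1. w = X'y / ||X'y||  (the predictive weight; invariant under orthogonal
   deflation since t_o'y = 0 by construction),
2. for each orthogonal component: t = Xw, p = X't/t't,
   w_o = p - (w'p)w normalized, t_o = Xw_o, p_o = X't_o/t_o't_o,
   X <- X - t_o p_o',
3. on the deflated X: t = Xw, p = X't/t't, q = y't/t't,
   R2Y = 1 - ||y - tq||^2 / ||y||^2.

Model significance uses sevenfold cross-validation: the model (orthogonal
and predictive components alike) is refit on each training split, held-out
samples are predicted, and Q2 = 1 - PRESS/SS(y). CV-ANOVA then compares
the cross-validated residuals against the total variation of y with an
F test whose model df is the number of fitted components C and residual
df is n - C - 1.

The per-variable summaries are VIP (variable importance in projection over
the predictive component, normalized so that mean(VIP^2) = 1) and p(corr),
the Pearson correlation of each variable with the predictive score t. The
sign of the model is fixed so that t correlates positively with the class
coded +1 (the treated class in this pipeline): positive p(corr) then means
elevated in the treated class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "PcaModel",
    "OplsModel",
    "CvResult",
    "fit_pca",
    "hierarchical_cluster",
    "fit_opls_da",
    "cross_validate_q2",
    "cv_anova",
    "compute_vip",
    "compute_pcorr",
    "variable_stats",
]


def _as_frame(X) -> pd.DataFrame:
    from .preprocess import ScaledMatrix

    if isinstance(X, ScaledMatrix):
        return X.values
    return pd.DataFrame(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    r2x: np.ndarray  # variance explained per component
    n_components: int

    @property
    def r2x_cum(self) -> np.ndarray:
        return np.cumsum(self.r2x)


def fit_pca(X, n_components: int) -> PcaModel:
    """SVD-based principal component analysis of a column-centered matrix.

    Scores are the left singular vectors scaled by the singular values;
    R2X of component a is sigma_a^2 / sum(sigma^2) over the full spectrum.
    """
    Xf = _as_frame(X)
    arr = Xf.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    comp = [f"PC{a + 1}" for a in range(n_components)]
    scores = pd.DataFrame((u * s)[:, :n_components], index=Xf.index, columns=comp)
    loadings = pd.DataFrame(vt[:n_components].T, index=Xf.columns, columns=comp)
    r2x = (s[:n_components] ** 2) / (s**2).sum()
    return PcaModel(scores=scores, loadings=loadings, r2x=r2x, n_components=n_components)


def hierarchical_cluster(
    X,
    linkage_rule: str = "average",
    metric: str = "euclidean",
):
    """Agglomerative clustering of samples; returns (linkage matrix, leaf order).

    The linkage matrix follows the scipy convention; leaf order gives the
    dendrogram ordering of sample ids. Ties are broken deterministically
    by sample index (scipy's ordering is stable for equal heights).
    """
    Xf = _as_frame(X)
    arr = Xf.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in clustering input")
    if arr.shape[0] < 2:
        return np.empty((0, 4)), list(Xf.index)
    Z = linkage(arr, method=linkage_rule, metric=metric)
    order = [Xf.index[i] for i in leaves_list(Z)]
    return Z, order


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    w: pd.Series  # predictive weights, unit norm
    t: pd.Series  # predictive scores
    p: pd.Series  # predictive loadings
    q: float  # y loading
    W_o: pd.DataFrame  # variables x orthogonal components
    T_o: pd.DataFrame  # samples x orthogonal components
    P_o: pd.DataFrame
    r2y: float
    n_orth: int
    classes: pd.Series  # sample -> class label
    positive_class: object
    y_mean: float
    x_mean: pd.Series
    q2: float | None = None
    cv_anova: tuple[float, float] | None = None  # (F, p)

    @property
    def n_components(self) -> int:
        return 1 + self.n_orth

    def predict(self, Xnew: pd.DataFrame) -> pd.Series:
        arr = Xnew[self.w.index].to_numpy(dtype=float) - self.x_mean.to_numpy()
        for a in self.W_o.columns:
            t_o = arr @ self.W_o[a].to_numpy()
            arr = arr - np.outer(t_o, self.P_o[a].to_numpy())
        yhat = (arr @ self.w.to_numpy()) * self.q + self.y_mean
        return pd.Series(yhat, index=Xnew.index)


def _encode_y(classes: pd.Series, positive_class=None) -> tuple[np.ndarray, object]:
    levels = sorted(pd.unique(classes), key=str)
    if len(levels) != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {levels}")
    if positive_class is None:
        positive_class = levels[1]
    if positive_class not in levels:
        raise ValueError(f"positive_class {positive_class!r} not among {levels}")
    y = np.where(classes.to_numpy() == positive_class, 1.0, -1.0)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("each class needs >= 2 samples")
    return y, positive_class


def _opls_core(arr: np.ndarray, y: np.ndarray, n_orth: int):
    """Raw OPLS on a centered array; returns w, W_o, P_o, T_o, t, q."""
    c = arr.T @ y
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("X carries no covariance with y; cannot fit")
    w = c / norm
    W_o, P_o, T_o = [], [], []
    Xd = arr.copy()
    for _ in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    return w, np.array(W_o).T, np.array(P_o).T, np.array(T_o).T, t, p, q


def fit_opls_da(
    X,
    classes: pd.Series,
    n_orth: int = 1,
    positive_class=None,
) -> OplsModel:
    """Fit a two-class OPLS-DA model with ``n_orth`` orthogonal components.

    X must be column-centered (an autoscaled matrix qualifies); y is the
    class coded +/-1 and centered. The returned model is sign-fixed so
    that q >= 0, i.e. large predictive scores mean the positive (treated)
    class.
    """
    Xf = _as_frame(X)
    classes = pd.Series(classes).reindex(Xf.index) if not isinstance(classes, pd.Series) else classes.reindex(Xf.index)
    if classes.isna().any():
        raise ValueError("class labels missing for some samples")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    arr = Xf.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr - arr.mean(axis=0))
    if n_orth >= rank:
        raise ValueError(f"n_orth={n_orth} must be below the matrix rank {rank}")
    y_raw, positive_class = _encode_y(classes, positive_class)
    x_mean = arr.mean(axis=0)
    arr = arr - x_mean
    y_mean = y_raw.mean()
    y = y_raw - y_mean

    w, W_o, P_o, T_o, t, p, q = _opls_core(arr, y, n_orth)
    if q < 0:  # fix sign: t points toward the positive class
        w, t, p, q = -w, -t, -p, -q
    resid = y - t * q
    r2y = float(1.0 - (resid @ resid) / (y @ y))

    k = W_o.shape[1] if W_o.size else 0
    ocols = [f"o{a + 1}" for a in range(k)]
    return OplsModel(
        w=pd.Series(w, index=Xf.columns, name="w"),
        t=pd.Series(t, index=Xf.index, name="t"),
        p=pd.Series(p, index=Xf.columns, name="p"),
        q=q,
        W_o=pd.DataFrame(W_o if k else np.empty((len(Xf.columns), 0)), index=Xf.columns, columns=ocols),
        T_o=pd.DataFrame(T_o if k else np.empty((len(Xf.index), 0)), index=Xf.index, columns=ocols),
        P_o=pd.DataFrame(P_o if k else np.empty((len(Xf.columns), 0)), index=Xf.columns, columns=ocols),
        r2y=r2y,
        n_orth=k,
        classes=classes,
        positive_class=positive_class,
        y_mean=float(y_mean),
        x_mean=pd.Series(x_mean, index=Xf.columns),
    )


@dataclass
class CvResult:
    q2: float
    press: float
    ss: float
    n: int
    predictions: pd.Series  # out-of-fold predictions per sample
    folds: pd.Series


def _round_robin_folds(classes: pd.Series, n_folds: int) -> pd.Series:
    """Deterministic stratified fold assignment: round-robin within class."""
    folds = pd.Series(index=classes.index, dtype=int)
    for cls in sorted(pd.unique(classes), key=str):
        idx = classes.index[classes == cls]
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def cross_validate_q2(
    X,
    classes: pd.Series,
    n_orth: int = 1,
    n_folds: int = 7,
    positive_class=None,
) -> CvResult:
    """Sevenfold cross-validated Q2 of an OPLS-DA model.

    Fold assignment is deterministic: round-robin within each class in
    sample order. Orthogonal and predictive components are re-fit inside
    every training split (no information leak); held-out samples are
    predicted, PRESS accumulated, and Q2 = 1 - PRESS/SS with SS the total
    centered variation of y. Folds left empty by small classes are
    skipped; a fold whose training split lacks a class is an error.
    """
    Xf = _as_frame(X)
    classes = classes.reindex(Xf.index)
    n = len(Xf)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds the {n} available samples")
    y_all, positive_class = _encode_y(classes, positive_class)
    folds = _round_robin_folds(classes, n_folds)
    arr = Xf.to_numpy(dtype=float)
    preds = pd.Series(index=Xf.index, dtype=float)
    for f in range(n_folds):
        test = folds.to_numpy() == f
        if not test.any():
            continue
        train = ~test
        if len(np.unique(y_all[train])) < 2:
            raise ValueError(f"fold {f} leaves a training split without both classes")
        xm = arr[train].mean(axis=0)
        ym = y_all[train].mean()
        w, W_o, P_o, _, _, _, q = _opls_core(arr[train] - xm, y_all[train] - ym, n_orth)
        Xt = arr[test] - xm
        for a in range(W_o.shape[1] if W_o.size else 0):
            t_o = Xt @ W_o[:, a]
            Xt = Xt - np.outer(t_o, P_o[:, a])
        preds.iloc[np.flatnonzero(test)] = (Xt @ w) * q + ym
    ss = float(((y_all - y_all.mean()) ** 2).sum())
    press = float(((y_all - preds.to_numpy()) ** 2).sum())
    return CvResult(q2=1.0 - press / ss, press=press, ss=ss, n=n, predictions=preds, folds=folds)


def cv_anova(cv: CvResult, n_components: int) -> tuple[float, float]:
    """CV-ANOVA F test of model significance from cross-validated residuals.

    Compares the variation explained by the cross-validated predictions
    (SS - PRESS, model df = number of fitted components C) against the
    residual PRESS (df = n - C - 1). Returns (F, p). A model predicting
    worse than the mean (PRESS >= SS) gives F <= 0 and p = 1.
    """
    df1 = n_components
    df2 = cv.n - n_components - 1
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degenerate degrees of freedom: df1={df1}, df2={df2}")
    F = ((cv.ss - cv.press) / df1) / (cv.press / df2)
    p = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return float(F), p


# ---------------------------------------------------------------------------
# per-variable statistics
# ---------------------------------------------------------------------------

def compute_vip(model: OplsModel) -> pd.Series:
    """Variable importance in projection over the predictive component.

    VIP_j = sqrt(J * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a) with the
    sum running over the predictive component only (a single component
    here, so VIP_j = sqrt(J) |w_j| for the unit-norm weight vector);
    mean(VIP^2) over the J variables is exactly 1.
    """
    w = model.w.to_numpy()
    J = len(w)
    vip = np.sqrt(J) * np.abs(w) / np.linalg.norm(w)
    return pd.Series(vip, index=model.w.index, name="vip")


def compute_pcorr(model: OplsModel, X) -> pd.Series:
    """Pearson correlation of each variable with the predictive score t.

    With the model's fixed sign convention (q >= 0), a positive p(corr)
    means the variable is elevated in the positive (treated) class.
    Zero-variance columns have no defined correlation and come back NaN.
    """
    Xf = _as_frame(X)
    arr = Xf.to_numpy(dtype=float)
    t = model.t.reindex(Xf.index).to_numpy()
    tc = t - t.mean()
    xc = arr - arr.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ tc) / (sx * st)
    r[sx == 0] = np.nan
    return pd.Series(r, index=Xf.columns, name="pcorr")


def variable_stats(model: OplsModel, X) -> pd.DataFrame:
    """VIP and p(corr) side by side, indexed by variable."""
    return pd.concat([compute_vip(model), compute_pcorr(model, X)], axis=1)
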