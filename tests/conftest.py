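import warnings

import numpy as np
import pandas as pd
import pytest

from ionopls.ions import IonPeakTable
from ionopls.synthetic import generate_design, generate_peak_table

warnings.filterwarnings("ignore", message="dropping constant")


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def table_truth(design):
    """One default synthetic dataset shared across read-only tests."""
    return generate_peak_table(design, seed=11)


def make_ion_table(intensities: dict, n_blanks: int = 0, analyte_of=None, identified=()):
    """Small hand-built ion table: intensities maps ion id -> list of values."""
    df = pd.DataFrame(intensities)
    n = len(df)
    sample_ids = [f"s{i}" for i in range(n - n_blanks)] + [f"b{i}" for i in range(n_blanks)]
    df.index = sample_ids
    analyte_of = analyte_of or {ion: ion.split(":")[0] for ion in df.columns}
    ion_meta = pd.DataFrame(
        {
            "analyte": [analyte_of[i] for i in df.columns],
            "mz": range(100, 100 + len(df.columns)),
            "rt": 10.0,
        },
        index=pd.Index(df.columns, name="ion_id"),
    )
    analytes = sorted(set(analyte_of.values()))
    analyte_meta = pd.DataFrame(
        {
            "metabolite": analytes,
            "identified": [a in identified for a in analytes],
            "rt": 10.0,
        },
        index=pd.Index(analytes, name="analyte"),
    )
    sample_meta = pd.DataFrame(
        {
            "carbon_source": "c1",
            "treatment": "control",
            "sample_type": "cells",
            "replicate": range(1, n + 1),
            "is_blank": [False] * (n - n_blanks) + [True] * n_blanks,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return IonPeakTable(df, ion_meta, sample_meta, analyte_meta)


def pls1_nipals(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 500):
    """Independent single-response PLS oracle (NIPALS iteration).

    Returns (w, t, q) of the first latent component for centered X, y.
    """
    u = y.copy()
    w = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w_new = X.T @ u
        w_new /= np.linalg.norm(w_new)
        t = X @ w_new
        q = float(y @ t / (t @ t))
        u_new = y * q
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w, u = w_new, u_new
    t = X @ w
    q = float(y @ t / (t @ t))
    return w, t, q
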