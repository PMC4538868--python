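"""Noise thresholding, PQN, autoscaling and Hotelling-T2 trimming."""

import numpy as np
import pandas as pd
import pytest

from ionopls.ions import MetaboliteTable
from ionopls.pipeline import PipelineConfig, run_pipeline
from ionopls.preprocess import (
    log_autoscale,
    noise_threshold,
    pqn_normalize,
    trim_outliers,
)
from ionopls.synthetic import generate_peak_table


def make_metabolite_table(values, n_blanks=0, meta_cols=None):
    df = pd.DataFrame(values, dtype=float)
    n = len(df)
    ids = [f"s{i}" for i in range(n - n_blanks)] + [f"b{i}" for i in range(n_blanks)]
    df.index = ids
    meta = pd.DataFrame(
        meta_cols
        or {
            "carbon_source": "c1",
            "treatment": "control",
            "sample_type": "cells",
            "replicate": range(1, n + 1),
        },
        index=df.index,
    )
    meta["is_blank"] = [False] * (n - n_blanks) + [True] * n_blanks
    return MetaboliteTable(df, meta, pd.Series(True, index=df.columns))


class TestNoiseThreshold:
    def test_values_below_blank_mean_zeroed_ties_retained(self):
        mt = make_metabolite_table({"m1": [5.0, 10.0, 19.0, 10.0, 30.0]}, n_blanks=2)
        out = noise_threshold(mt)  # blank mean = 20
        assert list(out.abundances["m1"]) == [0.0, 0.0, 0.0]
        mt2 = make_metabolite_table({"m1": [20.0, 25.0, 15.0, 20.0, 20.0]}, n_blanks=2)
        out2 = noise_threshold(mt2)
        assert list(out2.abundances["m1"]) == [20.0, 25.0, 0.0]  # tie kept

    def test_zero_blanks_leave_table_unchanged(self):
        mt = make_metabolite_table({"m1": [1.0, 2.0, 0.0, 0.0]}, n_blanks=2)
        out = noise_threshold(mt)
        assert list(out.abundances["m1"]) == [1.0, 2.0]

    def test_requires_blanks(self):
        mt = make_metabolite_table({"m1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="blank"):
            noise_threshold(mt)

    def test_output_zeros_superset_of_input_zeros(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, size=(8, 5))
        vals[rng.random(vals.shape) < 0.2] = 0.0
        mt = make_metabolite_table(
            {f"m{j}": vals[:, j] for j in range(5)}, n_blanks=3
        )
        out = noise_threshold(mt)
        inp = mt.abundances.loc[out.abundances.index]
        assert ((out.abundances <= inp) | inp.isna()).all().all()
        assert (out.abundances.to_numpy()[inp.to_numpy() == 0] == 0).all()


class TestPqn:
    def test_scalar_multiple_recovered_exactly(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        mt = make_metabolite_table(
            {f"m{j}": [ref[j], 2 * ref[j], 0.5 * ref[j]] for j in range(4)}
        )
        res = pqn_normalize(mt, reference_rule="median")
        np.testing.assert_allclose(res.quotient_factors, [1.0, 2.0, 0.5])
        np.testing.assert_allclose(res.normalized.abundances, np.tile(ref, (3, 1)))

    def test_median_quotient_robust_to_inflated_minority(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(10, 100, 50)
        sample = ref.copy()
        sample[:5] *= 10  # 10% of metabolites inflated tenfold
        mt = make_metabolite_table({f"m{j}": [ref[j], sample[j]] for j in range(50)})
        res = pqn_normalize(mt, reference_rule="median")
        # oracle: direct median of the quotient list against the median spectrum
        refspec = np.median(np.vstack([ref, sample]), axis=0)
        expected = np.median(sample / refspec)
        assert res.quotient_factors.iloc[1] == pytest.approx(expected)
        assert abs(res.quotient_factors.iloc[1] - 1.0) < 0.1

    def test_scale_equivariance_exact(self):
        """With a fixed (control-derived) reference, scaling a treated sample
        by c scales its factor by c and leaves the output unchanged."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 100, size=(4, 20))

        def build(v):
            mt = make_metabolite_table({f"m{j}": v[:, j] for j in range(20)})
            mt.sample_meta["treatment"] = ["control", "control", "trt", "trt"]
            return mt

        base = pqn_normalize(build(vals), reference_rule="control")
        scaled_vals = vals.copy()
        scaled_vals[3] *= 7.0
        res = pqn_normalize(build(scaled_vals), reference_rule="control")
        assert res.quotient_factors.iloc[3] == pytest.approx(
            7 * base.quotient_factors.iloc[3], rel=1e-12
        )
        np.testing.assert_allclose(
            res.normalized.abundances.iloc[3], base.normalized.abundances.iloc[3]
        )

    def test_disjoint_sample_raises_with_name(self):
        mt = make_metabolite_table(
            {"m1": [1.0, 1.0, 0.0], "m2": [2.0, 3.0, 0.0], "m3": [0.0, 0.0, 5.0]}
        )
        # median reference is positive only for m1, m2; s2 has neither
        with pytest.raises(ValueError, match="s2"):
            pqn_normalize(mt, reference_rule="median")

    def test_recovers_simulated_dilution_factors(self, design):
        """Median scale-free relative error below 5% at study defaults."""
        errs = []
        for seed in range(5):
            table, truth = generate_peak_table(design, seed=seed)
            sums = table.intensities.T.groupby(table.ion_meta["analyte"]).sum().T
            mt = MetaboliteTable(sums, table.sample_meta,
                                 pd.Series(True, index=sums.columns))
            mt = noise_threshold(mt)
            res = pqn_normalize(mt, reference_rule="stratified_control")
            truth_d = pd.Series(truth.dilution).reindex(res.quotient_factors.index)
            ratio = res.quotient_factors / truth_d
            meta = mt.sample_meta
            for _, sids in meta.groupby(["carbon_source", "sample_type"]).groups.items():
                r = ratio.loc[sids]
                errs.extend(np.abs(r / r.median() - 1.0))
        assert np.median(errs) < 0.05, f"median rel. error {np.median(errs):.3%}"


class TestLogAutoscale:
    def test_columns_centered_and_unit_variance(self):
        rng = np.random.default_rng(4)
        mt = make_metabolite_table({f"m{j}": rng.uniform(1, 50, 9) for j in range(6)})
        sm = log_autoscale(mt)
        np.testing.assert_allclose(sm.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(sm.values.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_two_samples_give_symmetric_unit_scores(self):
        mt = make_metabolite_table({"m1": [2.0, 8.0], "m2": [5.0, 1.0]})
        sm = log_autoscale(mt)
        # two centered points sit at +-d/2 with sample SD d/sqrt(2)
        np.testing.assert_allclose(np.abs(sm.values), np.sqrt(0.5), atol=1e-12)
        np.testing.assert_allclose(sm.values.sum(axis=0), 0, atol=1e-12)

    def test_rank_order_preserved_within_columns(self):
        rng = np.random.default_rng(5)
        mt = make_metabolite_table({f"m{j}": rng.uniform(0, 50, 7) for j in range(4)})
        sm = log_autoscale(mt)
        for c in mt.abundances.columns:
            assert (
                mt.abundances[c].rank() == sm.values[c].rank()
            ).all()

    def test_all_zero_metabolite_dropped_with_warning(self):
        mt = make_metabolite_table({"m1": [1.0, 2.0, 3.0], "dead": [0.0, 0.0, 0.0]})
        with pytest.warns(UserWarning, match="dead"):
            sm = log_autoscale(mt)
        assert list(sm.values.columns) == ["m1"]
        assert sm.log_offset == pytest.approx(0.5)  # half the smallest nonzero


class TestTrimOutliers:
    def _scaled(self, arr, labels):
        df = pd.DataFrame(np.asarray(arr, float),
                          index=[f"s{i}" for i in range(len(arr))])
        mt = make_metabolite_table({j: df[j] for j in df.columns})
        return log_autoscale(pd.DataFrame(np.exp(df))), pd.Series(labels, index=df.index)

    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 8))
        X[0] += 10 * np.array([1] + [0] * 7)  # 10 SD along one axis
        sm, labels = self._scaled(X, ["a"] * 10)
        res = trim_outliers(sm, labels, alpha=0.05)
        assert "s0" in res.flagged

    def test_tiny_alpha_flags_nothing(self):
        rng = np.random.default_rng(7)
        sm, labels = self._scaled(rng.normal(size=(12, 6)), ["a"] * 12)
        res = trim_outliers(sm, labels, alpha=1e-9)
        assert len(res.flagged) == 0

    def test_null_flag_rate_near_alpha(self):
        """Homogeneous Gaussian classes are flagged at ~alpha on average."""
        flags = total = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            sm, labels = self._scaled(rng.normal(size=(20, 10)), ["a"] * 20)
            res = trim_outliers(sm, labels, alpha=0.05)
            flags += len(res.flagged)
            total += 20
        rate = flags / total
        assert 0.02 < rate < 0.10, f"null flag rate {rate:.3f}"

    def test_small_class_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        sm, labels = self._scaled(rng.normal(size=(5, 4)), ["a", "a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="'b'"):
            res = trim_outliers(sm, labels)
        assert set(res.report["class"]) == {"a"}


class TestPipelineOrderSanity:
    def test_normalization_preserves_top_carbon_source_split(self, design):
        """Clustering of raw-log and normalized+scaled data agree on the top split."""
        from scipy.cluster.hierarchy import fcluster

        from ionopls.multivariate import hierarchical_cluster
        from ionopls.ions import merge_derivatives, remove_artifacts, validate_ions

        table, _ = generate_peak_table(design, seed=21)
        mt = merge_derivatives(validate_ions(remove_artifacts(table, 1e3)[0]))
        mt = noise_threshold(mt)
        raw_log = log_autoscale(
            pd.DataFrame(np.log(mt.abundances.to_numpy() + 1.0),
                         index=mt.abundances.index, columns=mt.abundances.columns)
        )
        norm = pqn_normalize(mt)
        scaled = log_autoscale(norm.normalized)
        carbon = mt.sample_meta["carbon_source"]
        for sm in (raw_log, scaled):
            Z, _ = hierarchical_cluster(sm)
            two = fcluster(Z, 2, criterion="maxclust")
            split = pd.Series(two, index=sm.values.index)
            # each cluster is pure in carbon source
            purity = split.groupby(carbon).nunique()
            assert (purity == 1).all()
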