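"""QC filters, NIPALS imputation and scaling."""

import numpy as np
import pandas as pd
import pytest

import metabosurr as ms
from metabosurr.dataset import CohortDataset
from metabosurr.panel import MetabolitePanel
from metabosurr.qc import apply_scaling, impute_nipals, zscale


def _toy_dataset(X, markers=None):
    X = np.asarray(X, dtype=float)
    markers = markers or [f"m{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=markers)
    df.insert(0, "sample_id", [f"s{i}" for i in range(len(X))])
    df.insert(1, "cohort", "c1")
    return CohortDataset(df=df, metabolite_cols=markers)


def _tiny_panel(n=5, exclusions=()):
    classes = {f"m{j}": "amino acids" for j in range(n)}
    return MetabolitePanel(classes, tuple(exclusions))


class TestSelectPanel:
    def test_exclusion_drops_in_panel_order(self):
        ds = _toy_dataset(np.ones((3, 5)))
        panel = _tiny_panel(5, exclusions=["m2"])
        out = ms.select_panel(ds, panel)
        assert out.metabolite_cols == ["m0", "m1", "m3", "m4"]

    def test_empty_exclusions_identity(self):
        ds = _toy_dataset(np.ones((3, 5)))
        out = ms.select_panel(ds, _tiny_panel(5))
        assert out.metabolite_cols == ds.metabolite_cols

    def test_missing_marker_error_names_it(self):
        ds = _toy_dataset(np.ones((3, 4)))
        with pytest.raises(KeyError, match="m4"):
            ms.select_panel(ds, _tiny_panel(5))


class TestFilterSamples:
    def _violating_toy(self):
        """30 clean samples + one missing + one zero + one far outlier.

        The rule-enumeration oracle: sample 30 violates the missing rule,
        31 the zero rule, and 32 sits far above the column-0 mean/SD
        computed on the survivors of the first two rules.
        """
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(10, 1, size=(30, 3)),
                       [np.nan, 10, 10],
                       [10, 0.0, 10],
                       [40.0, 10, 10]])
        return _toy_dataset(X)

    def test_rule_enumeration_toy(self):
        ds = self._violating_toy()
        kept, rep = ms.filter_samples(ds)
        assert (rep.n_removed_missing, rep.n_removed_zero,
                rep.n_removed_outlier) == (1, 1, 1)
        assert rep.n_kept == 30
        assert rep.removed_missing_ids == ["s30"]
        assert rep.removed_zero_ids == ["s31"]
        assert rep.removed_outlier_ids == ["s32"]

    def test_no_violations_identity(self):
        rng = np.random.default_rng(2)
        ds = _toy_dataset(rng.normal(5, 1, size=(20, 4)))
        kept, rep = ms.filter_samples(ds)
        assert rep.n_kept == 20
        assert (rep.n_removed_missing, rep.n_removed_zero,
                rep.n_removed_outlier) == (0, 0, 0)
        pd.testing.assert_frame_equal(kept.df, ds.df)

    def test_constant_column_never_flags_outliers(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        kept, rep = ms.filter_samples(_toy_dataset(X))
        assert rep.n_removed_outlier == 0

    def test_first_violated_rule_wins(self):
        # a sample with both a missing cell and a zero counts as missing
        X = np.ones((12, 2)) * 5
        X[0, 0] = np.nan
        X[0, 1] = 0.0
        _, rep = ms.filter_samples(_toy_dataset(X))
        assert rep.n_removed_missing == 1
        assert rep.n_removed_zero == 0

    def test_idempotence(self):
        ds = self._violating_toy()
        kept, _ = ms.filter_samples(ds)
        again, rep2 = ms.filter_samples(kept)
        assert rep2.n_kept == kept.n_samples
        assert (rep2.n_removed_missing, rep2.n_removed_zero,
                rep2.n_removed_outlier) == (0, 0, 0)

    def test_count_conservation(self, demo_small):
        cfg, ds, _ = demo_small
        corrupted, _ = ms.inject_artifacts(ds, 0.0005, 0.0005, 0.0005, seed=9)
        _, rep = ms.filter_samples(corrupted)
        assert rep.n_kept + rep.n_removed_missing + rep.n_removed_zero \
            + rep.n_removed_outlier == rep.n_input == corrupted.n_samples

    def test_all_removed_signals(self):
        X = np.full((3, 2), np.nan)
        X[:, 1] = 1.0
        with pytest.raises(ValueError, match="all samples removed"):
            ms.filter_samples(_toy_dataset(X))

    def test_removed_sets_match_injection_mask(self, demo_small):
        """Cross-module oracle: QC removes exactly the samples that carry
        injected missing/zero cells, and the far-outlier samples."""
        _, ds, _ = demo_small
        corrupted, mask = ms.inject_artifacts(ds, 0.001, 0.001, 0.001,
                                              seed=11)
        _, rep = ms.filter_samples(corrupted)
        ids = corrupted.df["sample_id"]
        assert set(rep.removed_missing_ids) == \
            set(ids.iloc[sorted(mask.samples("missing"))])
        assert set(rep.removed_zero_ids) == \
            set(ids.iloc[sorted(mask.samples("zero"))])
        injected_out = set(ids.iloc[sorted(mask.samples("outlier"))])
        captured = injected_out & set(rep.removed_outlier_ids)
        assert len(captured) >= 0.95 * len(injected_out)


class TestNipals:
    def test_rank_one_cell_recovered(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5])
        v = np.array([0.5, -1.0, 2.0, 1.5])
        X = np.outer(u, v)
        Xm = X.copy()
        Xm[2, 1] = np.nan
        out, n_imp = impute_nipals(Xm, n_components=1,
                                   max_missing_fraction=0.1)
        assert n_imp == 1
        assert out[2, 1] == pytest.approx(X[2, 1], abs=1e-6)

    def test_no_missing_identity(self):
        X = np.random.default_rng(3).normal(size=(10, 4))
        out, n_imp = impute_nipals(X)
        assert n_imp == 0
        np.testing.assert_array_equal(out, X)

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 8))
        Xm = X.copy()
        holes = [(i, i % 8) for i in range(0, 60, 13)]
        for r, c in holes:
            Xm[r, c] = np.nan
        out, _ = impute_nipals(Xm, n_components=5)
        obs = ~np.isnan(Xm)
        np.testing.assert_array_equal(out[obs], X[obs])

    def test_entirely_missing_column_raises(self):
        X = np.random.default_rng(5).normal(size=(10, 3))
        X[:, 1] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_nipals(X, max_missing_fraction=0.5)

    def test_missing_fraction_ceiling(self):
        X = np.random.default_rng(6).normal(size=(4, 4))
        X[0, :2] = np.nan
        with pytest.raises(ValueError, match="ceiling"):
            impute_nipals(X, max_missing_fraction=0.01)


class TestZscale:
    def test_basic_example(self):
        scaled, mu, sd = zscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled[:, 0], [-1.0, 0.0, 1.0])
        assert mu[0] == 2.0 and sd[0] == 1.0  # n-1 convention

    def test_columns_standardized(self):
        X = np.random.default_rng(7).normal(3, 5, size=(50, 6))
        scaled, _, _ = zscale(X)
        np.testing.assert_allclose(scaled.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_already_standardized_unchanged(self):
        X = np.random.default_rng(8).normal(size=(200, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        scaled, _, _ = zscale(X)
        np.testing.assert_allclose(scaled, X, atol=1e-10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            zscale(np.ones((5, 2)))

    def test_stored_parameters_project_mean_to_zero(self):
        X = np.random.default_rng(9).normal(size=(30, 4))
        _, mu, sd = zscale(X)
        np.testing.assert_allclose(apply_scaling(X.mean(0), mu, sd), 0,
                                   atol=1e-12)


def test_run_qc_end_to_end(demo_small):
    cfg, ds, _ = demo_small
    kept, rep = ms.run_qc(ds, cfg.panel)
    X = kept.metabolite_matrix()
    assert not np.isnan(X).any()
    np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-10)
    assert list(rep.scaling_mean) == kept.metabolite_cols
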