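"""Generator contracts: determinism, liability calibration, artifact masks,
and planted survival."""

import numpy as np
import pandas as pd
import pytest

import metabosurr as ms
from metabosurr.simulate import (GenerativeConfig, PlantedPhenotype,
                                 oracle_auc_from_separation,
                                 separation_from_auc, log_uniform_sizes)


def _one_pheno_config(seed=0, n=2000, d=1.0, prevalence=0.3, **kw):
    spec = PlantedPhenotype("p", prevalence, {}, d)
    return GenerativeConfig(cohort_sizes=[n], phenotype_specs=[spec],
                            seed=seed, **kw)


class TestConfigValidation:
    def test_rejects_nonpositive_cohort_sizes(self):
        with pytest.raises(ValueError):
            GenerativeConfig(cohort_sizes=[100, 0])

    @pytest.mark.parametrize("rate_kw", ["missing_rate", "zero_rate",
                                         "outlier_rate"])
    def test_rejects_out_of_range_rates(self, rate_kw):
        with pytest.raises(ValueError):
            GenerativeConfig(cohort_sizes=[10], **{rate_kw: 1.5})

    @pytest.mark.parametrize("prev", [0.0, 1.0, -0.1])
    def test_rejects_degenerate_prevalence(self, prev):
        with pytest.raises(ValueError):
            PlantedPhenotype("p", prev, {}, 1.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tmp_path):
        cfg = ms.demo_config(seed=5, n_cohorts=3, cohort_size=60,
                             missing_rate=0.002, zero_rate=0.001,
                             outlier_rate=0.001)
        ds1, t1 = ms.generate_dataset(cfg)
        ds2, t2 = ms.generate_dataset(cfg)
        pd.testing.assert_frame_equal(ds1.df, ds2.df)
        ds1.to_tsv(tmp_path / "a.tsv")
        ds2.to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == \
            (tmp_path / "b.tsv").read_bytes()
        t1.to_json(tmp_path / "a.json")
        t2.to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == \
            (tmp_path / "b.json").read_bytes()

    def test_different_seed_differs(self):
        ds1, _ = ms.generate_dataset(_one_pheno_config(seed=1, n=50))
        ds2, _ = ms.generate_dataset(_one_pheno_config(seed=2, n=50))
        assert not np.allclose(ds1.metabolite_matrix(),
                               ds2.metabolite_matrix())


class TestLiabilityModel:
    def test_zero_separation_gives_oracle_half(self):
        _, truth = ms.generate_dataset(_one_pheno_config(d=0.0, n=100))
        assert truth.oracle_auc("p") == 0.5

    def test_oracle_auc_closed_form_roundtrip(self):
        for auc in (0.6, 0.75, 0.9, 0.95):
            assert oracle_auc_from_separation(separation_from_auc(auc)) \
                == pytest.approx(auc)

    def test_liability_auc_matches_binormal_closed_form(self):
        # d = 1.81 -> Phi(1.81/sqrt(2)) ~ 0.90; Monte-Carlo at n = 10,000
        cfg = _one_pheno_config(seed=0, n=10_000, d=1.81)
        _, truth = ms.generate_dataset(cfg)
        emp = ms.auc(truth.liability("p"), truth.labels("p"))
        assert emp == pytest.approx(oracle_auc_from_separation(1.81),
                                    abs=0.01)

    def test_prevalence_within_monte_carlo_error(self):
        cfg = _one_pheno_config(seed=3, n=8000, d=1.0, prevalence=0.2)
        _, truth = ms.generate_dataset(cfg)
        p = truth.phenotypes["p"]["realized_prevalence"]
        assert abs(p - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 8000)

    def test_concentrations_positive(self, demo_small):
        _, ds, _ = demo_small
        assert (ds.metabolite_matrix() > 0).all()

    def test_sex_linked_prevalence_differs_by_sex(self):
        spec = PlantedPhenotype("p", 0.3, {}, 1.0, sex_linked=True)
        cfg = GenerativeConfig(cohort_sizes=[8000], phenotype_specs=[spec],
                               seed=4)
        ds, _ = ms.generate_dataset(cfg)
        male = ds.df["sex"] == 1
        assert ds.df.loc[male, "p"].mean() > ds.df.loc[~male, "p"].mean()


class TestInjectArtifacts:
    def test_zero_rates_identity(self, demo_small):
        _, ds, _ = demo_small
        out, mask = ms.inject_artifacts(ds, 0.0, 0.0, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.df, ds.df)
        assert not mask.missing_cells and not mask.zero_cells

    def test_mask_is_exact(self, demo_small):
        _, ds, _ = demo_small
        out, mask = ms.inject_artifacts(ds, 0.001, 0.001, 0.001, seed=2)
        X0 = ds.metabolite_matrix()
        X1 = out.metabolite_matrix()
        changed = {(int(r), int(c))
                   for r, c in zip(*np.where(~np.isclose(X0, X1) |
                                             np.isnan(X1)))}
        flagged = {tuple(c) for c in (mask.missing_cells + mask.zero_cells
                                      + mask.outlier_cells)}
        assert changed == flagged
        for r, c in mask.missing_cells:
            assert np.isnan(X1[r, c])
        for r, c in mask.zero_cells:
            assert X1[r, c] == 0.0

    def test_outliers_exceed_five_sd_of_leave_one_out_mean(self, demo_small):
        _, ds, _ = demo_small
        out, mask = ms.inject_artifacts(ds, 0.0, 0.0, 0.002, seed=3)
        X = out.metabolite_matrix()
        for r, c in mask.outlier_cells:
            col = np.delete(X[:, c], r)
            assert abs(X[r, c] - col.mean()) > 5 * col.std(ddof=1)

    def test_rate_out_of_range_raises(self, demo_small):
        _, ds, _ = demo_small
        with pytest.raises(ValueError):
            ms.inject_artifacts(ds, -0.1, 0, 0, seed=1)


class TestPlantSurvival:
    def test_hr_two_recovered_without_frailty(self, panel):
        cfg = GenerativeConfig(
            cohort_sizes=[2000], panel=panel, seed=77,
            phenotype_specs=[PlantedPhenotype("x", 0.3, {}, 1.0)])
        ds, _ = ms.generate_dataset(cfg)
        ds = ms.plant_survival(ds, {"x": np.log(2)}, censor_rate=0.2,
                               n_families=300, seed=7, frailty_variance=0.0)
        a = ms.cox_association(ds.df, "x", per_sd=False)
        assert 1.7 <= a.hazard_ratio <= 2.3

    def test_full_censoring_gives_zero_events_and_degenerate_fit(self, panel):
        cfg = _one_pheno_config(seed=9, n=200)
        ds, _ = ms.generate_dataset(cfg)
        ds = ms.plant_survival(ds, {"p": 0.0}, censor_rate=1.0,
                               n_families=20, seed=1)
        assert ds.df["event"].sum() == 0
        assert (ds.df["time"] > 0).all()
        with pytest.raises(ValueError, match="zero events"):
            ms.cox_association(ds.df, "p")

    def test_negative_censor_rate_rejected(self, demo_small):
        _, ds, _ = demo_small
        with pytest.raises(ValueError):
            ms.plant_survival(ds, {}, censor_rate=-0.5, n_families=5, seed=0)

    def test_unknown_covariate_rejected(self, demo_small):
        _, ds, _ = demo_small
        with pytest.raises(KeyError):
            ms.plant_survival(ds, {"nope": 1.0}, censor_rate=0.2,
                              n_families=5, seed=0)

    def test_censor_fraction_near_target(self, panel):
        cfg = _one_pheno_config(seed=10, n=3000)
        ds, _ = ms.generate_dataset(cfg)
        ds = ms.plant_survival(ds, {"p": 0.5}, censor_rate=0.3,
                               n_families=200, seed=2)
        assert 1 - ds.df["event"].mean() == pytest.approx(0.3, abs=0.02)


def test_log_uniform_sizes_sum_and_floor():
    sizes = log_uniform_sizes(28, 26_000, np.random.default_rng(0))
    assert sum(sizes) == 26_000
    assert min(sizes) >= 2
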