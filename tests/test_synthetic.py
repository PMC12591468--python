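"""Synthetic cohort generator and its independent error oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from cytocomm import (
    AnalysisSettings,
    Cohort,
    HypothesisModelSet,
    SyntheticConfig,
    adjusted_true_means,
    closed_form_pe_binary,
    default_true_models,
    fit_gm2,
    generate_cohorts,
    generate_sample_dataset,
    offsets_for_samples,
    oracle_bayes_error,
    run_sample_analysis,
    sample_gm,
    transform_sample,
)
from cytocomm.errors import DomainError

from conftest import univariate_model


class TestSampleGm:
    def test_deterministic_under_seed(self):
        m = univariate_model(1.0, 2.0, rho=0.4, mean2=5.0)
        np.testing.assert_array_equal(sample_gm(m, 500, seed=9),
                                      sample_gm(m, 500, seed=9))
        assert not np.array_equal(sample_gm(m, 500, seed=9),
                                  sample_gm(m, 500, seed=10))

    def test_moment_oracle(self):
        rho, m1, m2 = 0.3, -2.0, 4.0
        m = univariate_model(m1, 1.0, rho=rho, mean2=m2, var2=1.0)
        n = 100000
        X = sample_gm(m, n, seed=1)
        mix_mean = rho * m1 + (1 - rho) * m2
        mix_var = rho * (1 + m1**2) + (1 - rho) * (1 + m2**2) - mix_mean**2
        assert X.mean() == pytest.approx(mix_mean, abs=3 * np.sqrt(mix_var / n))

    def test_component_label_fraction(self):
        rho = 0.3
        m = univariate_model(0.0, 0.01, rho=rho, mean2=10.0, var2=0.01)
        n = 100000
        X = sample_gm(m, n, seed=2)
        frac = np.mean(X[:, 0] < 5.0)
        assert frac == pytest.approx(rho, abs=3 * np.sqrt(rho * (1 - rho) / n))


class TestGenerate:
    def test_sample_dataset_structure(self):
        cfg = SyntheticConfig(n_subjects=(1, 1), cells_per_treatment=64, seed=5)
        sample, truth = generate_sample_dataset(cfg, "S0", Cohort.HD)
        assert sample.M == 6
        assert len(truth) == 6
        assert all(rm.n_cells == 64 for rm in sample.responses.values())
        assert all(np.all(rm.values > 0) for rm in sample.responses.values())

    def test_cells_drawn_from_range(self):
        cfg = SyntheticConfig(n_subjects=(1, 1), cells_per_treatment=(100, 200),
                              seed=5)
        sample, _ = generate_sample_dataset(cfg, "S0", "HD")
        counts = [rm.n_cells for rm in sample.responses.values()]
        assert all(100 <= n <= 200 for n in counts)
        assert len(set(counts)) > 1

    def test_cohorts_have_distinct_reproducible_subjects(self):
        cfg = SyntheticConfig(n_subjects=(5, 5), cells_per_treatment=50, seed=3)
        ds, truths = generate_cohorts(cfg)
        assert len(ds) == 10
        assert sum(s.cohort is Cohort.HD for s in ds) == 5
        assert len(truths) == 10
        a, b = ds.samples[0], ds.samples[1]
        assert not np.array_equal(a.responses[0].values, b.responses[0].values)
        ds2, _ = generate_cohorts(cfg)
        np.testing.assert_array_equal(ds.samples[3].responses[2].values,
                                      ds2.samples[3].responses[2].values)

    def test_pipeline_recovers_true_means(self):
        """preprocess + EM on raw-scale output recovers the (shift-adjusted)
        transformed-space component means."""
        cfg = SyntheticConfig(n_subjects=(1, 0), cells_per_treatment=5000, seed=21)
        sample, truth = generate_sample_dataset(cfg, "S0", "HD")
        offsets = offsets_for_samples([sample])
        transformed = transform_sample(sample, offsets)
        for i in (0, 5):
            fit = fit_gm2(transformed[i], seed=i, n_init=2)
            adj1, adj2 = adjusted_true_means(truth[i], offsets.alpha,
                                             cfg.raw_offset)
            n1 = truth[i].rho * 5000
            tol1 = 3 * np.sqrt(np.trace(truth[i].comp1.cov) / n1)
            tol2 = 3 * np.sqrt(np.trace(truth[i].comp2.cov) / (5000 - n1))
            assert np.linalg.norm(fit.comp1.mean - adj1) < tol1
            assert np.linalg.norm(fit.comp2.mean - adj2) < tol2

    def test_noise_inflation_reduces_fitted_snr(self):
        base = SyntheticConfig(n_subjects=(1, 1), cells_per_treatment=800,
                               seed=13, f_bc=3.0, s_bc=1.0)
        sample_hd, _ = generate_sample_dataset(base, "S0", "HD", seed=77)
        sample_bc, _ = generate_sample_dataset(base, "S0", "BC", seed=77)
        settings = AnalysisSettings(seed=1, n_init=2, include_pairwise=False)
        r_hd = run_sample_analysis(sample_hd, offsets_for_samples([sample_hd]),
                                   settings)
        r_bc = run_sample_analysis(sample_bc, offsets_for_samples([sample_bc]),
                                   settings)
        assert r_bc.snr.snr_linear < r_hd.snr.snr_linear


class TestOracles:
    def test_identical_hypotheses_error_at_chance(self):
        m = univariate_model(0.0, 1.0, rho=0.5, mean2=2.0)
        pe, se = oracle_bayes_error([m] * 4, n_mc=20000, seed=0)
        # identical densities tie; ties resolve to the first hypothesis, so
        # exactly the other three quarters of draws are errors
        assert pe == pytest.approx(0.75, abs=max(3 * se, 1e-6))

    def test_far_separation_error_vanishes(self):
        models = [univariate_model(0.0), univariate_model(50.0)]
        pe, _ = oracle_bayes_error(models, n_mc=10000, seed=1)
        assert pe == 0.0

    def test_binary_matches_closed_form(self):
        models = [univariate_model(0.0), univariate_model(2.0)]
        pe, se = oracle_bayes_error(models, n_mc=100000, seed=2)
        assert pe == pytest.approx(closed_form_pe_binary(2.0, 1.0),
                                   abs=3 * se)


class TestClosedForm:
    def test_values(self):
        assert closed_form_pe_binary(0.0, 1.0) == pytest.approx(0.5)
        assert closed_form_pe_binary(2.0, 1.0) == pytest.approx(
            float(norm.cdf(-1.0))
        )
        assert closed_form_pe_binary(50.0, 1.0) < 1e-10

    def test_domain(self):
        with pytest.raises(DomainError):
            closed_form_pe_binary(-1.0, 1.0)
        with pytest.raises(DomainError):
            closed_form_pe_binary(1.0, 0.0)


def test_default_models_follow_signature_pattern():
    models = default_true_models()
    assert len(models) == 6
    # IFN-gamma responder shifts pSTAT1 (channel 0); IL-2 shifts pSTAT5 (3)
    assert models[5].comp1.mean[0] > models[0].comp1.mean[0]
    assert models[2].comp1.mean[3] > models[0].comp1.mean[3]
    for m in models:
        np.linalg.cholesky(m.comp1.cov)
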