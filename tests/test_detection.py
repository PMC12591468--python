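"""Maximum-likelihood detection, confusion matrices and Pe estimation."""

import numpy as np
import pytest

from cytocomm import (
    ConfusionMatrix,
    HypothesisModelSet,
    closed_form_pe_binary,
    error_probability,
    estimate_confusion,
    fit_gm2,
    ml_classify,
    neglog_display,
    pairwise_error_matrix,
    sample_gm,
)
from cytocomm.errors import DomainError, EmptyInputError, UndefinedConditionalError

from conftest import random_model_set, univariate_model


def _binary_models(mu0=0.0, mu1=2.0, sigma2=1.0):
    return HypothesisModelSet(
        [univariate_model(mu0, sigma2, index=0), univariate_model(mu1, sigma2, index=1)]
    )


class TestMlClassify:
    def test_point_at_a_mean_with_far_separation(self):
        models = _binary_models(0.0, 10.0)
        assert ml_classify(np.array([0.0]), models) == 0
        assert ml_classify(np.array([10.0]), models) == 1

    def test_exact_tie_breaks_to_lowest_index(self):
        models = _binary_models(0.0, 10.0)
        assert ml_classify(np.array([5.0]), models) == 0

    def test_matches_naive_density_oracle(self, rng):
        """Decisions agree with brute-force densities evaluated without
        log-sum-exp or Cholesky tricks."""
        models = random_model_set(rng, M=4, K=2)
        X = rng.normal(0, 3, size=(100, 2))
        decided = ml_classify(X, models)

        def naive_pdf(x, mean, cov):
            k = len(mean)
            dev = x - mean
            return np.exp(-0.5 * dev @ np.linalg.inv(cov) @ dev) / np.sqrt(
                (2 * np.pi) ** k * np.linalg.det(cov)
            )

        for n, x in enumerate(X):
            dens = [
                m.rho * naive_pdf(x, m.comp1.mean, m.comp1.cov)
                + (1 - m.rho) * naive_pdf(x, m.comp2.mean, m.comp2.cov)
                for m in models.models
            ]
            assert decided[n] == int(np.argmax(dens))


class TestConfusion:
    def test_perfect_separation_gives_diagonal_counts(self):
        models = HypothesisModelSet(
            [univariate_model(50.0 * i, 1.0, index=i) for i in range(3)]
        )
        data = {i: sample_gm(models.models[i], 500, seed=i) for i in range(3)}
        cm = estimate_confusion(data, models)
        assert np.all(cm.counts == np.diag([500, 500, 500]))

    def test_column_sums_conserved(self, rng):
        models = random_model_set(rng, M=3, K=2)
        data = {i: sample_gm(models.models[i], 100 + 37 * i, seed=i)
                for i in range(3)}
        cm = estimate_confusion(data, models)
        np.testing.assert_array_equal(cm.n_per_hypothesis, [100, 137, 174])
        assert cm.N == 411

    def test_empty_hypothesis_rejected(self):
        models = _binary_models()
        with pytest.raises(EmptyInputError):
            estimate_confusion({0: np.zeros((0, 1)), 1: np.zeros((5, 1))}, models)

    def test_identical_distribution_with_fitted_models_is_near_uniform(self):
        """M independent samples of one distribution, each hypothesis fitted
        to its own draw: decisions are at chance in expectation.

        A single realization deviates from 1/M by model-fitting noise (all
        cells share the same fitted models, so decisions are correlated),
        which dominates per-cell binomial noise; the symmetry property is
        therefore tested on the mean over independent replicates, against
        the empirical between-replicate standard error.
        """
        M, n, R = 4, 1000, 15
        source = univariate_model(1.0, 1.0, rho=0.5, mean2=3.0)
        qs = []
        for r in range(R):
            data = {j: sample_gm(source, n, seed=1000 * r + j) for j in range(M)}
            fitted = HypothesisModelSet(
                [fit_gm2(data[j], seed=r * M + j, n_init=2, hypothesis_index=j)
                 for j in range(M)]
            )
            qs.append(estimate_confusion(data, fitted).counts / n)
        qs = np.asarray(qs)
        mean_q = qs.mean(axis=0)
        se = qs.std(axis=0, ddof=1) / np.sqrt(R)
        assert np.all(np.abs(mean_q - 1 / M) < 3 * se + 0.01)


class TestErrorProbability:
    def test_diagonal_counts_mean_zero_error(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]))
        summary = error_probability(cm)
        assert summary.pe == 0.0
        assert summary.pc == 1.0
        np.testing.assert_allclose(summary.conditional_q.sum(axis=0), 1.0)

    def test_zero_count_hypothesis_is_undefined(self):
        counts = np.array([[5, 0], [0, 0]])
        with pytest.raises(UndefinedConditionalError):
            error_probability(ConfusionMatrix(counts))

    def test_weightings_differ_only_for_unbalanced_counts(self):
        counts = np.array([[90, 30], [10, 270]])  # N_0=100, N_1=300
        cm = ConfusionMatrix(counts)
        eq = error_probability(cm, "equiprobable")
        emp = error_probability(cm, "empirical")
        assert eq.pe == pytest.approx(1 - 0.5 * (0.9 + 0.9))
        assert emp.pe == pytest.approx(1 - 360 / 400)
        balanced = ConfusionMatrix(np.array([[80, 20], [20, 80]]))
        assert error_probability(balanced, "equiprobable").pe == pytest.approx(
            error_probability(balanced, "empirical").pe
        )

    def test_binary_gaussian_matches_closed_form(self):
        """Means 0 and 2 at unit variance: Pe should approach Phi(-1)."""
        models = _binary_models(0.0, 2.0, 1.0)
        n = 20000
        data = {i: sample_gm(models.models[i], n, seed=10 + i) for i in range(2)}
        pe = error_probability(estimate_confusion(data, models)).pe
        assert pe == pytest.approx(closed_form_pe_binary(2.0, 1.0), abs=0.01)

    def test_error_non_increasing_in_separation(self):
        """Larger mean separation can only improve binary detection."""
        n = 8000
        pes = []
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            models = _binary_models(0.0, delta, 1.0)
            data = {i: sample_gm(models.models[i], n, seed=50 + i)
                    for i in range(2)}
            pes.append(error_probability(estimate_confusion(data, models)).pe)
        se = np.sqrt(0.25 / (2 * n))
        assert all(b <= a + se for a, b in zip(pes, pes[1:]))


class TestPairwise:
    def test_identical_pair_is_at_chance(self):
        m = univariate_model(0.0, 1.0, rho=0.5, mean2=1.0)
        models = HypothesisModelSet([m, m, univariate_model(30.0)])
        data = {0: sample_gm(m, 4000, seed=0), 1: sample_gm(m, 4000, seed=1),
                2: sample_gm(models.models[2], 4000, seed=2)}
        pw = pairwise_error_matrix(data, models)
        # ties between identical models all resolve to the lower index: the
        # pair splits 50/50 under equal weighting of the two truths
        assert pw[0, 1] == pytest.approx(0.5, abs=0.02)
        assert pw[0, 2] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(np.diag(pw), 0.0)
        np.testing.assert_allclose(pw, pw.T)

    def test_binary_closed_form_on_a_pair(self):
        models = HypothesisModelSet(
            [univariate_model(0.0), univariate_model(2.0), univariate_model(40.0)]
        )
        data = {i: sample_gm(models.models[i], 20000, seed=70 + i)
                for i in range(3)}
        pw = pairwise_error_matrix(data, models)
        assert pw[0, 1] == pytest.approx(closed_form_pe_binary(2.0, 1.0), abs=0.01)

    def test_renormalized_variant_agrees_for_well_separated_extremes(self):
        models = HypothesisModelSet(
            [univariate_model(0.0), univariate_model(2.0), univariate_model(40.0)]
        )
        data = {i: sample_gm(models.models[i], 5000, seed=90 + i)
                for i in range(3)}
        binary = pairwise_error_matrix(data, models, method="binary")
        renorm = pairwise_error_matrix(data, models, method="renormalize")
        # H2 is far from both others: the two estimators coincide there
        assert renorm[0, 2] == pytest.approx(binary[0, 2], abs=1e-9)
        assert renorm[0, 1] == pytest.approx(binary[0, 1], abs=0.02)


class TestNeglogDisplay:
    @pytest.mark.parametrize(
        "pe, base, expected",
        [
            (0.0, 10, 6.0),
            (0.01, 10, 2.0),
            (1.0, 10, 0.0),
            (0.0, "e", 6.0 * np.log(10.0)),
            (np.exp(-3.0), "e", 3.0),
        ],
    )
    def test_values(self, pe, base, expected):
        assert neglog_display(pe, base=base) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("pe", [-0.1, 1.0001, 2.0])
    def test_domain(self, pe):
        with pytest.raises(DomainError):
            neglog_display(pe)
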