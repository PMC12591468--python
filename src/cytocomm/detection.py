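"""Maximum-likelihood multi-hypothesis detection and error-probability estimation.

Each of the M stimulation conditions is a hypothesis H_i with a fitted
mixture density. A cell's response x is assigned to the hypothesis of
maximal likelihood (with equiprobable priors this is the Bayes-optimal
rule). Running every measured cell through the detector yields an M x M
confusion matrix, from which the overall probability of misidentifying
the ligand, Pe = 1 - sum_j P(H_j) Q_jj, is estimated. Evaluation is
resubstitution by default: models are fitted on the same cells they
classify, one deterministic pass, no resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, EmptyInputError, UndefinedConditionalError
from .gmm import GMParams, gm_log_density

#: Display value substituted for -log10(Pe) when Pe is exactly zero.
SENTINEL_NEGLOG10 = 6.0


@dataclass
class HypothesisModelSet:
    """Ordered per-hypothesis mixture models plus prior probabilities."""

    models: list[GMParams]
    priors: np.ndarray | None = None

    def __post_init__(self):
        self.models = list(self.models)
        M = len(self.models)
        if M < 2:
            raise ValueError("need at least two hypotheses")
        ks = {m.K for m in self.models}
        if len(ks) != 1:
            raise ValueError("all hypothesis models must share K")
        if self.priors is None:
            self.priors = np.full(M, 1.0 / M)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.priors.shape != (M,) or np.any(self.priors < 0):
            raise ValueError("priors must be a nonnegative length-M vector")
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1 within 1e-12")

    @property
    def M(self) -> int:
        return len(self.models)

    @property
    def K(self) -> int:
        return self.models[0].K

    def subset(self, indices: Sequence[int]) -> "HypothesisModelSet":
        """Restricted detection problem over a subset of hypotheses, equal priors."""
        return HypothesisModelSet([self.models[i] for i in indices])


def log_likelihood_matrix(X: np.ndarray, models: HypothesisModelSet) -> np.ndarray:
    """(N, M) matrix of per-cell mixture log-densities under each hypothesis."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([gm_log_density(X, m) for m in models.models])


def ml_classify(x: np.ndarray, models: HypothesisModelSet) -> int | np.ndarray:
    """Most likely hypothesis index for a vector (int) or each row (array).

    Log priors are added, so with the default uniform priors the decision
    is the pure maximum-likelihood rule. Exact ties resolve to the lowest
    hypothesis index (np.argmax convention).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    with np.errstate(divide="ignore"):
        scores = log_likelihood_matrix(x, models) + np.log(models.priors)
    decided = np.argmax(scores, axis=1)
    return int(decided[0]) if single else decided


@dataclass
class ConfusionMatrix:
    """Detection counts: entry (i, j) = cells of true hypothesis j decided as i."""

    counts: np.ndarray
    treatment_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def M(self) -> int:
        return self.counts.shape[0]

    @property
    def n_per_hypothesis(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def estimate_confusion(transformed_sample: Mapping[int, np.ndarray],
                       models: HypothesisModelSet,
                       treatment_labels: tuple[str, ...] | None = None,
                       ) -> ConfusionMatrix:
    """Classify every cell of every true hypothesis; accumulate counts.

    ``transformed_sample`` maps hypothesis index j to the (N_j, K) matrix of
    its log-transformed responses. One deterministic pass, no resampling.
    """
    M = models.M
    counts = np.zeros((M, M), dtype=int)
    for j in range(M):
        Xj = np.atleast_2d(np.asarray(transformed_sample[j], dtype=float))
        if Xj.shape[0] == 0:
            raise EmptyInputError(f"hypothesis {j} has no cells")
        decided = ml_classify(Xj, models)
        counts[:, j] = np.bincount(decided, minlength=M)
    return ConfusionMatrix(counts, treatment_labels)


@dataclass
class ErrorSummary:
    """Overall and conditional detection-error probabilities for one sample."""

    pe: float
    conditional_q: np.ndarray
    weighting: str
    pairwise_pe: np.ndarray | None = None

    @property
    def pc(self) -> float:
        return 1.0 - self.pe

    @property
    def neglog10_pe(self) -> float:
        return neglog_display(self.pe, base=10)


def error_probability(cm: ConfusionMatrix,
                      weighting: str = "equiprobable") -> ErrorSummary:
    """Pe and the conditional-probability confusion matrix from counts.

    conditional_q[i, j] = counts[i, j] / N_j estimates Q_ij = P(decide H_i |
    H_j true). Under ``equiprobable`` weighting (the default, matching equal
    priors P(H_j) = 1/M), Pe = 1 - (1/M) sum_j Q_jj; under ``empirical``
    weighting hypotheses are weighted by their observed cell counts,
    Pe = 1 - sum_j counts[j, j] / N. The two coincide for balanced counts.
    """
    if weighting not in ("equiprobable", "empirical"):
        raise ValueError(f"unknown weighting '{weighting}'")
    n_j = cm.n_per_hypothesis
    if np.any(n_j == 0):
        raise UndefinedConditionalError(
            f"hypotheses {np.flatnonzero(n_j == 0).tolist()} have zero cells"
        )
    q = cm.counts / n_j[np.newaxis, :]
    if weighting == "equiprobable":
        pe = 1.0 - float(np.mean(np.diag(q)))
    else:
        pe = 1.0 - float(np.trace(cm.counts)) / cm.N
    pe = min(max(pe, 0.0), 1.0)
    return ErrorSummary(pe=pe, conditional_q=q, weighting=weighting)


def pairwise_error_matrix(transformed_sample: Mapping[int, np.ndarray],
                          models: HypothesisModelSet,
                          method: str = "binary") -> np.ndarray:
    """Symmetric M x M matrix of two-hypothesis error rates.

    ``binary`` (default): for each pair {i, j} the detection is re-run
    restricted to those two hypotheses, over the cells of those two
    treatments, with equal priors. ``renormalize``: the pairwise rate is
    instead read off the full M-ary confusion matrix by renormalizing its
    {i, j} submatrix. The diagonal is 0 by convention.
    """
    if method not in ("binary", "renormalize"):
        raise ValueError(f"unknown pairwise method '{method}'")
    M = models.M
    out = np.zeros((M, M), dtype=float)
    if method == "renormalize":
        full = estimate_confusion(transformed_sample, models)
    for i in range(M):
        for j in range(i + 1, M):
            if method == "binary":
                pair_models = models.subset([i, j])
                pair_data = {0: transformed_sample[i], 1: transformed_sample[j]}
                cm = estimate_confusion(pair_data, pair_models)
            else:
                sub = full.counts[np.ix_([i, j], [i, j])]
                cm = ConfusionMatrix(sub)
            pe = error_probability(cm, weighting="equiprobable").pe
            out[i, j] = out[j, i] = pe
    return out


def neglog_display(pe: float, base: int | str = 10,
                   sentinel: float | None = None) -> float:
    """-log(Pe) for display, with a finite sentinel at Pe = 0.

    Bar graphs of -log10(Pe) need a finite bar for perfectly discriminated
    samples; the convention is -log10(0) -> 6. For natural log the
    equivalent sentinel is 6 ln 10, keeping the two scales consistent.
    """
    if not 0.0 <= pe <= 1.0:
        raise DomainError(f"pe={pe} outside [0, 1]")
    if base in (10, "10"):
        log_fn, default_sentinel = np.log10, SENTINEL_NEGLOG10
    elif base in ("e", np.e):
        log_fn, default_sentinel = np.log, SENTINEL_NEGLOG10 * np.log(10.0)
    else:
        raise ValueError(f"base must be 10 or 'e', got {base!r}")
    if sentinel is None:
        sentinel = default_sentinel
    if pe == 0.0:
        return float(sentinel)
    return float(-log_fn(pe))
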