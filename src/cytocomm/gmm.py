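"""Two-component multivariate Gaussian mixture per stimulation condition.

Log-transformed responses under each hypothesis H_i are modeled as

    p(x) = rho * N(x; m1, Sigma1) + (1 - rho) * N(x; m2, Sigma2)

with full covariances. Fitting is expectation-maximization (scikit-learn's
``GaussianMixture``) with k-means++ initialization, multiple seeded
restarts, and a small ridge added to covariance diagonals for numerical
stability. Density evaluation uses Cholesky factorizations and
log-sum-exp and is owned by this module so the detector does not depend
on the fitting backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular, LinAlgError
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .errors import DecompositionError, DegenerateCovarianceError, InsufficientDataError

_LOG_2PI = float(np.log(2.0 * np.pi))

#: EM defaults: restarts, convergence tolerance, iteration cap, relative ridge.
DEFAULT_N_INIT = 5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_REG_SCALE = 1e-6


@dataclass(frozen=True)
class GaussianComponent:
    """One multivariate normal component (mean vector, full covariance)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        k = mean.shape[0]
        if cov.shape != (k, k):
            raise ValueError(f"cov must be {k}x{k}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric (tol 1e-8)")

    @property
    def K(self) -> int:
        return self.mean.shape[0]

    def chol(self) -> np.ndarray:
        """Lower Cholesky factor; raises :class:`DecompositionError` if not PD."""
        try:
            return cholesky(self.cov, lower=True)
        except LinAlgError as exc:
            raise DecompositionError(
                f"covariance not positive-definite: {exc}"
            ) from exc

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Log N(x; mean, cov) for each row of X (or a single vector)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        L = self.chol()
        dev = solve_triangular(L, (X - self.mean).T, lower=True)
        maha = np.sum(dev * dev, axis=0)
        log_det = 2.0 * np.sum(np.log(np.diag(L)))
        return -0.5 * (self.K * _LOG_2PI + log_det + maha)


@dataclass
class GMParams:
    """Fitted mixture for one hypothesis: weight rho on comp1, 1-rho on comp2."""

    rho: float
    comp1: GaussianComponent
    comp2: GaussianComponent
    hypothesis_index: int = -1
    n_fit: int = 0
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.comp1.K != self.comp2.K:
            raise ValueError("components must share dimensionality")

    @property
    def K(self) -> int:
        return self.comp1.K

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "mean1": self.comp1.mean.tolist(),
            "cov1": self.comp1.cov.tolist(),
            "mean2": self.comp2.mean.tolist(),
            "cov2": self.comp2.cov.tolist(),
            "hypothesis_index": self.hypothesis_index,
            "n_fit": self.n_fit,
            "fit_meta": dict(self.fit_meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMParams":
        return cls(
            rho=float(d["rho"]),
            comp1=GaussianComponent(np.asarray(d["mean1"]), np.asarray(d["cov1"])),
            comp2=GaussianComponent(np.asarray(d["mean2"]), np.asarray(d["cov2"])),
            hypothesis_index=int(d.get("hypothesis_index", -1)),
            n_fit=int(d.get("n_fit", 0)),
            fit_meta=dict(d.get("fit_meta", {})),
        )


def fit_gm2(X: np.ndarray, seed: int = 0, reg: float | None = None,
            n_init: int = DEFAULT_N_INIT, tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER,
            hypothesis_index: int = -1) -> GMParams:
    """EM fit of the two-component full-covariance mixture.

    Parameters
    ----------
    X
        (N, K) transformed responses; needs N >= 2(K+1) rows so both full
        covariances are estimable under regularization.
    seed
        Seeds initialization; the fit is deterministic given (X, seed, n_init).
    reg
        Ridge added to covariance diagonals. Default: 1e-6 times the mean
        per-channel variance of X (floored at 1e-12 for constant data).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if n < 2 * (k + 1):
        raise InsufficientDataError(
            f"need at least {2 * (k + 1)} cells to fit two full covariances "
            f"in K={k} dimensions, got {n}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if reg is None:
        mean_var = float(np.mean(np.var(X, axis=0)))
        reg = DEFAULT_REG_SCALE * mean_var if mean_var > 0 else 1e-12
    degenerate = bool(np.all(X == X[0]))
    if degenerate and reg <= 0:
        raise DegenerateCovarianceError(
            "all rows identical and reg=0: covariance is singular"
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        reg_covar=max(reg, 0.0) if not degenerate else max(reg, 1e-12),
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        init_params="k-means++",
        random_state=int(seed) % (2**31),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence reported via fit_meta
        gm.fit(X)

    weights = gm.weights_
    order = (0, 1)
    # comp1 carries the larger weight; ties broken by larger first-channel mean
    if weights[1] > weights[0] or (
        weights[1] == weights[0] and gm.means_[1, 0] > gm.means_[0, 0]
    ):
        order = (1, 0)
    comps = [GaussianComponent(gm.means_[i], gm.covariances_[i]) for i in order]
    for c in comps:
        c.chol()  # raises DecompositionError / DegenerateCovarianceError early
    return GMParams(
        rho=float(weights[order[0]]),
        comp1=comps[0],
        comp2=comps[1],
        hypothesis_index=hypothesis_index,
        n_fit=n,
        fit_meta={
            "seed": int(seed),
            "n_init": int(n_init),
            "reg": float(reg),
            "tol": float(tol),
            "max_iter": int(max_iter),
            "n_iter": int(gm.n_iter_),
            "converged": bool(gm.converged_),
            "log_likelihood": float(gm.score(X) * n),
        },
    )


def gm_log_density(x: np.ndarray, params: GMParams) -> np.ndarray | float:
    """ln[rho N(x; m1, S1) + (1-rho) N(x; m2, S2)], stable via log-sum-exp.

    Accepts a single length-K vector (returns a float) or an (N, K) matrix
    (returns a length-N array).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.K:
        raise ValueError(f"x has {X.shape[1]} columns, model has K={params.K}")
    parts, logw = [], []
    for w, comp in ((params.rho, params.comp1), (1.0 - params.rho, params.comp2)):
        if w > 0.0:
            parts.append(comp.log_pdf(X))
            logw.append(np.log(w))
    out = logsumexp(np.column_stack(parts) + np.asarray(logw), axis=1)
    return float(out[0]) if single else out
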