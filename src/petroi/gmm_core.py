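"""Gaussian mixture model, EM fitting and BIC/AIC model selection.

The mixture density is p(x|θ) = Σ_k π_k N(x | μ_k, Σ_k) with full
covariances.  Everything likelihood-related is computed in log space with
the max factored out of the inner sum (log-sum-exp), so the fit remains
finite on data whose raw Gaussian densities underflow or overflow double
precision.

The number of components K is chosen by minimizing an information
criterion over a grid of candidates:

    BIC = -2 log L + log(N) · P,      AIC = -2 log L + 2 P,

where P = K·D·(D+3)/2 + K - 1 is the free-parameter count of a K-component
full-covariance mixture in D dimensions (K-1 proportions, K·D means,
K·D·(D+1)/2 covariance entries).  Lower is better; ties break toward the
simpler (smaller-K) model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateComponentError, GMMFitError, SelectionError

logger = logging.getLogger(__name__)

_DEGENERATE_RESP = 1e-12


@dataclass
class GMMParams:
    """Mixture parameters θ = {π_k, μ_k, Σ_k}."""

    pi: np.ndarray  # (K,)
    mu: np.ndarray  # (K, D)
    sigma: np.ndarray  # (K, D, D)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.ndim == 2:
            self.sigma = self.sigma[None, :, :]
        K, D = self.mu.shape
        if self.pi.shape != (K,) or self.sigma.shape != (K, D, D):
            raise ConfigurationError("inconsistent GMM parameter shapes")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixing proportions must be >=0 and sum to 1")

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    @property
    def D(self) -> int:
        return self.mu.shape[1]


@dataclass
class FitResult:
    """One EM fit: final parameters, likelihood and its trajectory."""

    params: GMMParams
    loglik: float
    trajectory: np.ndarray
    n_iter: int
    converged: bool
    seed: int


@dataclass
class ModelSelectionResult:
    """Scores of every candidate K and the selected one."""

    k_grid: list[int]
    bic: dict[int, float]
    aic: dict[int, float]
    loglik: dict[int, float]
    P: dict[int, int]
    chosen_k: int
    criterion: str
    fits: dict[int, FitResult] = field(repr=False, default_factory=dict)

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.chosen_k]

    def to_dict(self) -> dict:
        """JSON-serializable summary (scores and chosen K, no raw fits)."""
        return {
            "k_grid": self.k_grid,
            "criterion": self.criterion,
            "chosen_k": self.chosen_k,
            "bic": {str(k): v for k, v in self.bic.items()},
            "aic": {str(k): v for k, v in self.aic.items()},
            "loglik": {str(k): v for k, v in self.loglik.items()},
            "free_params": {str(k): v for k, v in self.P.items()},
        }


def gaussian_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray | float:
    """Log-density of the D-dimensional Gaussian N(μ, Σ) at ``x``.

    Evaluated via a Cholesky factorization of Σ, never through the raw
    density, so it stays finite far into the tails.  ``x`` may be a single
    D-vector or an (N, D) array; the return matches (scalar or (N,)).
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64).ravel()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=np.float64))
    D = mu.shape[0]
    single = x.ndim == 1
    X = np.atleast_2d(x)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance not positive-definite: {exc}") from exc
    diff = X - mu
    # solve L z = diff^T; Mahalanobis = ||z||^2
    z = np.linalg.solve(L, diff.T)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    out = -0.5 * (D * math.log(2.0 * math.pi) + logdet + maha)
    return float(out[0]) if single else out


def _log_joint(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """(N, K) matrix of log(π_k) + log N(x_n | μ_k, Σ_k); -inf where π_k=0.

    All components are factorized and solved in one batched call; the
    per-component cost is O(N·D²) after a single D×D Cholesky each.
    """
    K, D = params.K, params.D
    L = np.linalg.cholesky(params.sigma)  # (K, D, D), raises on non-PD
    diff = X[None, :, :] - params.mu[:, None, :]  # (K, N, D)
    z = np.linalg.solve(L, diff.transpose(0, 2, 1))  # (K, D, N)
    maha = np.einsum("kdn,kdn->kn", z, z)
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)  # (K,)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    A = logpi[None, :] - 0.5 * (D * math.log(2.0 * math.pi) + logdet[None, :] + maha.T)
    A[:, params.pi <= 0.0] = -np.inf  # zero-weight component: -inf, not NaN
    return A


def _logsumexp_rows(A: np.ndarray) -> np.ndarray:
    """Row-wise log Σ_k exp(A_nk) with the row maximum factored out."""
    Am = A.max(axis=1)
    out = np.where(np.isfinite(Am), Am, -np.inf).astype(np.float64)
    finite = np.isfinite(Am)
    if np.any(finite):
        shifted = A[finite] - Am[finite, None]
        out[finite] = Am[finite] + np.log(np.exp(shifted).sum(axis=1))
    return out


def log_likelihood(X: np.ndarray, params: GMMParams) -> float:
    """Mixture log-likelihood L = Σ_n log Σ_k π_k N(x_n|μ_k,Σ_k).

    The inner sum is evaluated with the per-point maximum term A_m factored
    out (log-sum-exp), which keeps L finite where direct evaluation of the
    densities would underflow.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return float(_logsumexp_rows(_log_joint(X, params)).sum())


def e_step(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Posterior responsibilities p_nk ∝ π_k N(x_n|μ_k,Σ_k), rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    A = _log_joint(X, params)
    lse = _logsumexp_rows(A)
    return np.exp(A - lse[:, None])


def m_step(X: np.ndarray, resp: np.ndarray, reg: float = 0.0) -> GMMParams:
    """Maximization step: weighted proportions, means and scatter matrices.

    Covariances get ``reg`` added on the diagonal (ridge regularization
    against collapsed, e.g. co-planar, components).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    resp = np.asarray(resp, dtype=np.float64)
    N, D = X.shape
    Nk = resp.sum(axis=0)
    if np.any(Nk < _DEGENERATE_RESP):
        raise DegenerateComponentError(
            f"component with total responsibility {Nk.min():.3g} < {_DEGENERATE_RESP}"
        )
    pi = Nk / N
    mu = (resp.T @ X) / Nk[:, None]
    # weighted second moment minus mean outer product; computed about the
    # global mean to avoid cancellation when coordinates are far from 0
    center = X.mean(axis=0)
    Xc = X - center
    muc = mu - center
    S2 = np.einsum("nk,nd,ne->kde", resp, Xc, Xc, optimize=True) / Nk[:, None, None]
    sigma = S2 - muc[:, :, None] * muc[:, None, :] + reg * np.eye(D)[None]
    sigma = 0.5 * (sigma + sigma.transpose(0, 2, 1))  # exact symmetry
    return GMMParams(pi, mu, sigma)


def free_param_count(K: int, D: int) -> int:
    """Free parameters of a K-component full-covariance mixture in D dims."""
    if K < 1 or D < 1:
        raise ConfigurationError(f"need K>=1 and D>=1, got K={K}, D={D}")
    return (K * D * (D + 3)) // 2 + K - 1


def bic(loglik: float, N: int, P: int) -> float:
    """Bayesian information criterion, -2L + log(N)·P (natural log)."""
    if N < 1:
        raise ConfigurationError("N must be >= 1")
    return -2.0 * loglik + math.log(N) * P


def aic(loglik: float, P: int) -> float:
    """Akaike information criterion, -2L + 2P."""
    return -2.0 * loglik + 2.0 * P


def grade_evidence(bic_difference: float) -> str:
    """Qualitative evidence grade of a (non-negative) BIC difference.

    0-2 weak, 2-6 positive, 6-10 strong, >10 very strong; values on a
    boundary fall into the lower band.
    """
    if bic_difference < 0:
        raise ConfigurationError("BIC difference must be non-negative")
    if bic_difference <= 2:
        return "weak"
    if bic_difference <= 6:
        return "positive"
    if bic_difference <= 10:
        return "strong"
    return "very strong"


def assign_labels(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Hard assignment: component with the largest posterior per point.

    Ties break toward the lowest component index.
    """
    return np.argmax(e_step(X, params), axis=1)


def _default_reg(X: np.ndarray, reg_scale: float) -> float:
    return max(reg_scale * float(np.mean(np.var(X, axis=0))), 1e-12)


def _init_resp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point seeding of K centers, then one hard-assignment pass.

    The first center is a random data point; each further center is the
    point farthest from all chosen ones.  Small jitter decorrelates
    restarts; a floor keeps every column of the responsibilities positive.
    """
    N, D = X.shape
    centers = [int(rng.integers(N))]
    d2 = np.sum((X - X[centers[0]]) ** 2, axis=1)
    for _ in range(K - 1):
        nxt = int(np.argmax(d2))
        centers.append(nxt)
        d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
    mu = X[centers] + rng.normal(scale=0.01 * (X.std(axis=0) + 1e-12), size=(K, D))
    dist = np.sum((X[:, None, :] - mu[None, :, :]) ** 2, axis=2)
    hard = np.argmin(dist, axis=1)
    resp = np.full((N, K), 1e-6 / K)
    resp[np.arange(N), hard] += 1.0 - 1e-6
    return resp


def fit_gmm(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 300,
    reg_scale: float = 1e-6,
) -> FitResult:
    """Fit a K-component GMM by EM, keeping the best of ``n_restarts`` runs.

    Deterministic given ``seed``.  Convergence when the absolute change of
    the log-likelihood falls below ``tol``.  Covariance diagonals are
    regularized by ``reg_scale`` times the mean per-axis data variance.

    Raises
    ------
    GMMFitError
        if every restart loses a component (degenerate responsibilities).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    N, D = X.shape
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if N < K:
        raise ConfigurationError(f"need at least K={K} points, got N={N}")
    reg = _default_reg(X, reg_scale)
    best: FitResult | None = None
    failures: list[str] = []
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        try:
            resp = _init_resp(X, K, rng)
            params = m_step(X, resp, reg)
            traj: list[float] = []
            prev = -np.inf
            converged = False
            it = 0
            for it in range(1, max_iter + 1):
                A = _log_joint(X, params)
                lse = _logsumexp_rows(A)
                ll = float(lse.sum())
                traj.append(ll)
                if abs(ll - prev) < tol:
                    converged = True
                    break
                prev = ll
                params = m_step(X, np.exp(A - lse[:, None]), reg)
            result = FitResult(params, traj[-1], np.asarray(traj), it, converged, int(seed))
        except DegenerateComponentError as exc:
            failures.append(str(exc))
            continue
        if best is None or result.loglik > best.loglik:
            best = result
    if best is None:
        raise GMMFitError(
            f"all {n_restarts} restarts degenerate for K={K}: {failures[-1]}"
        )
    return best


def select_k(
    X: np.ndarray,
    k_grid: list[int] | range,
    criterion: str = "bic",
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelectionResult:
    """Fit every K in ``k_grid`` and pick the one minimizing BIC or AIC.

    Candidate K larger than the sample size, or whose fit degenerates, are
    skipped with a logged warning.  Ties break toward the smallest K.
    """
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ConfigurationError("k_grid is empty")
    if criterion not in ("bic", "aic"):
        raise ConfigurationError(f"criterion must be 'bic' or 'aic', got {criterion!r}")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    N, D = X.shape
    bics: dict[int, float] = {}
    aics: dict[int, float] = {}
    lls: dict[int, float] = {}
    Ps: dict[int, int] = {}
    fits: dict[int, FitResult] = {}
    for K in k_grid:
        if K > N:
            logger.warning("select_k: skipping K=%d > N=%d", K, N)
            continue
        try:
            fit = fit_gmm(X, K, seed=seed, **fit_kwargs)
        except GMMFitError as exc:
            logger.warning("select_k: K=%d failed (%s)", K, exc)
            continue
        P = free_param_count(K, D)
        fits[K] = fit
        lls[K] = fit.loglik
        Ps[K] = P
        bics[K] = bic(fit.loglik, N, P)
        aics[K] = aic(fit.loglik, P)
    if not fits:
        raise SelectionError("model selection failed: no candidate K could be fitted")
    scores = bics if criterion == "bic" else aics
    chosen = min(sorted(scores), key=lambda k: (scores[k], k))
    return ModelSelectionResult(
        k_grid=sorted(fits),
        bic=bics,
        aic=aics,
        loglik=lls,
        P=Ps,
        chosen_k=int(chosen),
        criterion=criterion,
        fits=fits,
    )
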