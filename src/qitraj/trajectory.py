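"""Group-based trajectory modeling (latent-class growth analysis) via EM.

The model is a finite mixture of longitudinal mean curves with Gaussian
residuals.  Area i's trajectory y_i (length T) belongs to latent class k with
probability π_k; within class k,

    y_it = B(t) β_k + ε_it,   ε_it ~ Normal(0, σ²),

with B the shared time basis (linear, quadratic, or cubic B-spline) and σ²
shared across classes and periods.  The observed-data log-likelihood

    ℓ = Σ_i log Σ_k π_k Π_t Normal(y_it; B(t) β_k, σ²)

is maximized by EM over several seeded initializations (k-means on the raw
trajectories, then random posterior draws).  The number of classes is chosen
by BIC = −2ℓ + p log N with p = K·d + (K−1) + 1 free parameters; posterior-
weighted mean absolute error (WMAE) and residual sum of squares (WRSS) are
reported as complementary fit diagnostics.  Fitted groups are ranked by their
mean curve at the final period and named by level bands ("high to high",
"low to middle", ...) at the first and last period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .config import BasisSpec
from .errors import ConfigurationError, ConvergenceError, DomainError

_LOG_2PI = float(np.log(2.0 * np.pi))
_SIGMA2_FLOOR = 1e-12  # keeps the likelihood finite on noiseless data


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

def build_basis(spec: BasisSpec, periods: Sequence[float]) -> np.ndarray:
    """Design matrix (T × d) of the time basis evaluated at ``periods``.

    ``linear`` gives columns (1, t); ``quadratic`` (1, t, t²); ``spline`` a
    B-spline basis of ``spec.df`` columns, degree min(3, df−1), interior knots
    at equally spaced quantiles of the period range.  Raises
    :class:`ConfigurationError` if the resulting matrix is rank-deficient for
    the given periods (over-parameterized basis).
    """
    t = np.asarray(periods, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ConfigurationError("periods must be a non-empty 1-d sequence")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("periods must be strictly increasing")

    if spec.kind == "linear":
        B = np.column_stack([np.ones_like(t), t])
    elif spec.kind == "quadratic":
        B = np.column_stack([np.ones_like(t), t, t**2])
    else:
        d = spec.df
        degree = min(3, d - 1)
        n_interior = d - degree - 1
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(t, qs)
        else:
            interior = np.array([])
        knots = np.concatenate([
            np.repeat(t[0], degree + 1), interior, np.repeat(t[-1], degree + 1),
        ])
        B = BSpline.design_matrix(t, knots, degree, extrapolate=False).toarray()

    if not spec.include_intercept:
        B = B[:, 1:]
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ConfigurationError(
            f"basis {spec.kind} (df={B.shape[1]}) is rank-deficient on {t.size} periods"
        )
    return B


# ---------------------------------------------------------------------------
# fitted-model containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryMixture:
    """A fitted latent-class growth model."""

    K: int
    pi: np.ndarray                 # (K,) mixing proportions
    beta: np.ndarray               # (K, d) class coefficients on the basis scale
    sigma2: float                  # shared residual variance
    loglik: float                  # observed-data log-likelihood, nats
    n_params: int                  # K·d + (K−1) + 1
    basis_spec: BasisSpec
    basis: np.ndarray              # (T, d) design matrix used for the fit
    periods: np.ndarray            # (T,)
    converged: bool = True
    n_iter: int = 0
    final_delta: float = np.nan
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def class_means(self) -> np.ndarray:
        """Fitted mean curves, (K, T)."""
        return self.beta @ self.basis.T


@dataclass
class GroupAssignment:
    """Posterior class memberships and display names for a fitted model."""

    posterior: np.ndarray          # (N, K), rows sum to 1
    modal: np.ndarray              # (N,) argmax labels, ties -> lowest index
    area_ids: Optional[list] = None
    names: Optional[list[str]] = None        # e.g. "high to high", rank order
    short_names: Optional[list[str]] = None  # e.g. "HH"

    @property
    def counts(self) -> np.ndarray:
        K = self.posterior.shape[1]
        return np.bincount(self.modal, minlength=K)


@dataclass
class FitMetrics:
    bic: float
    wmae: float
    wrss: float


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _e_step(Y, B, pi, beta, sigma2):
    """Posterior log-responsibilities and the log-likelihood."""
    N, T = Y.shape
    mu = beta @ B.T                                   # (K, T)
    d2 = ((Y[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)  # (N, K)
    log_phi = -0.5 * T * (_LOG_2PI + np.log(sigma2)) - 0.5 * d2 / sigma2
    log_w = np.log(np.clip(pi, 1e-300, None))[None, :] + log_phi
    log_norm = logsumexp(log_w, axis=1)
    return log_w - log_norm[:, None], float(log_norm.sum())

def _m_step(Y, B, P):
    """Posterior-weighted least squares for β, closed forms for π and σ²."""
    N, T = Y.shape
    K = P.shape[1]
    nk = P.sum(axis=0)                                # (K,)
    pi = nk / N
    BtB = B.T @ B
    ybar = (P.T @ Y) / np.where(nk > 0, nk, np.nan)[:, None]  # (K, T)
    beta = np.linalg.solve(BtB, B.T @ ybar.T).T       # (K, d)
    mu = beta @ B.T
    d2 = ((Y[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    sigma2 = float((P * d2).sum() / (N * T))
    return pi, beta, max(sigma2, _SIGMA2_FLOOR)


def _init_posterior(Y, K, how, rng):
    N = Y.shape[0]
    if how == "kmeans":
        seed = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(Y)
        P = np.zeros((N, K))
        P[np.arange(N), labels] = 1.0
    else:
        P = rng.dirichlet(np.ones(K), size=N)
    return P


def _run_em(Y, B, P0, tol, max_iter):
    """One EM run from initial posteriors P0; returns the fitted state."""
    pi, beta, sigma2 = _m_step(Y, B, P0)
    trace = []
    loglik = -np.inf
    converged = False
    delta = np.nan
    for it in range(1, max_iter + 1):
        logP, new_loglik = _e_step(Y, B, pi, beta, sigma2)
        trace.append(new_loglik)
        delta = new_loglik - loglik
        loglik = new_loglik
        if it > 1 and abs(delta) < tol:
            converged = True
            break
        P = np.exp(logP)
        pi, beta, sigma2 = _m_step(Y, B, P)
    logP, loglik = _e_step(Y, B, pi, beta, sigma2)
    return {
        "pi": pi, "beta": beta, "sigma2": sigma2, "loglik": loglik,
        "posterior": np.exp(logP), "trace": np.asarray(trace),
        "converged": converged, "n_iter": len(trace), "delta": delta,
    }


def n_parameters(K: int, d: int) -> int:
    """Free parameters: K·d curve coefficients, K−1 mixing shares, one σ²."""
    return K * d + (K - 1) + 1


def em_fit(
    Y: np.ndarray,
    K: int,
    spec: BasisSpec = BasisSpec(),
    *,
    periods: Optional[Sequence[float]] = None,
    n_starts: int = 10,
    seed: Optional[int] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    area_ids: Optional[list] = None,
) -> tuple[TrajectoryMixture, GroupAssignment, FitMetrics]:
    """Fit a K-class latent-class growth model to the trajectory matrix Y.

    Parameters
    ----------
    Y : (N, T) complete matrix of responses (proportions in [0, 1], or logits
        if the caller fits on the logit scale).
    K : number of latent classes, 1 <= K <= N.
    spec : time basis specification.
    periods : time values for the basis; defaults to 0..T-1.
    n_starts : number of initializations (first k-means, the rest random
        posterior draws); the best final log-likelihood wins.
    seed : RNG seed; the same seed reproduces the fit exactly.
    tol, max_iter : EM stopping rule on |Δℓ|.

    Raises
    ------
    ConvergenceError
        if every start collapses a class below the empty-class floor 1/(10N).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise DomainError("Y must be a 2-d (areas × periods) matrix")
    N, T = Y.shape
    if not (1 <= K <= N):
        raise DomainError(f"K must be in [1, {N}], got {K}")
    if np.isnan(Y).any():
        raise DomainError("Y contains missing values; complete the panel first")
    if periods is None:
        periods = np.arange(T, dtype=float)
    B = build_basis(spec, periods)
    d = B.shape[1]
    rng = np.random.default_rng(seed)
    floor = 1.0 / (10.0 * N)

    best = None
    n_collapsed = 0
    for s in range(n_starts):
        P0 = _init_posterior(Y, K, "kmeans" if s == 0 else "random", rng)
        state = _run_em(Y, B, P0, tol, max_iter)
        if K > 1 and (state["posterior"].max(axis=0) < floor).any():
            n_collapsed += 1  # degenerate: some class owns no area even weakly
            continue
        if best is None or state["loglik"] > best["loglik"]:
            best = state
    if best is None:
        raise ConvergenceError(
            f"all {n_starts} starts collapsed a class below the floor {floor:.3g} "
            f"(K={K}, N={N})",
            best_attempt={"n_collapsed": n_collapsed},
        )

    mixture = TrajectoryMixture(
        K=K, pi=best["pi"], beta=best["beta"], sigma2=best["sigma2"],
        loglik=best["loglik"], n_params=n_parameters(K, d),
        basis_spec=spec, basis=B, periods=np.asarray(periods, dtype=float),
        converged=best["converged"], n_iter=best["n_iter"],
        final_delta=best["delta"], loglik_trace=best["trace"],
    )
    P = best["posterior"]
    assignment = GroupAssignment(posterior=P, modal=P.argmax(axis=1), area_ids=area_ids)
    metrics = FitMetrics(
        bic=compute_bic(mixture.loglik, mixture.n_params, N),
        wmae=compute_wmae(Y, mixture, P),
        wrss=compute_wrss(Y, mixture, P),
    )
    return mixture, assignment, metrics


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

def compute_bic(loglik: float, n_params: int, n_trajectories: int) -> float:
    """BIC = −2ℓ + p·log(N); lower is better, negative when ℓ > 0."""
    if n_trajectories < 1 or n_params < 1:
        raise DomainError("compute_bic requires N >= 1 and p >= 1")
    return -2.0 * loglik + n_params * np.log(n_trajectories)


def compute_wmae(Y, mixture: TrajectoryMixture, P) -> float:
    """Posterior-weighted mean absolute error of the class curves.

    WMAE = (1/(N·T)) Σ_i Σ_k p_ik Σ_t |y_it − μ_k(t)|.
    """
    Y = np.asarray(Y, dtype=float)
    N, T = Y.shape
    mu = mixture.class_means
    ad = np.abs(Y[:, None, :] - mu[None, :, :]).sum(axis=2)  # (N, K)
    return float((np.asarray(P) * ad).sum() / (N * T))


def compute_wrss(Y, mixture: TrajectoryMixture, P) -> float:
    """Posterior-weighted residual sum of squares (no 1/(N·T) normalization)."""
    Y = np.asarray(Y, dtype=float)
    mu = mixture.class_means
    d2 = ((Y[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    return float((np.asarray(P) * d2).sum())


# ---------------------------------------------------------------------------
# model selection over K
# ---------------------------------------------------------------------------

def select_model(
    Y: np.ndarray,
    K_range: Sequence[int] = range(1, 6),
    spec: BasisSpec = BasisSpec(),
    *,
    seed: Optional[int] = None,
    n_starts: int = 10,
    periods: Optional[Sequence[float]] = None,
    area_ids: Optional[list] = None,
    **em_kwargs,
):
    """Fit every K in ``K_range`` and choose the BIC minimizer.

    Returns
    -------
    table : DataFrame with one row per K — columns ``K, loglik, n_params, BIC,
        WMAE, WRSS, converged, failed`` (``failed`` marks fits that collapsed
        on every start; they are excluded from the argmin).
    chosen_K : the BIC-minimizing K (ties broken toward smaller K).
    fits : dict K -> (mixture, assignment, metrics) for the successful fits.
    """
    K_list = list(K_range)
    if not K_list:
        raise DomainError("K_range must be non-empty")
    ss = np.random.SeedSequence(seed).spawn(len(K_list))
    rows, fits = [], {}
    for K, child in zip(K_list, ss):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        try:
            mixture, assignment, metrics = em_fit(
                Y, K, spec, periods=periods, n_starts=n_starts,
                seed=child_seed, area_ids=area_ids, **em_kwargs,
            )
        except ConvergenceError:
            rows.append({"K": K, "loglik": np.nan, "n_params": np.nan,
                         "BIC": np.nan, "WMAE": np.nan, "WRSS": np.nan,
                         "converged": False, "failed": True})
            continue
        fits[K] = (mixture, assignment, metrics)
        rows.append({"K": K, "loglik": mixture.loglik, "n_params": mixture.n_params,
                     "BIC": metrics.bic, "WMAE": metrics.wmae, "WRSS": metrics.wrss,
                     "converged": mixture.converged, "failed": False})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise ConvergenceError("no K in the range produced a usable fit")
    # stable sort: ties in BIC resolve toward the smaller K
    chosen_K = int(ok.sort_values(["BIC", "K"], kind="mergesort").iloc[0]["K"])
    return table, chosen_K, fits


# ---------------------------------------------------------------------------
# group ordering and naming
# ---------------------------------------------------------------------------

def _band(value: float, low: float, high: float) -> str:
    if value < low:
        return "low"
    if value < high:
        return "middle"
    return "high"


def order_and_name_groups(
    mixture: TrajectoryMixture,
    assignment: GroupAssignment,
    naming_thresholds: tuple[float, float] = (0.45, 0.60),
    *,
    curve_transform=None,
) -> tuple[TrajectoryMixture, GroupAssignment]:
    """Rank classes by fitted mean at the final period and attach display names.

    Classes are reordered (highest final-period mean first, ties keeping the
    original index order) and each is named "<band(first)> to <band(last)>"
    with bands low/middle/high cut at ``naming_thresholds`` on the proportion
    scale.  Duplicate names get " (1)", " (2)" suffixes in rank order.

    ``curve_transform`` maps fitted class means onto the proportion scale
    before banding (pass ``scipy.special.expit`` for logit-scale fits).
    """
    low, high = naming_thresholds
    if not low < high:
        raise ConfigurationError(f"naming thresholds must satisfy low < high, got ({low}, {high})")
    means = mixture.class_means
    if curve_transform is not None:
        means = curve_transform(means)
    final = means[:, -1]
    order = np.argsort(-final, kind="stable")

    names = [f"{_band(means[k, 0], low, high)} to {_band(means[k, -1], low, high)}" for k in order]
    shorts = [f"{a[0].upper()}{b[0].upper()}" for a, b in (n.split(" to ") for n in names)]
    for label in set(names):
        idx = [i for i, n in enumerate(names) if n == label]
        if len(idx) > 1:
            for j, i in enumerate(idx, start=1):
                names[i] = f"{label} ({j})"
                shorts[i] = f"{shorts[i]}{j}"

    remap = np.empty(mixture.K, dtype=int)
    remap[order] = np.arange(mixture.K)
    new_mixture = replace(mixture, pi=mixture.pi[order], beta=mixture.beta[order])
    new_assignment = GroupAssignment(
        posterior=assignment.posterior[:, order],
        modal=remap[assignment.modal],
        area_ids=assignment.area_ids,
        names=names,
        short_names=shorts,
    )
    return new_mixture, new_assignment
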