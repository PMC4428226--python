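"""Constrained maximum-likelihood estimation of pattern frequencies.

The observed counts ``y`` over read patterns are multinomial with cell
probabilities ``phi = theta M``, where ``theta`` is the unknown true pattern
distribution and ``M`` the pattern transition matrix of the error model.
The log-likelihood

    L(theta | y) = sum_k y_k log( sum_j theta_j M_jk )

is maximised over the probability simplex.  Simply inverting M on the naive
estimate ``y / N`` fails because M shrinks the simplex: with many zero
counts, ``y / N`` sits on a face the shrunken simplex does not contain, and
the inverted vector leaves the simplex.  The constrained MLE is unique, so
any simplex-respecting ascent finds it; multiplicative EM updates

    theta_j <- theta_j * sum_k ( y_k M_jk / phi_k ) / N

are used here.  They stay on the simplex and approach boundary points
(theta_j = 0) gracefully.  Because any finite-precision optimiser stalls
slightly inside the boundary, a refinement step compares the log-likelihood
at nearby boundary points (near-zero components snapped to exact zero, the
rest re-optimised) and adopts a boundary point whenever its likelihood is at
least as high; observed patterns whose final estimate is identically zero
are reported as spurious.

Two search modes mirror the exponential growth of the pattern space: the
slow (exact) mode searches all ``2**n`` patterns and is practical for
``n <= 8``; the fast (default) mode fixes ``theta_k = 0`` wherever
``y_k = 0`` and searches the sub-simplex supported on observed patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .error_model import ErrorModel, PatternDistribution, transition_submatrix
from .patterns import PatternCounts, index_bits

__all__ = [
    "EstimationResult",
    "log_likelihood",
    "estimate_slow",
    "estimate_fast",
    "boundary_refine",
    "call_spurious",
    "marginal_methylation",
    "naive_estimate",
    "inversion_estimate",
]

#: Stop when the log-likelihood improves by less than this (nats) per sweep.
CONVERGENCE_TOL = 1e-10

#: Default cap on EM sweeps.
MAX_ITER = 100_000

#: Components below this are candidates for snapping to the boundary.
ZERO_CANDIDATE_TOL = 1e-5

#: Adopt a boundary point if its log-likelihood is >= current minus this.
BOUNDARY_LL_TOL = 1e-9

#: Slow mode refuses above this n unless forced.
SLOW_MODE_N_LIMIT = 8

#: Fast mode warns above this many observed patterns.
FAST_MODE_PATTERN_LIMIT = 200


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of a constrained MLE run.

    Attributes
    ----------
    theta_hat
        The estimated pattern distribution; components are exactly zero or
        strictly positive after boundary refinement.
    mode
        ``"slow"`` (all ``2**n`` patterns) or ``"fast"`` (observed support).
    log_likelihood
        Final log-likelihood in nats.
    spurious
        1-based indices of observed patterns (``y_k > 0``) whose estimate is
        identically zero — called absent from the underlying sample.
    iterations
        Total EM sweeps across all support restrictions.
    converged
        Whether every EM stage met the tolerance within its iteration cap.
    boundary_snaps
        Indices set to exactly zero by boundary refinement, in the order
        they were snapped.
    """

    theta_hat: PatternDistribution
    mode: str
    log_likelihood: float
    spurious: frozenset[int]
    iterations: int
    converged: bool
    boundary_snaps: tuple[int, ...] = field(default_factory=tuple)


def _loglik(theta: np.ndarray, y: np.ndarray, M_sub: np.ndarray) -> float:
    phi = theta @ M_sub
    if np.any(phi <= 0):
        return -np.inf
    return float(y @ np.log(phi))


def log_likelihood(
    theta: PatternDistribution, counts: PatternCounts, model: ErrorModel
) -> float:
    """Multinomial log-likelihood of ``theta`` given observed counts (nats).

    Sums ``y_k log phi_k`` over observed patterns only; returns ``-inf`` if
    any observed pattern has zero probability under ``theta M``.
    """
    if not (theta.n == counts.n == model.n):
        raise ValueError("theta, counts and model must share the same n")
    obs = counts.observed_indices()
    y = counts.count_vector(obs)
    M_sub = transition_submatrix(theta.support, obs, model)
    return _loglik(theta.probs, y, M_sub)


def _em(
    theta: np.ndarray,
    y: np.ndarray,
    M_sub: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool]:
    """Multiplicative EM ascent of the multinomial log-likelihood.

    ``theta`` is over the active support (rows of ``M_sub``); ``y`` over the
    observed patterns (columns).  Monotone in the log-likelihood.
    """
    n_read = y.sum()
    ll = _loglik(theta, y, M_sub)
    for it in range(1, max_iter + 1):
        phi = theta @ M_sub
        theta = theta * (M_sub @ (y / phi)) / n_read
        theta /= theta.sum()  # guard accumulated round-off
        new_ll = _loglik(theta, y, M_sub)
        if new_ll - ll < tol:
            return theta, new_ll, it, True
        ll = new_ll
    return theta, ll, max_iter, False


def boundary_refine(
    theta: PatternDistribution,
    counts: PatternCounts,
    model: ErrorModel,
    zero_candidate_tol: float = ZERO_CANDIDATE_TOL,
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITER,
) -> tuple[PatternDistribution, float, tuple[int, ...], int, bool]:
    """Snap near-zero components to the simplex boundary when likelihood allows.

    For every component below ``zero_candidate_tol`` the log-likelihood is
    evaluated with that component (and, additionally, with all candidates
    jointly) set to exactly zero and the remaining mass renormalised.  If the
    best such boundary point has log-likelihood at least the current value
    (within a small slack), it is adopted, the estimate is re-optimised over
    the reduced support, and the search repeats until the support is stable.

    Returns ``(theta, log_likelihood, snapped_indices, extra_iterations,
    converged)``.
    """
    obs = counts.observed_indices()
    y = counts.count_vector(obs)

    support = theta.support.copy()
    probs = theta.probs.copy()
    M_sub = transition_submatrix(support, obs, model)
    ll = _loglik(probs, y, M_sub)
    snapped: list[int] = []
    extra_iters = 0
    converged = True

    while True:
        cand = np.flatnonzero((probs > 0) & (probs < zero_candidate_tol))
        if cand.size == 0 or cand.size == probs.size:
            break
        trials = [np.array([j]) for j in cand]
        if cand.size > 1:
            trials.append(cand)
        best_ll, best_drop = -np.inf, None
        for drop in trials:
            keep = np.ones(probs.size, dtype=bool)
            keep[drop] = False
            t = probs[keep] / probs[keep].sum()
            cand_ll = _loglik(t, y, M_sub[keep])
            if cand_ll > best_ll:
                best_ll, best_drop = cand_ll, drop
        if best_drop is None or best_ll < ll - BOUNDARY_LL_TOL:
            break
        # adopt the boundary point, then re-optimise over the reduced support
        snapped.extend(int(k) for k in support[best_drop])
        keep = np.ones(probs.size, dtype=bool)
        keep[best_drop] = False
        support = support[keep]
        M_sub = M_sub[keep]
        probs = probs[keep] / probs[keep].sum()
        probs, ll, iters, ok = _em(probs, y, M_sub, tol, max_iter)
        extra_iters += iters
        converged &= ok

    refined = PatternDistribution(theta.n, support, probs, validate=False)
    return refined, ll, tuple(snapped), extra_iters, converged


def _estimate(
    counts: PatternCounts,
    model: ErrorModel,
    support: np.ndarray,
    mode: str,
    tol: float,
    max_iter: int,
    zero_candidate_tol: float,
    theta0: np.ndarray | None = None,
) -> EstimationResult:
    obs = counts.observed_indices()
    y = counts.count_vector(obs)
    M_sub = transition_submatrix(support, obs, model)

    if theta0 is None:
        # strictly interior start: additively smoothed observed proportions
        y_support = counts.count_vector(support)
        theta0 = (y_support + 0.5) / (counts.n_read + 0.5 * support.size)
    else:
        theta0 = np.asarray(theta0, dtype=float)
        if theta0.shape != support.shape or np.any(theta0 <= 0):
            raise ValueError("theta0 must be strictly positive over the search support")
    theta0 = theta0 / theta0.sum()

    probs, ll, iters, converged = _em(theta0, y, M_sub, tol, max_iter)
    if not converged:
        warnings.warn(
            f"{mode} mode: EM did not meet tol={tol} within {max_iter} sweeps",
            stacklevel=3,
        )
    interior = PatternDistribution(counts.n, support, probs, validate=False)
    refined, ll, snapped, extra, refine_ok = boundary_refine(
        interior, counts, model, zero_candidate_tol, tol, max_iter
    )
    theta_hat = refined.trimmed()
    obs_set = set(int(k) for k in obs)
    spurious = frozenset(obs_set - set(int(k) for k in theta_hat.support))
    return EstimationResult(
        theta_hat=theta_hat,
        mode=mode,
        log_likelihood=ll,
        spurious=spurious,
        iterations=iters + extra,
        converged=converged and refine_ok,
        boundary_snaps=snapped,
    )


def estimate_slow(
    counts: PatternCounts,
    model: ErrorModel,
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITER,
    zero_candidate_tol: float = ZERO_CANDIDATE_TOL,
    force: bool = False,
    theta0: np.ndarray | None = None,
) -> EstimationResult:
    """Exact-mode MLE: search over all ``2**n`` patterns.

    Exponential in ``n``; refuses above ``n = 8`` unless ``force=True``.
    ``theta0`` optionally overrides the interior starting point (aligned
    with pattern index order); the MLE is unique, so the result is
    start-independent.
    """
    if counts.n != model.n:
        raise ValueError("counts and model must share the same n")
    if counts.n > SLOW_MODE_N_LIMIT and not force:
        raise ValueError(
            f"slow mode over 2**{counts.n} patterns is computationally "
            f"prohibitive (limit n={SLOW_MODE_N_LIMIT}); use estimate_fast "
            "or pass force=True"
        )
    support = np.arange(1, 2**counts.n + 1)
    return _estimate(
        counts, model, support, "slow", tol, max_iter, zero_candidate_tol, theta0
    )


def estimate_fast(
    counts: PatternCounts,
    model: ErrorModel,
    tol: float = CONVERGENCE_TOL,
    max_iter: int = MAX_ITER,
    zero_candidate_tol: float = ZERO_CANDIDATE_TOL,
    theta0: np.ndarray | None = None,
) -> EstimationResult:
    """Fast-mode MLE: fix ``theta_k = 0`` wherever ``y_k = 0``.

    Searches the sub-simplex supported on observed patterns only.  In
    practice patterns truly present almost never draw zero reads, so the
    restriction loses very little; it scales to large ``n`` as long as the
    number of observed patterns stays modest (a warning is issued above
    about 200).
    """
    if counts.n != model.n:
        raise ValueError("counts and model must share the same n")
    support = counts.observed_indices()
    if support.size > FAST_MODE_PATTERN_LIMIT:
        warnings.warn(
            f"{support.size} observed patterns exceeds the ~{FAST_MODE_PATTERN_LIMIT} "
            "soft limit; fast mode may be slow",
            stacklevel=2,
        )
    return _estimate(
        counts, model, support, "fast", tol, max_iter, zero_candidate_tol, theta0
    )


def call_spurious(result: EstimationResult) -> frozenset[int]:
    """Observed patterns called absent: ``y_k > 0`` with ``theta_hat_k == 0``."""
    return result.spurious


def marginal_methylation(theta: PatternDistribution) -> np.ndarray:
    """Per-site methylation levels: the marginal of ``theta`` at each CpG site."""
    bits = index_bits(theta.support, theta.n)
    return theta.probs @ bits


def naive_estimate(counts: PatternCounts) -> PatternDistribution:
    """The raw read proportions ``y / N_read`` as a distribution.

    Exposed for comparison with the MLE; it ignores the error model entirely.
    """
    obs = counts.observed_indices()
    return PatternDistribution(counts.n, obs, counts.count_vector(obs) / counts.n_read)


def inversion_estimate(counts: PatternCounts, model: ErrorModel) -> np.ndarray:
    """The matrix-inversion estimate ``(y / N) M^{-1}`` (dense, n small).

    Exposed only to demonstrate why inversion fails: M maps the simplex into
    a strictly smaller region, so with zero counts present the inverted
    vector generally has negative components and is not a distribution.
    Returned as a raw dense vector indexed by ``k - 1``, NOT clipped.
    """
    from .error_model import full_transition_matrix

    M = full_transition_matrix(model)
    phi_hat = counts.dense_counts() / counts.n_read
    return np.linalg.solve(M.T, phi_hat)


def binomial_closed_form(counts: PatternCounts, model: ErrorModel) -> PatternDistribution:
    """Closed-form MLE for a single CpG site (``n = 1``).

    Inverts the 2x2 site matrix on the observed methylated proportion and
    clips to [0, 1].  Provided as an independent cross-check of the generic
    optimiser in the single-site (binomial) case.
    """
    if counts.n != 1 or model.n != 1:
        raise ValueError("closed form applies to n=1 only")
    p_obs = counts.counts.get("1", 0) / counts.n_read
    E = model.site_matrices()[0]
    # phi_1 = theta_1 E[1,1] + (1 - theta_1) E[0,1]  =>  solve for theta_1
    denom = E[1, 1] - E[0, 1]
    theta1 = 0.5 if denom == 0 else (p_obs - E[0, 1]) / denom
    theta1 = min(1.0, max(0.0, theta1))
    return PatternDistribution(1, [1, 2], [1 - theta1, theta1], validate=False)
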