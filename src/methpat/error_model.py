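"""Per-site and pattern-level error structure of bisulphite sequencing.

Two error processes act on each CpG site of a read.  Incomplete bisulphite
conversion leaves an unmethylated cytosine unconverted with probability
``epsilon``, so it registers as methylated; methylated sites are unaffected
by conversion.  Sequencing error then flips the observed state in either
direction with per-site probability ``eta_s``.  The per-site transition
matrix is the product of the conversion and read-error matrices,

    E_s = [[1 - eps - eta_s + 2*eps*eta_s, eps + eta_s - 2*eps*eta_s],
           [eta_s,                          1 - eta_s]],

rows and columns labelled 0 (unmethylated) and 1 (methylated).  Sites are
independent given the true pattern, so the pattern-level transition matrix
is the Kronecker product M = E_1 (x) ... (x) E_n, and the distribution of
observed read patterns is phi = theta M for true pattern distribution theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .patterns import index_bits

__all__ = [
    "ErrorModel",
    "PatternDistribution",
    "site_error_matrix",
    "transition_prob",
    "transition_submatrix",
    "full_transition_matrix",
    "read_distribution",
]

#: Largest n for which 2**n x 2**n matrices are materialised by default.
DENSE_N_LIMIT = 12

#: Tolerance for simplex / row-stochasticity validation.
SIMPLEX_TOL = 1e-10


def site_error_matrix(epsilon: float, eta_s: float) -> np.ndarray:
    """The 2x2 row-stochastic transition matrix of one CpG site.

    Entry ``(a, b)`` is the probability that a site with true state ``a``
    registers as state ``b`` after conversion failure and sequencing error.
    """
    if not 0 <= epsilon < 1:
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    if not 0 <= eta_s < 0.5:
        raise ValueError(f"eta must be in [0, 0.5), got {eta_s}")
    return np.array(
        [
            [1 - epsilon - eta_s + 2 * epsilon * eta_s, epsilon + eta_s - 2 * epsilon * eta_s],
            [eta_s, 1 - eta_s],
        ]
    )


@dataclass(frozen=True)
class ErrorModel:
    """Non-conversion rate and per-site sequencing error rates for a locus.

    Parameters
    ----------
    n
        Number of CpG sites.
    epsilon
        Probability an unmethylated cytosine fails to convert (appears
        methylated).  Typically O(1e-2); estimated externally, e.g. from
        non-CpG cytosines or unmethylated spike-ins.
    eta
        Per-site sequencing error probability; a scalar is broadcast to all
        ``n`` sites.  Symmetric: applies to 0->1 and 1->0 alike.
    """

    n: int
    epsilon: float
    eta: np.ndarray

    def __init__(self, n: int, epsilon: float, eta) -> None:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        eta_vec = np.broadcast_to(np.asarray(eta, dtype=float), (n,)).copy()
        if not 0 <= epsilon < 1:
            raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
        if np.any(eta_vec < 0) or np.any(eta_vec >= 0.5):
            raise ValueError(f"every eta_s must be in [0, 0.5), got {eta_vec}")
        if epsilon > 0.1 or np.any(eta_vec > 0.1):
            warnings.warn(
                "error rates above 0.1 are far outside the O(1e-2) regime "
                "these corrections are designed for",
                stacklevel=2,
            )
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "epsilon", float(epsilon))
        object.__setattr__(self, "eta", eta_vec)
        self.eta.setflags(write=False)

    def site_matrices(self) -> list[np.ndarray]:
        """The per-site 2x2 matrices ``E_1, ..., E_n``."""
        return [site_error_matrix(self.epsilon, e) for e in self.eta]


@dataclass(frozen=True)
class PatternDistribution:
    """A point on the (2**n - 1)-simplex of methylation-pattern frequencies.

    Stored sparsely as aligned arrays of 1-based pattern indices (ascending)
    and probabilities; indices absent from ``support`` carry probability 0.
    """

    n: int
    support: np.ndarray  # 1-based pattern indices, strictly ascending
    probs: np.ndarray

    def __init__(self, n: int, support, probs, *, validate: bool = True) -> None:
        support = np.asarray(support, dtype=np.int64)
        probs = np.asarray(probs, dtype=float)
        if support.shape != probs.shape or support.ndim != 1:
            raise ValueError("support and probs must be aligned 1-d arrays")
        order = np.argsort(support)
        support, probs = support[order], probs[order]
        if validate:
            if support.size and (support[0] < 1 or support[-1] > 2**n):
                raise ValueError(f"pattern index out of range for n={n}")
            if np.any(np.diff(support) == 0):
                raise ValueError("duplicate pattern index in support")
            if np.any(probs < -SIMPLEX_TOL):
                raise ValueError("negative probability")
            if abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError(f"probabilities sum to {probs.sum()}, not 1")
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        self.support.setflags(write=False)
        self.probs.setflags(write=False)

    @classmethod
    def from_dense(cls, theta: np.ndarray, *, keep_zeros: bool = False) -> "PatternDistribution":
        """Build from a dense length-``2**n`` vector indexed by ``k - 1``."""
        theta = np.asarray(theta, dtype=float)
        n = int(np.log2(theta.size))
        if 2**n != theta.size:
            raise ValueError("dense vector length must be a power of 2")
        if keep_zeros:
            support = np.arange(1, theta.size + 1)
        else:
            support = np.flatnonzero(theta > 0) + 1
        return cls(n, support, theta[support - 1])

    @classmethod
    def from_dict(cls, n: int, probs: dict) -> "PatternDistribution":
        """Build from a mapping of pattern strings (or indices) to probabilities."""
        from .patterns import encode_pattern

        items = [
            (k if isinstance(k, (int, np.integer)) else encode_pattern(k), p)
            for k, p in probs.items()
        ]
        return cls(n, [k for k, _ in items], [p for _, p in items])

    def to_dense(self) -> np.ndarray:
        """Dense length-``2**n`` probability vector (n <= dense limit)."""
        if self.n > DENSE_N_LIMIT:
            raise ValueError(f"refusing to densify a distribution with n={self.n}")
        theta = np.zeros(2**self.n)
        theta[self.support - 1] = self.probs
        return theta

    def prob(self, k: int) -> float:
        """Probability of the pattern with 1-based index ``k``."""
        i = np.searchsorted(self.support, k)
        if i < self.support.size and self.support[i] == k:
            return float(self.probs[i])
        return 0.0

    def __getitem__(self, k: int) -> float:
        return self.prob(k)

    def trimmed(self) -> "PatternDistribution":
        """Drop exact zeros from the stored support."""
        keep = self.probs > 0
        return PatternDistribution(self.n, self.support[keep], self.probs[keep], validate=False)


def transition_submatrix(
    rows: np.ndarray, cols: np.ndarray, model: ErrorModel
) -> np.ndarray:
    """Matrix of transition probabilities M[k, l] for given index arrays.

    Evaluates the Kronecker-product entries site by site without forming the
    full 2**n x 2**n matrix; cost is O(n * len(rows) * len(cols)).
    """
    rows = np.atleast_1d(np.asarray(rows, dtype=np.int64))
    cols = np.atleast_1d(np.asarray(cols, dtype=np.int64))
    rbits = index_bits(rows, model.n)
    cbits = index_bits(cols, model.n)
    out = np.ones((rows.size, cols.size))
    for s, E in enumerate(model.site_matrices()):
        out *= E[rbits[:, s][:, None], cbits[:, s][None, :]]
    return out


def transition_prob(k: int, l: int, model: ErrorModel) -> float:
    """Probability that true pattern ``k`` registers as pattern ``l``."""
    if not (1 <= k <= 2**model.n and 1 <= l <= 2**model.n):
        raise IndexError(f"pattern index out of range for n={model.n}")
    return float(transition_submatrix(np.array([k]), np.array([l]), model)[0, 0])


def full_transition_matrix(model: ErrorModel, *, force: bool = False) -> np.ndarray:
    """The dense 2**n x 2**n pattern transition matrix M = E_1 (x) ... (x) E_n."""
    if model.n > DENSE_N_LIMIT and not force:
        raise ValueError(
            f"n={model.n} exceeds the dense limit {DENSE_N_LIMIT}; use "
            "transition_submatrix on the index sets you need, or pass force=True"
        )
    M = np.ones((1, 1))
    for E in model.site_matrices():
        M = np.kron(M, E)
    return M


def read_distribution(theta: PatternDistribution, model: ErrorModel) -> PatternDistribution:
    """Push a true pattern distribution through the error model: phi = theta M."""
    if theta.n != model.n:
        raise ValueError(f"dimension mismatch: theta has n={theta.n}, model n={model.n}")
    if model.n > DENSE_N_LIMIT:
        raise ValueError(
            f"phi over all 2**{model.n} patterns is too large to materialise; "
            "use transition_submatrix on the observed patterns instead"
        )
    all_idx = np.arange(1, 2**model.n + 1)
    M_sub = transition_submatrix(theta.support, all_idx, model)
    phi = theta.probs @ M_sub
    return PatternDistribution(model.n, all_idx, phi, validate=False)
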