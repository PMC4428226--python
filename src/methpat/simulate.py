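"""Synthetic bisulphite read-count generation with the model's error structure.

Reads are simulated in two stages that mirror the generative model exactly:
``N_read`` true patterns are drawn multinomially from a prescribed
distribution ``theta``, then each read is corrupted site by site —
non-conversion first (an unmethylated site registers methylated with
probability ``epsilon``), then symmetric sequencing error (the observed
state flips with per-site probability ``eta_s``).  The observed counts are
therefore a single multinomial draw from ``phi = theta M`` in distribution,
but the latent true pattern of every read is retained so tests can compute
exact spurious/real ground truth.

Two fixed datasets used throughout the tests are also provided here: a
contrived n=6 amplicon with known true frequencies (six real patterns, 18
spurious ones among 24 observed, N_read=2000) and a honey-bee
6-phosphofructokinase amplicon with n=8 sites, 36 observed patterns and
N_read=1793.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .error_model import ErrorModel, PatternDistribution
from .patterns import PatternCounts, index_bits, pattern_to_string

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "truncate_distribution",
    "table1_fixture",
    "table2_fixture",
]


@dataclass(frozen=True)
class SimulationSpec:
    """True distribution, read depth, error model and seed for one simulation."""

    theta: PatternDistribution
    n_reads: int
    model: ErrorModel
    seed: int

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError(f"n_reads must be >= 1, got {self.n_reads}")
        if self.theta.n != self.model.n:
            raise ValueError("theta and model must share the same n")


def simulate_counts(spec: SimulationSpec) -> tuple[PatternCounts, PatternCounts]:
    """Simulate observed read counts; returns (observed, latent true counts).

    Deterministic given ``spec.seed``.  The latent table records how many of
    the ``n_reads`` true draws carried each pattern before corruption.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.model.n

    true_counts = rng.multinomial(spec.n_reads, spec.theta.probs)
    drawn = true_counts > 0
    # expand to one row of bits per read
    bits = np.repeat(index_bits(spec.theta.support[drawn], n), true_counts[drawn], axis=0)

    # non-conversion: unmethylated (0) sites register methylated with prob eps
    nonconv = rng.random(bits.shape) < spec.model.epsilon
    bits = np.where((bits == 0) & nonconv, 1, bits)
    # sequencing error: observed state flips with per-site prob eta_s
    flips = rng.random(bits.shape) < spec.model.eta[None, :]
    bits = np.where(flips, 1 - bits, bits)

    weights = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
    observed_idx, observed_y = np.unique(bits @ weights + 1, return_counts=True)

    def _table(idx: np.ndarray, y: np.ndarray) -> PatternCounts:
        pats = index_bits(idx, n)
        return PatternCounts(
            n, {pattern_to_string(row): int(c) for row, c in zip(pats, y)}
        )

    observed = _table(observed_idx, observed_y)
    latent = _table(spec.theta.support[drawn], true_counts[drawn])
    return observed, latent


def truncate_distribution(
    theta: PatternDistribution, floor: float
) -> PatternDistribution:
    """Zero components below ``floor`` and renormalise the remainder.

    Used to build 'true' distributions for simulations from an initial
    estimate on real data: components estimated below the floor are treated
    as absent, so the simulated locus has a known, sparse truth.
    """
    if not 0 <= floor < 1:
        raise ValueError(f"floor must be in [0, 1), got {floor}")
    keep = theta.probs >= floor
    if not np.any(keep):
        raise ValueError(f"all components fall below floor={floor}")
    return PatternDistribution(
        theta.n, theta.support[keep], theta.probs[keep], validate=False
    )


# --- fixed datasets ---------------------------------------------------------

# n=6 synthetic amplicon: (pattern, true theta, observed reads).
# Six real patterns (theta > 0) mimicking a mix of high- and low-abundance
# epialleles; error corruption at eps=0.005, eta=(.008,.006,.006,.006,.006,.008)
# produced 18 additional spurious observed patterns and N_read=2000.
_TABLE1 = [
    ("000000", 0.50, 907),
    ("000001", 0.00, 15),
    ("000010", 0.00, 8),
    ("000100", 0.00, 7),
    ("001000", 0.04, 99),
    ("001001", 0.00, 4),
    ("001010", 0.00, 1),
    ("001100", 0.00, 1),
    ("010000", 0.00, 6),
    ("011000", 0.00, 2),
    ("011011", 0.00, 1),
    ("011101", 0.00, 2),
    ("011111", 0.03, 63),
    ("100000", 0.03, 77),
    ("101101", 0.00, 1),
    ("101111", 0.00, 1),
    ("110000", 0.00, 1),
    ("110111", 0.00, 2),
    ("111001", 0.00, 1),
    ("111011", 0.00, 1),
    ("111100", 0.00, 3),
    ("111101", 0.20, 393),
    ("111110", 0.00, 3),
    ("111111", 0.20, 401),
]

# n=8 honey-bee amplicon (gene GB17113, 454 bisulphite amplicon reads):
# (pattern, observed reads); N_read=1793, analysed at eps=0.01, eta=0.02.
_TABLE2 = [
    ("00000000", 1265),
    ("00000001", 52),
    ("00000010", 32),
    ("00000100", 40),
    ("00000110", 3),
    ("00001000", 75),
    ("00001001", 1),
    ("00001010", 2),
    ("00010000", 36),
    ("00010100", 10),
    ("00100000", 31),
    ("00100001", 2),
    ("00101000", 1),
    ("00110000", 1),
    ("01000000", 20),
    ("01000001", 1),
    ("01100000", 39),
    ("01100001", 4),
    ("01101000", 1),
    ("01110000", 1),
    ("01110100", 1),
    ("10000000", 84),
    ("10000001", 2),
    ("10000010", 5),
    ("10000100", 14),
    ("10001000", 1),
    ("10010000", 2),
    ("10010100", 8),
    ("10100000", 2),
    ("11000100", 1),
    ("11010000", 1),
    ("11100000", 1),
    ("11100100", 2),
    ("11110000", 2),
    ("11110100", 42),
    ("11110110", 8),
]


def table1_fixture() -> tuple[PatternDistribution, PatternCounts, ErrorModel]:
    """The n=6 synthetic benchmark: (true theta, observed counts, error model)."""
    theta = PatternDistribution.from_dict(
        6, {p: t for p, t, _ in _TABLE1 if t > 0}
    )
    counts = PatternCounts(6, {p: y for p, _, y in _TABLE1})
    model = ErrorModel(6, 0.005, [0.008, 0.006, 0.006, 0.006, 0.006, 0.008])
    return theta, counts, model


def table2_fixture() -> tuple[PatternCounts, ErrorModel]:
    """The n=8 honey-bee amplicon benchmark: (observed counts, error model)."""
    counts = PatternCounts(8, dict(_TABLE2))
    model = ErrorModel(8, 0.01, 0.02)
    return counts, model
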