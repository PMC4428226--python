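"""Methylation-pattern encoding and the read-count table data model.

A methylation pattern is the ordered vector of binary CpG states carried by a
single bisulphite read: 0 for unmethylated (converted, read as T), 1 for
methylated (protected, read as C).  Patterns at a locus with ``n`` CpG sites
are indexed by the integers ``k = 1, ..., 2**n``, where ``k - 1`` has binary
expansion equal to the pattern with the leftmost (5'-most) site as the most
significant bit.  Lexicographic order of the pattern strings therefore
coincides with numeric order of the indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MethylationPattern",
    "PatternCounts",
    "encode_pattern",
    "decode_pattern",
    "lexicographic_order",
    "methylation_count",
    "pattern_to_string",
    "parse_pattern",
]


class InvalidPatternError(ValueError):
    """Raised for a pattern containing states other than 0/1."""


#: A methylation pattern: any sequence of 0/1 ints, or a '0'/'1' string.
MethylationPattern = Sequence[int]


def parse_pattern(pattern: "MethylationPattern | str") -> tuple[int, ...]:
    """Coerce a pattern given as string or int sequence to a tuple of bits."""
    if isinstance(pattern, str):
        if not pattern or any(c not in "01" for c in pattern):
            raise InvalidPatternError(
                f"pattern string must be non-empty over '0'/'1', got {pattern!r}"
            )
        return tuple(int(c) for c in pattern)
    states = tuple(int(s) for s in pattern)
    if not states or any(s not in (0, 1) for s in states):
        raise InvalidPatternError(f"pattern states must be 0 or 1, got {pattern!r}")
    return states


def pattern_to_string(pattern: "MethylationPattern | str") -> str:
    """Render a pattern as a '0'/'1' string (leftmost = first CpG site)."""
    return "".join(str(s) for s in parse_pattern(pattern))


def encode_pattern(pattern: "MethylationPattern | str") -> int:
    """Return the 1-based integer index ``k`` of a pattern.

    ``k - 1`` is the integer whose binary representation is the pattern,
    leftmost site = most significant bit; the all-unmethylated pattern maps
    to 1 and the all-methylated pattern of length ``n`` to ``2**n``.
    """
    states = parse_pattern(pattern)
    k = 0
    for s in states:
        k = (k << 1) | s
    return k + 1


def decode_pattern(k: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_pattern`: pattern of index ``k`` at ``n`` sites."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 1 <= k <= 2**n:
        raise IndexError(f"pattern index {k} out of range [1, {2**n}] for n={n}")
    bits = k - 1
    return tuple((bits >> (n - 1 - s)) & 1 for s in range(n))


def methylation_count(pattern: "MethylationPattern | str") -> int:
    """Number of methylated (1) sites in the pattern."""
    return sum(parse_pattern(pattern))


def index_bits(indices: np.ndarray, n: int) -> np.ndarray:
    """Bit matrix of shape ``(len(indices), n)`` for 1-based pattern indices."""
    ks = np.asarray(indices, dtype=np.int64) - 1
    shifts = np.arange(n - 1, -1, -1, dtype=np.int64)
    return (ks[:, None] >> shifts[None, :]) & 1


@dataclass(frozen=True)
class PatternCounts:
    """Observed read counts over methylation patterns at one locus.

    Parameters
    ----------
    n
        Number of CpG sites in the amplicon.
    counts
        Mapping from pattern string (length ``n``) to a non-negative integer
        read count.  Patterns with zero counts may be present but are omitted
        from most outputs.
    """

    n: int
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for pat, y in self.counts.items():
            key = pattern_to_string(pat)
            if len(key) != self.n:
                raise ValueError(
                    f"pattern {key!r} has length {len(key)}, expected n={self.n}"
                )
            if key in clean:
                raise ValueError(f"duplicate pattern {key!r} in count table")
            y = int(y)
            if y < 0:
                raise ValueError(f"negative count {y} for pattern {key!r}")
            clean[key] = y
        if sum(clean.values()) < 1:
            raise ValueError("count table must contain at least one read")
        object.__setattr__(self, "counts", clean)

    @property
    def n_read(self) -> int:
        """Total number of reads, N_read."""
        return sum(self.counts.values())

    def observed_patterns(self) -> list[str]:
        """Patterns with ``y > 0``, in lexicographic order."""
        return sorted(p for p, y in self.counts.items() if y > 0)

    def observed_indices(self) -> np.ndarray:
        """1-based indices of patterns with ``y > 0``, ascending."""
        return np.array(sorted(encode_pattern(p) for p, y in self.counts.items() if y > 0))

    def count_vector(self, indices: Iterable[int]) -> np.ndarray:
        """Counts aligned with the given 1-based pattern indices."""
        by_index = {encode_pattern(p): y for p, y in self.counts.items()}
        return np.array([by_index.get(k, 0) for k in indices], dtype=float)

    def dense_counts(self) -> np.ndarray:
        """Length-``2**n`` count vector indexed by ``k - 1``."""
        y = np.zeros(2**self.n)
        for pat, c in self.counts.items():
            y[encode_pattern(pat) - 1] = c
        return y


def lexicographic_order(counts: PatternCounts, include_zeros: bool = False) -> list[str]:
    """Patterns of a count table sorted as binary strings (= by index k)."""
    pats = [p for p, y in counts.counts.items() if include_zeros or y > 0]
    return sorted(pats)
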