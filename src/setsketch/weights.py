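"""Per-item multiplicities driving weighted (probability-Jaccard) sketching.

A weight is an item's relative frequency: count / total occurrences. Exact
counting uses a hash table; the feature-hashed alternative is a single-row
count-min structure that can only overestimate, trading memory for a small
upward bias on colliding keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hashing import hash_codes


@dataclass
class ExactCounter:
    """Exact per-code occurrence counts."""

    counts: dict[int, int] = field(default_factory=dict)
    total: int = 0

    def add(self, codes: np.ndarray) -> None:
        uniq, cnt = np.unique(np.asarray(codes, dtype=np.uint64), return_counts=True)
        for code, c in zip(uniq.tolist(), cnt.tolist()):
            self.counts[code] = self.counts.get(code, 0) + c
        self.total += int(len(codes))

    def count_of(self, code: int) -> int:
        return self.counts.get(int(code), 0)


@dataclass
class FeatureHashCounter:
    """Single-row count-min: cell index = hash(code) mod width. Estimated
    counts are never below the true count."""

    width: int
    hash_seed: int = 0
    cells: np.ndarray = field(init=False)
    total: int = 0

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("feature-hash width must be >= 1")
        self.cells = np.zeros(self.width, dtype=np.int64)

    def _indices(self, codes: np.ndarray) -> np.ndarray:
        return (hash_codes(codes, self.hash_seed) % np.uint64(self.width)).astype(
            np.int64
        )

    def add(self, codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.uint64)
        np.add.at(self.cells, self._indices(codes), 1)
        self.total += int(len(codes))

    def count_of(self, code: int) -> int:
        idx = self._indices(np.array([code], dtype=np.uint64))[0]
        return int(self.cells[idx])


#: feature-hash width used as the documented large-scale example configuration
DEFAULT_COUNTSKETCH_WIDTH = 5_000_000


def count_stream(codes, counter):
    """Tally a stream (iterable of arrays, or one array) into a counter."""
    if isinstance(codes, np.ndarray):
        counter.add(codes)
    else:
        for chunk in codes:
            counter.add(np.asarray(chunk, dtype=np.uint64))
    return counter


def weight_of(counter, code: int) -> float:
    """Relative frequency of a code: count / total occurrences (0.0 signals
    an unseen code in exact mode)."""
    if counter.total == 0:
        return 0.0
    return counter.count_of(code) / counter.total


def weights_for(counter, codes: np.ndarray) -> np.ndarray:
    """Vectorized weight lookup for a batch of codes."""
    codes = np.asarray(codes, dtype=np.uint64)
    if counter.total == 0:
        return np.zeros(len(codes), dtype=np.float64)
    if isinstance(counter, FeatureHashCounter):
        cnt = counter.cells[counter._indices(codes)]
    else:
        cnt = np.fromiter(
            (counter.count_of(int(c)) for c in codes), dtype=np.int64, count=len(codes)
        )
    return cnt / counter.total
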