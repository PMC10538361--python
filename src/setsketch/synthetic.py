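"""Synthetic inputs with known ground truth.

Set-level generators produce 64-bit code collections with exact overlap (the
primary oracle substrate: sketching consumes codes directly); sequence-level
generators exercise the whole pipeline including canonicalization. Every
generator is seed-deterministic and returns its ground truth alongside the
data. Distinctness of generated codes is guaranteed by passing distinct
integers through a bijective 64-bit mixer rather than by rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .estimators import probability_jaccard_exact
from .hashing import MASK64, mix64


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Two sets with n_a and n_b distinct items sharing exactly `overlap`."""

    n_a: int
    n_b: int
    overlap: int
    seed: int = 0
    weight_law: str = "uniform"  # uniform | geometric
    mutation_rate: float = 0.0

    def __post_init__(self):
        if self.overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap cannot exceed the smaller set")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must lie in [0, 1)")

    @property
    def true_jaccard(self) -> float:
        union = self.n_a + self.n_b - self.overlap
        return self.overlap / union if union else 1.0


def _distinct_codes(n: int, seed: int, stream: int = 0) -> np.ndarray:
    """n distinct pseudo-random 64-bit codes (bijective mixer over a range)."""
    base = (mix64(seed ^ (stream * 0x9E3779B97F4A7C15)) | 1) & MASK64
    idx = np.arange(n, dtype=np.uint64) + np.uint64(base)
    out = idx.copy()
    # splitmix64 finalizer, vectorized; bijective so distinct inputs stay distinct
    out ^= out >> np.uint64(30)
    out *= np.uint64(0xBF58476D1CE4E5B9)
    out ^= out >> np.uint64(27)
    out *= np.uint64(0x94D049BB133111EB)
    out ^= out >> np.uint64(31)
    return out


def gen_set_pair(spec: SyntheticPairSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """(codes_a, codes_b, exact Jaccard) with exact distinct counts/overlap."""
    total = spec.n_a + spec.n_b - spec.overlap
    codes = _distinct_codes(total, spec.seed)
    a = codes[: spec.n_a]
    b = codes[spec.n_a - spec.overlap :]
    return a, b, spec.true_jaccard


def _draw_weights(n: int, law: str, rng: np.random.Generator) -> np.ndarray:
    if law == "uniform":
        return rng.uniform(0.5, 1.5, size=n)
    if law == "geometric":
        return rng.geometric(0.25, size=n).astype(np.float64)
    raise ValueError(f"unknown weight law {law!r}")


def gen_weighted_pair(spec: SyntheticPairSpec) -> tuple[dict, dict, float]:
    """(weight map A, weight map B, exact probability Jaccard).

    One weight is drawn per union item, so an item shared by both multisets
    carries the same multiplicity in each — the regime (equal counts for
    shared items) in which registerwise value comparison estimates J_P.
    """
    a_codes, b_codes, _ = gen_set_pair(spec)
    rng = np.random.default_rng(mix64(spec.seed))
    union = spec.n_a + spec.n_b - spec.overlap
    w = _draw_weights(union, spec.weight_law, rng)
    wa = dict(zip(a_codes.tolist(), w[: spec.n_a]))
    wb = dict(zip(b_codes.tolist(), w[spec.n_a - spec.overlap :]))
    return wa, wb, probability_jaccard_exact(wa, wb)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def gen_sequence_pair(
    length: int, mutation_rate: float, seed: int = 0
) -> tuple[str, str]:
    """A random DNA sequence and a copy with independent per-base
    substitutions at the stated rate (always to a different base)."""
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation rate must lie in [0, 1)")
    rng = np.random.default_rng(mix64(seed))
    first = rng.integers(0, 4, size=length, dtype=np.uint8)
    second = first.copy()
    hits = np.flatnonzero(rng.random(length) < mutation_rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size, dtype=np.uint8)
        second[hits] = (second[hits] + shift) % 4
    return (
        _BASES[first].tobytes().decode("ascii"),
        _BASES[second].tobytes().decode("ascii"),
    )


def gen_cluster_panel(
    n_clusters: int,
    per_cluster: int,
    n_items: int,
    within_jaccard: float,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Code sets in similarity clusters: members of a cluster share a core so
    their pairwise Jaccard is ~within_jaccard; cross-cluster Jaccard is 0.

    Returns (code sets, cluster label per set). A member keeps a shared
    fraction s of its n_items codes with s/(2-s) = within_jaccard.
    """
    share = 2 * within_jaccard / (1 + within_jaccard)
    n_shared = int(round(share * n_items))
    sets, labels = [], []
    for c in range(n_clusters):
        core = _distinct_codes(n_shared, seed, stream=2 * c + 1)
        for g in range(per_cluster):
            own = _distinct_codes(
                n_items - n_shared, seed ^ mix64(c * 7919 + g + 1), stream=2 * c + 2
            )
            sets.append(np.concatenate([core, own]))
            labels.append(c)
    return sets, np.asarray(labels)


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> Path:
    """Write (id, sequence) records as FASTA (fixture helper)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return path


def write_weights_tsv(path: str | Path, features: list[tuple[str, float]]) -> Path:
    """Write key<TAB>weight rows (fixture helper)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, w in features:
            fh.write(f"{key}\t{w}\n")
    return path
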