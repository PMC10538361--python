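"""Streaming canonical k-mer codes from sequence or tabular inputs.

DNA k-mers are packed two bits per base (A=0, C=1, G=2, T=3, most significant
first) and canonicalized to the numerically smaller of the code and its
reverse complement, so strand choice never matters. Protein k-mers are packed
base-|alphabet|; with the default k, every code fits a 64-bit unsigned value.
Windows containing symbols outside the alphabet are skipped.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import alphabets
from ._kernels import dna_kmer_codes_kernel, radix_kmer_codes_kernel
from .hashing import hash_string, mix64

DEFAULT_DNA_K = 31  # odd default avoids palindromic self-reverse-complement k-mers


def max_k(alphabet: str) -> int:
    """Largest k with |alphabet|^k representable in 64 bits (DNA capped at 31)."""
    size = alphabets.ALPHABETS[alphabet].size
    k = int(64 / math.log2(size))
    while size**k > 2**64:
        k -= 1
    while size ** (k + 1) <= 2**64:
        k += 1
    if alphabet == alphabets.DNA:
        k = DEFAULT_DNA_K
    return k


@dataclass(frozen=True)
class KmerEncoding:
    """How residues become 64-bit k-mer codes."""

    alphabet: str = alphabets.DNA
    k: int = 0  # 0 = alphabet default

    def __post_init__(self):
        if self.alphabet not in alphabets.ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.k == 0:
            object.__setattr__(self, "k", max_k(self.alphabet))
        if self.k < 1:
            raise ValueError("k must be positive")
        size = alphabets.ALPHABETS[self.alphabet].size
        if self.k * math.log2(size) > 64:
            raise ValueError(f"k={self.k} over alphabet size {size} exceeds 64 bits")

    @property
    def bits_per_symbol(self) -> float:
        return math.log2(alphabets.ALPHABETS[self.alphabet].size)

    @property
    def canonicalize(self) -> bool:
        return alphabets.ALPHABETS[self.alphabet].canonicalize


class ParseError(ValueError):
    """Malformed sequence input, annotated with the failing record index."""


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_sequences(
    path: str | Path, format_hint: str | None = None
) -> Iterator[tuple[str, str]]:
    """Yield (identifier, residue string) from FASTA or FASTQ, plain or gzip.

    The format is autodetected from the first non-blank character unless a
    hint ('fasta'/'fastq') is given; FASTQ qualities are discarded. Truncated
    or malformed records raise :class:`ParseError` naming the record index.
    """
    handle = _open_maybe_gzip(path)
    with handle:
        first = handle.read(1)
        while first in ("\n", "\r", " ", "\t"):
            first = handle.read(1)
        if first == "":
            return
        handle.seek(0)
        fmt = format_hint
        if fmt is None:
            if first == ">":
                fmt = "fasta"
            elif first == "@":
                fmt = "fastq"
            else:
                raise ParseError(f"{path}: cannot detect FASTA/FASTQ format")
        index = 0
        try:
            for record in SeqIO.parse(handle, fmt):
                yield record.id, str(record.seq).upper()
                index += 1
        except ValueError as exc:
            raise ParseError(f"{path}: malformed {fmt} record {index}: {exc}") from exc


_DNA_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _base in enumerate("ACGT"):
    _DNA_LUT[ord(_base)] = _i
    _DNA_LUT[ord(_base.lower())] = _i


def _protein_lut(alphabet: str, table: dict[str, str] | None = None) -> np.ndarray:
    mapping = table if table is not None else alphabets.reduction_map(alphabet)
    reps = sorted(set(mapping.values()))
    lut = np.full(256, 255, dtype=np.uint8)
    for residue, rep in mapping.items():
        lut[ord(residue)] = reps.index(rep)
        lut[ord(residue.lower())] = reps.index(rep)
    return lut


def reduce_protein_sequence(
    sequence: str, alphabet: str, table: dict[str, str] | None = None
) -> str:
    """Replace each residue by its class representative under a reduced
    alphabet; residues outside the 20-letter alphabet become '*' (a skip
    sentinel that invalidates windows containing it)."""
    mapping = table if table is not None else alphabets.reduction_map(alphabet)
    return "".join(mapping.get(ch, "*") for ch in sequence.upper())


def canonical_kmer_codes(
    sequence: str, enc: KmerEncoding, table: dict[str, str] | None = None
) -> np.ndarray:
    """64-bit k-mer codes for one sequence (canonicalized for DNA)."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    if enc.alphabet == alphabets.DNA:
        symbols = _DNA_LUT[raw]
        return dna_kmer_codes_kernel(symbols, enc.k)
    symbols = _protein_lut(enc.alphabet, table)[raw]
    size = alphabets.ALPHABETS[enc.alphabet].size
    return radix_kmer_codes_kernel(symbols, enc.k, size)


@dataclass(frozen=True)
class ReadFilterConfig:
    """Error-k-mer filters for sequencing-read inputs: admit a k-mer only at
    its min_count-th occurrence, and/or keep each occurrence independently
    with probability downsample_fraction."""

    min_count: int = 1
    downsample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0 < self.downsample_fraction <= 1:
            raise ValueError("downsample_fraction must lie in (0, 1]")

    @property
    def is_passthrough(self) -> bool:
        return self.min_count == 1 and self.downsample_fraction == 1.0


class MinCountGate:
    """Streaming threshold gate: returns True exactly once per distinct code,
    on its threshold-th occurrence. Threshold 1 allocates no state."""

    def __init__(self, threshold: int):
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.threshold = threshold
        self._pending: dict[int, int] | None = None if threshold == 1 else {}

    def admit(self, code: int) -> bool:
        if self.threshold == 1:
            return True
        seen = self._pending.get(code, 0) + 1
        if seen >= self.threshold:
            # drop from the below-threshold dictionary; later copies are the
            # sketch's business (idempotent) not the gate's
            self._pending[code] = self.threshold  # sentinel: already admitted
            return seen == self.threshold
        self._pending[code] = seen
        return False

    def admit_array(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized gate over a code array (order-preserving)."""
        if self.threshold == 1:
            return np.ones(len(codes), dtype=bool)
        return np.fromiter(
            (self.admit(int(c)) for c in codes), dtype=bool, count=len(codes)
        )


def min_count_gate(code: int, threshold: int, state: dict[int, int]) -> bool:
    """Functional form of the streaming gate over an external count table."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if threshold == 1:
        return True
    seen = state.get(code, 0) + 1
    state[code] = seen
    return seen == threshold


class Downsampler:
    """Per-occurrence Bernoulli(fraction) keep/suppress decisions, seeded."""

    def __init__(self, fraction: float, seed: int = 0):
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        self.fraction = fraction
        self._rng = np.random.default_rng(mix64(seed ^ 0xA0761D6478BD642F))

    def keep(self, n: int = 1) -> np.ndarray:
        if self.fraction == 1.0:
            return np.ones(n, dtype=bool)
        return self._rng.random(n) < self.fraction


def downsample_gate(occurrence_count: int, fraction: float, rng) -> np.ndarray:
    """Keep mask for a run of occurrences (each kept independently)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return np.ones(occurrence_count, dtype=bool)
    return rng.random(occurrence_count) < fraction


def read_weighted_features(path: str | Path, seed: int = 0) -> list[tuple[str, float]]:
    """Key/weight pairs from a two-column TSV; duplicate keys sum their
    weights. Weights must be positive numbers."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["key", "weight"], dtype={"key": str}
        )
    except pd.errors.EmptyDataError:
        return []
    if len(df) == 0:
        return []
    if df["weight"].isna().any() or not np.issubdtype(df["weight"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric weight column")
    if (df["weight"] <= 0).any():
        raise ValueError(f"{path}: weights must be positive")
    grouped = df.groupby("key", sort=False)["weight"].sum()
    return list(grouped.items())


def weighted_features_to_codes(
    features: list[tuple[str, float]], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Hash string keys to 64-bit codes with the same avalanche hash used for
    k-mer codes; returns (codes, weights)."""
    codes = np.fromiter(
        (hash_string(key, seed) for key, _ in features),
        dtype=np.uint64,
        count=len(features),
    )
    weights = np.fromiter((w for _, w in features), dtype=np.float64, count=len(features))
    return codes, weights


def sequence_file_codes(
    path: str | Path,
    enc: KmerEncoding,
    filters: ReadFilterConfig | None = None,
    table: dict[str, str] | None = None,
) -> np.ndarray:
    """All (filtered) k-mer codes of a sequence file, in file order."""
    chunks = []
    gate = None
    sampler = None
    if filters is not None and not filters.is_passthrough:
        if filters.min_count > 1:
            gate = MinCountGate(filters.min_count)
        if filters.downsample_fraction < 1.0:
            sampler = Downsampler(filters.downsample_fraction, filters.seed)
    for _, seq in parse_sequences(path):
        codes = canonical_kmer_codes(seq, enc, table)
        if sampler is not None:
            codes = codes[sampler.keep(len(codes))]
        if gate is not None:
            codes = codes[gate.admit_array(codes)]
        if len(codes):
            chunks.append(codes)
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.concatenate(chunks)
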