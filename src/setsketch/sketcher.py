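"""High-level sketching pipeline shared by the library API and the CLI.

Builds untruncated sketches from item codes (or sequence files), pools the
register values across all inputs of an invocation to fit (a, b), then
finalizes every sketch with the shared parameters so they stay comparable.
One-permutation sketches are densified after finalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import kmers
from .core import (
    DEFAULT_M,
    DEFAULT_REGISTER_WIDTH,
    MODE_FULL,
    MODE_ONE_PERM,
    FinalSketch,
    SketchParams,
    UntruncatedSketch,
    densify,
    finalize,
    fit_parameters,
    q_for_width,
)
from .hashing import hash_codes
from .weights import ExactCounter, FeatureHashCounter, count_stream

logger = logging.getLogger("setsketch")


@dataclass(frozen=True)
class SketchConfig:
    """Everything that determines how items turn into registers."""

    m: int = DEFAULT_M
    seed: int = 0
    weighted: bool = False
    full_updates: bool = False  # force the full rule for unweighted sketches
    register_width: int = DEFAULT_REGISTER_WIDTH
    use_fast_log: bool = True
    countsketch_width: int = 0  # 0 = exact counting in weighted mode

    @property
    def mode(self) -> str:
        return MODE_FULL if (self.weighted or self.full_updates) else MODE_ONE_PERM

    @property
    def q(self) -> int:
        return q_for_width(self.register_width)


def sketch_codes(
    codes: np.ndarray,
    config: SketchConfig,
    weights: np.ndarray | None = None,
) -> UntruncatedSketch:
    """Sketch one dataset given its item codes (occurrences, not necessarily
    distinct). In weighted mode without explicit weights, multiplicities are
    counted and converted to relative frequencies first."""
    sketch = UntruncatedSketch(
        m=config.m,
        seed=config.seed,
        mode=config.mode,
        weighted=config.weighted,
        use_fast_log=config.use_fast_log,
    )
    codes = np.asarray(codes, dtype=np.uint64)
    if config.weighted and weights is None:
        codes, weights = _counted_weights(codes, config)
    hashes = hash_codes(codes, config.seed)
    sketch.add_hashes(hashes, weights if config.weighted else None)
    return sketch


def _counted_weights(codes: np.ndarray, config: SketchConfig):
    # Weights are occurrence counts rather than count/total: the probability
    # Jaccard is invariant under a per-set global scaling, and count weights
    # make the draws of items with equal multiplicity cancel exactly between
    # datasets, which is what the registerwise comparison relies on.
    if config.countsketch_width > 0:
        counter = FeatureHashCounter(config.countsketch_width, hash_seed=config.seed)
        count_stream(codes, counter)
        distinct = np.unique(codes)
        counts = counter.cells[counter._indices(distinct)].astype(np.float64)
    else:
        distinct, c = np.unique(codes, return_counts=True)
        counts = c.astype(np.float64)
    return distinct, counts


def finalize_sketches(
    sketches: list[UntruncatedSketch],
    config: SketchConfig,
    k: int = 0,
    alphabet: str = "",
    params: SketchParams | None = None,
) -> tuple[list[FinalSketch], SketchParams]:
    """Fit (a, b) from the pooled registers of all sketches (unless given),
    finalize each, and densify one-permutation sketches."""
    if params is None:
        pooled = np.concatenate([s.registers for s in sketches])
        params = fit_parameters(pooled, q=config.q, register_width=config.register_width)
        logger.info("fitted parameters a=%.6g b=%.8f q=%d", params.a, params.b, params.q)
    finals = []
    for s in sketches:
        f = finalize(s, params, k=k, alphabet=alphabet)
        if s.mode == MODE_ONE_PERM and f.empty_mask is not None:
            f = densify(f)
        finals.append(f)
    return finals, params


def sketch_sequence_files(
    paths,
    enc: kmers.KmerEncoding,
    config: SketchConfig,
    filters: kmers.ReadFilterConfig | None = None,
    params: SketchParams | None = None,
) -> tuple[list[FinalSketch], SketchParams]:
    """End-to-end: files -> k-mer codes -> finalized, comparable sketches."""
    raws = []
    for path in paths:
        codes = kmers.sequence_file_codes(path, enc, filters)
        if len(codes) == 0:
            raise ValueError(f"{path}: no k-mers survive parsing/filtering")
        raws.append(sketch_codes(codes, config))
    return finalize_sketches(
        raws, config, k=enc.k, alphabet=enc.alphabet, params=params
    )
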