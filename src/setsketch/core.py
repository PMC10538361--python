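"""SetSketch construction: full and one-permutation updates, parameter
fitting, finalization, densification, and merging.

A sketch accumulates, per register, the minimum of exponential draws seeded by
the input items (extended-precision, sentinel +inf when empty). Truncation to
integer registers is delayed to :func:`finalize`, which applies
``K' = floor(1 - log_b(K/a))`` clamped to ``[0, q+1]``. The rate ``a`` and log
base ``b`` are fitted from the pooled untruncated registers of all inputs
(:func:`fit_parameters`), so every sketch of an invocation shares them and
stays comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import (
    FAST_LOG_GUARD,
    fast_ln_array,
    fast_ln_scalar,
    full_update_batch,
    item_draws_kernel,
    one_perm_update_batch,
)
from .hashing import mix64

MODE_FULL = "full"
MODE_ONE_PERM = "one_permutation"

#: default number of registers
DEFAULT_M = 1024
#: default register width in bits
DEFAULT_REGISTER_WIDTH = 8


def q_for_width(register_width: int = DEFAULT_REGISTER_WIDTH) -> int:
    """One less than the maximum register value: q = 2^width - 2 (254 for 8-bit)."""
    return 2**register_width - 2


@dataclass(frozen=True)
class SketchParams:
    """Finalization parameters: exponential rate scale `a`, log base `b`,
    and register ceiling `q` (one less than the maximum register value)."""

    a: float
    b: float
    q: int = q_for_width()
    register_width: int = DEFAULT_REGISTER_WIDTH

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("rate scale a must be positive")
        if self.b <= 1:
            raise ValueError("log base b must exceed 1")
        # register_width 0 marks a width-less parameter set (e.g. analytic use)
        if self.register_width and self.q != 2**self.register_width - 2:
            raise ValueError("q must equal 2**register_width - 2")


class MaxTree:
    """Tournament tree of m-1 internal nodes maintaining the running maximum
    over a register array in O(log m) per (decreasing) register update."""

    def __init__(self, registers: np.ndarray):
        self.registers = registers
        m = len(registers)
        if m & (m - 1):
            raise ValueError("register count must be a power of two")
        self.m = m
        # heap layout: internal nodes at 1..m-1, leaves are the registers
        self._nodes = np.empty(max(m, 2), dtype=np.float64)
        self._rebuild()

    def _rebuild(self) -> None:
        m, regs, t = self.m, self.registers, self._nodes
        t[:] = -np.inf
        for i in range(m - 1, 0, -1):
            left, right = 2 * i, 2 * i + 1
            lv = t[left] if left < m else regs[left - m]
            rv = t[right] if right < m else regs[right - m]
            t[i] = max(lv, rv)

    def max(self) -> float:
        return float(self._nodes[1]) if self.m > 1 else float(self.registers[0])

    def update(self, value: float, index: int) -> float:
        """Record registers[index] = value (must not increase it); returns the
        new overall maximum."""
        if not 0 <= index < self.m:
            raise IndexError(f"register index {index} out of range [0, {self.m})")
        if value > self.registers[index]:
            raise ValueError("MaxTree updates may only decrease register values")
        regs, t, m = self.registers, self._nodes, self.m
        regs[index] = value
        i = (m + index) >> 1
        while i >= 1:
            left, right = 2 * i, 2 * i + 1
            lv = t[left] if left < m else regs[left - m]
            rv = t[right] if right < m else regs[right - m]
            v = max(lv, rv)
            if t[i] == v:
                break
            t[i] = v
            i >>= 1
        return self.max()

    @property
    def internal_nodes(self) -> np.ndarray:
        """The m-1 internal node values (root first)."""
        return self._nodes[1 : self.m]


@dataclass
class UntruncatedSketch:
    """Pre-finalization sketch: extended-precision minimum draws per register."""

    m: int = DEFAULT_M
    seed: int = 0
    mode: str = MODE_ONE_PERM
    weighted: bool = False
    use_fast_log: bool = True
    registers: np.ndarray = field(init=False)
    total_update_iterations: int = field(init=False, default=0)
    n_updates: int = field(init=False, default=0)

    def __post_init__(self):
        if self.m < 1 or self.m & (self.m - 1):
            raise ValueError("m must be a positive power of two")
        if self.weighted and self.mode != MODE_FULL:
            raise ValueError("weighted sketching requires full updates")
        self.registers = np.full(self.m, np.inf, dtype=np.float64)
        if self.mode == MODE_FULL:
            self._tree = np.full(self.m, np.inf, dtype=np.float64)
            self._perm = np.arange(self.m, dtype=np.int64)
            self._rbuf = np.zeros(self.m, dtype=np.int64)
        elif self.mode != MODE_ONE_PERM:
            raise ValueError(f"unknown sketch mode {self.mode!r}")

    @property
    def log2m(self) -> int:
        return self.m.bit_length() - 1

    def add_hashes(
        self, item_hashes: np.ndarray, weights: np.ndarray | float | None = None
    ) -> np.ndarray:
        """Add a batch of pre-hashed items; returns per-item inner-loop
        iteration counts (all ones in one-permutation mode)."""
        item_hashes = np.ascontiguousarray(item_hashes, dtype=np.uint64)
        n = len(item_hashes)
        iters = np.ones(n, dtype=np.int64)
        if self.mode == MODE_ONE_PERM:
            if weights is not None and np.any(np.asarray(weights) != 1.0):
                raise ValueError("weighted sketching requires full updates")
            one_perm_update_batch(self.registers, item_hashes, self.log2m)
        else:
            if weights is None:
                w = np.ones(n, dtype=np.float64)
            elif np.isscalar(weights):
                w = np.full(n, float(weights), dtype=np.float64)
            else:
                w = np.ascontiguousarray(weights, dtype=np.float64)
            if np.any(w <= 0):
                raise ValueError("item weights must be positive")
            full_update_batch(
                self.registers,
                self._tree,
                self._perm,
                self._rbuf,
                item_hashes,
                w,
                self.use_fast_log,
                iters,
            )
        self.total_update_iterations += int(iters.sum())
        self.n_updates += n
        return iters

    def max_register(self) -> float:
        if self.mode == MODE_FULL:
            return float(self._tree[1]) if self.m > 1 else float(self.registers[0])
        return float(self.registers.max())

    def copy(self) -> "UntruncatedSketch":
        out = UntruncatedSketch(
            m=self.m,
            seed=self.seed,
            mode=self.mode,
            weighted=self.weighted,
            use_fast_log=self.use_fast_log,
        )
        out.registers[:] = self.registers
        if self.mode == MODE_FULL:
            out._tree[:] = self._tree
        out.total_update_iterations = self.total_update_iterations
        out.n_updates = self.n_updates
        return out


@dataclass
class FinalSketch:
    """Finalized (truncated integer) sketch plus everything needed to decide
    whether two sketches are comparable."""

    registers: np.ndarray
    params: SketchParams
    m: int
    seed: int
    k: int = 0
    alphabet: str = ""
    mode: str = MODE_ONE_PERM
    weighted: bool = False
    densified: bool = False
    empty_mask: np.ndarray | None = None
    #: registers empty before densification (drives small-range cardinality)
    original_empty_count: int = 0

    def compatible_with(self, other: "FinalSketch") -> bool:
        return (
            self.m == other.m
            and self.params == other.params
            and self.seed == other.seed
            and self.k == other.k
            and self.alphabet == other.alphabet
            and self.mode == other.mode
            and self.weighted == other.weighted
        )

    def require_compatible(self, other: "FinalSketch") -> None:
        if not self.compatible_with(other):
            raise ValueError(
                "sketches are not comparable: m/params/seed/k/alphabet/mode must match"
            )


def item_draw_sequence(
    item_hash: int, m: int, weight: float = 1.0, count: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """First `count` (strictly increasing draw value, register index) pairs of
    the full-update stream for one item.

    The draw values are the running Kahan-compensated sums of exponential
    spacings Exp(W)/(m-j); the indices are a prefix of a Fisher-Yates
    permutation of 0..m-1. Deterministic in (item_hash, m, weight).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if m < 1 or m & (m - 1):
        raise ValueError("m must be a positive power of two")
    if count is None:
        count = m
    if not 0 <= count <= m:
        raise ValueError("count must lie in [0, m]")
    return item_draws_kernel(np.uint64(item_hash), m, float(weight), count)


def update_full(
    sketch: UntruncatedSketch, item_hash: int, weight: float = 1.0
) -> UntruncatedSketch:
    """Add one item via the full update rule (early abort at the tree max)."""
    if sketch.mode != MODE_FULL:
        raise ValueError("update_full requires a full-mode sketch")
    sketch.add_hashes(np.array([item_hash], dtype=np.uint64), float(weight))
    return sketch


def update_one_perm(sketch: UntruncatedSketch, item_hash: int) -> UntruncatedSketch:
    """Add one item via the one-permutation rule (touches at most one register)."""
    if sketch.mode != MODE_ONE_PERM:
        raise ValueError("update_one_perm requires a one-permutation sketch")
    if sketch.weighted:
        raise ValueError("weighted sketching requires full updates")
    sketch.add_hashes(np.array([item_hash], dtype=np.uint64))
    return sketch


def fit_parameters(
    pooled: np.ndarray, q: int = q_for_width(), register_width: int = DEFAULT_REGISTER_WIDTH
) -> SketchParams:
    """Fit (a, b) from pooled untruncated register values of all inputs:
    b = exp(ln(max/min)/q), a = max/b. Sentinel (+inf) entries are ignored."""
    pooled = np.asarray(pooled, dtype=np.float64)
    finite = pooled[np.isfinite(pooled)]
    if finite.size == 0:
        raise ValueError("parameter fitting needs at least one finite register value")
    if np.any(finite <= 0):
        raise ValueError("untruncated register values must be positive")
    hi = float(finite.max())
    lo = float(finite.min())
    if hi == lo:
        warnings.warn(
            "all pooled register values are equal; clamping log base to 1+1e-9",
            RuntimeWarning,
            stacklevel=2,
        )
        b = 1.0 + 1e-9
    else:
        b = math.exp(math.log(hi / lo) / q)
    return SketchParams(a=hi / b, b=b, q=q, register_width=register_width)


def finalize(
    sketch: UntruncatedSketch,
    params: SketchParams,
    k: int = 0,
    alphabet: str = "",
) -> FinalSketch:
    """Truncate to integer registers: K' = clamp(floor(1 - log_b(K/a)), 0, q+1);
    sentinel (+inf, empty) registers map to 0."""
    regs = sketch.registers
    empty = ~np.isfinite(regs)
    out = np.zeros(sketch.m, dtype=np.int64)
    fin = regs[~empty]
    if fin.size:
        vals = np.floor(1.0 - np.log(fin / params.a) / math.log(params.b))
        out[~empty] = np.clip(vals, 0, params.q + 1).astype(np.int64)
    return FinalSketch(
        registers=out,
        params=params,
        m=sketch.m,
        seed=sketch.seed,
        k=k,
        alphabet=alphabet,
        mode=sketch.mode,
        weighted=sketch.weighted,
        empty_mask=empty if empty.any() else None,
        original_empty_count=int(empty.sum()),
    )


def densify(sketch: FinalSketch) -> FinalSketch:
    """Fill empty registers of a finalized one-permutation sketch by copying
    non-empty registers chosen by a deterministic per-register probe sequence.
    Sketches without empty registers are returned unchanged."""
    if sketch.empty_mask is None or not sketch.empty_mask.any():
        return sketch
    if sketch.empty_mask.all():
        raise ValueError("cannot densify a sketch with no occupied registers")
    m = sketch.m
    regs = sketch.registers.copy()
    occupied = ~sketch.empty_mask
    source = sketch.registers  # copy only from originally occupied registers
    salt = mix64(sketch.seed ^ 0x5851F42D4C957F2D)
    for i in np.flatnonzero(sketch.empty_mask):
        attempt = 0
        while True:
            j = mix64((int(i) * 0x2545F4914F6CDD1D + attempt) ^ salt) % m
            if occupied[j]:
                regs[i] = source[j]
                break
            attempt += 1
    return replace(sketch, registers=regs, densified=True, empty_mask=None)


def merge_sketches(a, b):
    """Union sketch: elementwise min of untruncated registers, elementwise max
    of finalized ones. Equals the sketch of the concatenated inputs exactly."""
    if isinstance(a, UntruncatedSketch) and isinstance(b, UntruncatedSketch):
        if (a.m, a.seed, a.mode, a.weighted) != (b.m, b.seed, b.mode, b.weighted):
            raise ValueError("cannot merge sketches with different shapes or modes")
        out = a.copy()
        np.minimum(a.registers, b.registers, out=out.registers)
        if a.mode == MODE_FULL and a.m > 1:
            out._tree[: a.m] = MaxTree(out.registers)._nodes[: a.m]
        out.total_update_iterations = a.total_update_iterations + b.total_update_iterations
        out.n_updates = a.n_updates + b.n_updates
        return out
    if isinstance(a, FinalSketch) and isinstance(b, FinalSketch):
        a.require_compatible(b)
        regs = np.maximum(a.registers, b.registers)
        ea = a.empty_mask if a.empty_mask is not None else np.zeros(a.m, dtype=bool)
        eb = b.empty_mask if b.empty_mask is not None else np.zeros(b.m, dtype=bool)
        both_empty = ea & eb
        return replace(
            a,
            registers=regs,
            empty_mask=both_empty if both_empty.any() else None,
            original_empty_count=int(both_empty.sum()),
            densified=a.densified or b.densified,
        )
    raise TypeError("merge requires two sketches of the same stage")


def fast_log(x: float) -> float:
    """Approximate natural log from the float's integral representation.

    Monotone; for x>1 the ratio to ln(x) stays within (0.7, 1.42]; the
    magnitude of -fast_log(u) for u in (0,1) overestimates -ln(u) by at most
    the guard factor 1.42, which is what makes the guarded early-abort in the
    update loop conclusive.
    """
    if not (x > 0) or math.isinf(x):
        raise ValueError("fast_log requires a positive finite argument")
    return float(fast_ln_scalar(float(x)))


def fast_log_grid(xs: np.ndarray) -> np.ndarray:
    """Vectorized fast_log for grid scans."""
    xs = np.ascontiguousarray(xs, dtype=np.float64)
    if np.any(xs <= 0) or np.any(~np.isfinite(xs)):
        raise ValueError("fast_log requires positive finite arguments")
    return fast_ln_array(xs)


FAST_LOG_BOUND = FAST_LOG_GUARD
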