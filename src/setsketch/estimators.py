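"""Cardinality, Jaccard, containment, intersection and ANI estimation from
finalized sketches, plus the exact (unsketched) oracles.

The joint similarity estimator is closed-form. Registers hold truncated logs
of exponential minima; modelling register i of sketches A and B as minima of
independent exponentials over the exclusive and shared item groups gives

    E[D+/m] = 1 - log_b(b - alpha (b-1)),

where D+ counts registers with A > B and alpha = |A\\B|/|A u B|. Inverting
yields the estimator used here,

    alpha_hat = b (1 - b^(-D+/m)) / (b - 1),

and symmetrically beta_hat from D-; the Jaccard estimate is 1 - alpha - beta.
When the sets are mostly disjoint the primary estimate can leave the simplex
(alpha + beta > 1); the fallback then sets J = 0 and splits alpha/beta by the
cardinality estimates. Cardinality uses n_hat = m(1-1/b)/(a ln b sum b^(-K'_i)),
from E[b^(-K')] ~= (1-1/b)/(n a ln b) for a register built from n items.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MODE_ONE_PERM, FinalSketch, SketchParams


@dataclass(frozen=True)
class JointCounts:
    """Registerwise tallies: d_plus = #{A>B}, d_minus = #{A<B}, d_equal rest."""

    d_plus: int
    d_minus: int
    d_equal: int
    m: int

    def __post_init__(self):
        if self.d_plus + self.d_minus + self.d_equal != self.m:
            raise ValueError("joint counts must sum to m")


@dataclass(frozen=True)
class SimilarityEstimate:
    """Union-fraction estimates: alpha = |A\\B|/|AuB|, beta = |B\\A|/|AuB|,
    jaccard = 1 - alpha - beta; all clamped to the simplex."""

    alpha: float
    beta: float
    jaccard: float
    card_a: float
    card_b: float
    used_disjoint_fallback: bool


def joint_counts(a: FinalSketch, b: FinalSketch) -> JointCounts:
    """Exact registerwise D+/D-/equal tallies for two comparable sketches."""
    a.require_compatible(b)
    gt = int(np.count_nonzero(a.registers > b.registers))
    lt = int(np.count_nonzero(a.registers < b.registers))
    return JointCounts(d_plus=gt, d_minus=lt, d_equal=a.m - gt - lt, m=a.m)


def estimate_cardinality(s: FinalSketch) -> float:
    """Distinct-item count estimate from the register multiset and (a, b, q)."""
    regs = s.registers
    if not np.any(regs):
        return 0.0
    if s.mode == MODE_ONE_PERM:
        n_empty = s.original_empty_count
        if n_empty > 0:
            # balls-in-bins linear counting while some registers are empty
            return float(s.m * math.log(s.m / n_empty))
        return s.m * _rate_estimate(regs, s.params)
    return _rate_estimate(regs, s.params)


def _rate_estimate(regs: np.ndarray, params: SketchParams) -> float:
    lnb = math.log(params.b)
    total = float(np.exp(-regs.astype(np.float64) * lnb).sum())
    return len(regs) * (1.0 - 1.0 / params.b) / (params.a * lnb * total)


def _mu_simple(count: int, m: int, b: float) -> float:
    p = count / m
    return b * (1.0 - b**-p) / (b - 1.0)


def estimate_similarity(
    counts: JointCounts,
    params: SketchParams,
    card_a: float,
    card_b: float,
) -> SimilarityEstimate:
    """Closed-form joint similarity estimate with disjoint fallback."""
    alpha = _mu_simple(counts.d_plus, counts.m, params.b)
    beta = _mu_simple(counts.d_minus, counts.m, params.b)
    fallback = alpha + beta > 1.0
    if fallback:
        # mostly-disjoint regime: J pinned to 0, union split by cardinality
        denom = card_a + card_b
        alpha = card_a / denom if denom > 0 else 0.5
        beta = card_b / denom if denom > 0 else 0.5
        jaccard = 0.0
    else:
        alpha = min(max(alpha, 0.0), 1.0)
        beta = min(max(beta, 0.0), 1.0)
        # alpha + beta is commutative in IEEE arithmetic, so swapping the
        # input sketches preserves the Jaccard estimate bitwise
        jaccard = 1.0 - (alpha + beta)
    return SimilarityEstimate(
        alpha=alpha,
        beta=beta,
        jaccard=jaccard,
        card_a=card_a,
        card_b=card_b,
        used_disjoint_fallback=fallback,
    )


def compare_sketches(a: FinalSketch, b: FinalSketch) -> SimilarityEstimate:
    """Convenience: joint counts + cardinalities + similarity in one call."""
    counts = joint_counts(a, b)
    return estimate_similarity(
        counts, a.params, estimate_cardinality(a), estimate_cardinality(b)
    )


def ani_from_jaccard(j: float, k: int) -> float:
    """Average nucleotide identity from a Jaccard estimate via the Mash
    distance rescaling ANI = 1 + (1/k) ln(2J/(1+J)), clamped at zero."""
    if not 0 <= j <= 1:
        raise ValueError("Jaccard value must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    if j == 0.0:
        return 0.0
    return max(0.0, 1.0 + math.log(2.0 * j / (1.0 + j)) / k)


def derived_coefficients(
    j: float, card_a: float, card_b: float
) -> tuple[float, float, float]:
    """(containment of A in B, symmetric containment, intersection size) by
    inclusion-exclusion from a Jaccard estimate and two cardinalities."""
    if card_a < 0 or card_b < 0:
        raise ValueError("cardinalities must be non-negative")
    intersection = j / (1.0 + j) * (card_a + card_b) if j > 0 else 0.0
    if card_a == 0:
        raise ValueError("containment of an empty set is undefined")
    containment = min(1.0, intersection / card_a)
    smaller = min(card_a, card_b)
    symmetric = min(1.0, intersection / smaller) if smaller > 0 else 0.0
    return containment, symmetric, intersection


def exact_jaccard(a, b) -> float:
    """|A n B| / |A u B| over distinct codes (the estimation oracle)."""
    sa, sb = set(map(int, a)), set(map(int, b))
    if not sa and not sb:
        warnings.warn(
            "Jaccard of two empty sets defined as 1 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return len(sa & sb) / len(sa | sb)


def probability_jaccard_exact(wa: dict, wb: dict) -> float:
    """Brute-force probability Jaccard J_P of two weight maps.

    J_P = sum over keys d with both weights positive of
    1 / sum_d' max(wA(d')/wA(d), wB(d')/wB(d)); scale-invariant per map.
    """
    for name, w in (("A", wa), ("B", wb)):
        if w and not any(v > 0 for v in w.values()):
            raise ValueError(f"weight map {name} has no positive weights")
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
    # fixed summation order keeps the value bitwise symmetric in (A, B)
    universe = sorted(set(wa) | set(wb), key=repr)
    total = 0.0
    for d in universe:
        va, vb = wa.get(d, 0.0), wb.get(d, 0.0)
        if va <= 0 or vb <= 0:
            continue
        denom = 0.0
        for dp in universe:
            denom += max(wa.get(dp, 0.0) / va, wb.get(dp, 0.0) / vb)
        total += 1.0 / denom
    return min(total, 1.0)  # guard accumulated rounding above the simplex
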