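# Methods

## Sketch model

A dataset is reduced to `m` registers. Conceptually every item `d` supplies
one exponential draw per register, `h_i(d) ~ Exp(a·w(d))`, and register `i`
records the minimum draw seen. Registers are therefore independent
high-water-mark statistics of the whole input, which is what makes the joint
estimators below work. Accumulation keeps the untruncated minimum as a
64-bit float (sentinel `+inf` when empty); only a finalization step maps it
to an integer register via `K' = clamp(⌊1 − log_b(K/a)⌋, 0, q+1)`, so at
most `m` logarithms are spent per sketch regardless of input size. `q` is
one less than the maximum register value (254 for the 8-bit registers this
package writes); empty registers encode as 0.

Draws are generated per item from a splitmix64 counter stream seeded only by
the item's 64-bit hash and `m` — never by the dataset — so a shared item
produces bitwise-identical draws in every sketch. Uniform variates use 53
hash bits as `(u + 0.5)/2^53`, which can never be 0 or 1. The draw sequence
is produced in increasing order through the exponential-spacing recurrence
`x_j = x_{j−1} + Exp(w)/(m−j)` (Kahan-compensated), paired with a lazy
Fisher–Yates permutation for the register order; the update loop aborts as
soon as the running draw exceeds the current maximum register, maintained by
a tournament tree of `m−1` internal nodes in `O(log m)` per modification.
Over a long stream the mean inner-loop work per update settles near one
iteration; the suite asserts `< 3` over the last 10 % of a 2×10^5-item
stream at `m = 1024` (the decay has long converged by that size).

### Parameter fitting

`a` and `b` are fitted from the pooled untruncated registers of all inputs
of an invocation: `b = exp(ln(max/min)/q)`, `a = max/b`. This maps the
pooled maximum to register 0 and the pooled minimum to register `q`, using
the full register range with out-of-range clamps only for values outside the
pooled envelope (asserted `< 1 %` when parameters are fitted from the data).
A degenerate pool (all values equal) clamps `b` to `1 + 1e−9` with a
warning. Sketches are comparable only if `m`, `(a, b, q)`, seed, `k`,
alphabet, update mode and weighting all match; mismatches raise rather than
return numbers.

### One-permutation mode and densification

Unweighted sketching by default touches one register per item: the high
`log2 m` bits of the item hash select the register and a re-mixed copy of
the hash yields a unit-rate exponential value (a fresh avalanche pass is
used because fewer than 53 raw bits remain once the index bits are taken).
Small inputs leave registers empty; after finalization these are filled by
copying occupied registers chosen by a deterministic per-register probe
sequence (splitmix64 probes until an occupied register is hit). Densified
registers are marked, and the pre-densification empty count is retained
because cardinality estimation needs it.

### Fast logarithm and its guard

Exponential draws cost one `log` each. The update path first uses an
approximation from the float's integral representation,
`fast_ln(x) = 0.71·(e + f)` with `x = 2^e(1+f)`: it is monotone and
overestimates `−ln(u)` for `u ∈ (0,1)` by a multiplicative factor of at most
1.42 (the scale 0.71 = 1.42/2 makes that worst case exact, attained as
`u → 1⁻`; for `x > 1` the ratio to the true logarithm peaks at ≈ 1.0243).
A draw is treated as conclusively above the abort ceiling only if the fast
value divided by 1.42 still exceeds it; otherwise the exact logarithm is
computed and used. Every register write therefore uses exact values, and a
guarded build is bitwise identical to an exact-log build (asserted in the
suite).

## Estimators

With registers modelled as truncated logs of exponential minima over the
exclusive and shared item groups, the probability that a register of A
exceeds its counterpart in B is `1 − log_b(b − α(b−1))`, where
`α = |A\B|/|A∪B|`. Inverting gives the closed-form joint estimator used
here: `α̂ = b(1 − b^(−D+/m))/(b−1)`, symmetrically `β̂` from `D−`, and
`Ĵ = 1 − (α̂+β̂)`. The `b`-dependence corrects for distinct values
colliding in the same truncation cell. When the sets are nearly disjoint the
primary estimate can leave the simplex (`α̂+β̂ > 1`); the fallback then
reports `Ĵ = 0` and splits the union by the two cardinality estimates.
Estimates are clamped to the simplex, and the arithmetic is arranged so that
swapping the inputs preserves `Ĵ` bitwise.

Cardinality uses `n̂ = m(1−1/b)/(a·ln b·Σ_i b^(−K'_i))`, from
`E[b^(−K')] ≈ (1−1/b)/(n·a·ln b)` (integral approximation of the lattice
sum; its oscillatory error is far below sketch noise). One-permutation
sketches split the input across registers, so the same formula estimates
`n/m` and is multiplied by `m`; while any registers remain empty the
balls-in-bins (linear-counting) estimate `m·ln(m/V)` is used instead, `V`
the pre-densification empty count. An all-zero register array reports 0.

Derived quantities: intersection `= J/(1+J)·(n̂_A+n̂_B)`, containment
`= intersection/n̂_A`, symmetric containment `= intersection/min(n̂_A,n̂_B)`;
ANI `= max(0, 1 + ln(2J/(1+J))/k)`.

### Weighted mode

An item's weight multiplies its exponential rate, which divides its whole
draw sequence by `w`; comparing weighted sketches then estimates the
probability Jaccard `J_P` (brute-force oracle implemented for testing).
Multiplicities are tracked exactly by hash table or approximately by a
single-row count-min (feature-hashing) table, which can only overestimate.
The sketcher feeds raw occurrence counts as weights: `J_P` is invariant to a
global per-set scaling, and counts make the draws of shared items with equal
multiplicity cancel exactly between datasets, which the registerwise value
comparison requires. **Limitation:** when a shared item's multiplicity
differs between datasets (or pre-supplied weight scales differ), its
register values no longer coincide and the estimate is biased downward;
value-storing registers cannot distinguish "different winning item" from
"same item, different weight". The synthetic weighted pairs used for
validation therefore assign each shared item one common multiplicity —
the regime the estimator is designed for.

## LSH index

Level `i` uses superregisters of size `P(i) = min(2^i, 2i)` with `P(0) = 1`
(so levels 0..5 give sizes 1, 2, 4, 6, 8, 10). For `P ≤ 2` the `m/P`
superregisters partition the registers; for `P ≥ 4`, `8m/P` contiguous runs
at seeded random offsets are fixed at index construction. Each table maps
(level, position, value-tuple) to the ids holding that value; a size-`P`
superregister matches between sketches with probability `J^P` (verified
empirically; truncation-cell collisions add ~1 % per register, so measured
rates sit slightly above `J^P`). Queries scan levels from most to least
specific, collect distinct co-bucketed ids in discovery order up to
`⌈Os·k⌉` (oversampling `Os = 3` by default), exclude the query itself, then
keep the `k` candidates with the greatest estimated Jaccard (ties broken by
insertion order, identically in the exhaustive reference). Threshold mode
estimates every co-bucketed pair once and reports those at or above the
threshold.

Default table levels are `{P=1, P=2}`. For tightly clustered collections a
third level (`P = 4`) is recommended and used in the validation panel:
tight clusters make members share register values, so a single chance
collision at a coarse level floods a bucket with a whole cluster and can
crowd the candidate cap before a true neighbor appears; scanning a more
specific level first removes this failure mode (0 discrepant edges against
exhaustive KNN over 25 000 edges across 10 panel seeds, versus ~0.06 %
with two levels).

## Synthetic data

Generators return their ground truth alongside the data and are
deterministic in the seed. Code sets are made distinct by construction
(distinct integers through a bijective 64-bit mixer). Sequence pairs are
uniform-random DNA with independent per-base substitutions (always to a
different base), so expected identity is `1 − rate`; they exercise the whole
pipeline including canonical 2-bit encoding (A=0, C=1, G=2, T=3,
most-significant-first; the canonical form is the smaller of code and
reverse-complement code). Cluster panels share a per-cluster core such that
within-cluster Jaccard is `s/(2−s)` for shared fraction `s`, with disjoint
cross-cluster supports. What these do *not* emulate: genomic repeat
structure, indels, coverage bias, and correlated errors — so passing tests
demonstrate estimator correctness under the stated models, not robustness
to every artifact of real libraries.

## Reference study conditions

The recovery checks in `tests/test_acceptance.py` run at: Jaccard recovery
`m = 1024`, true `J ∈ {0.1, 0.3, 0.5, 0.7, 0.9}`, 100 replicate pairs of
1500-element sets each, mean error within `3·sqrt(J(1−J)/m)`; RMSE
monotonicity across `m ∈ {256, 1024, 4096}` on a fixed 36-pair panel;
cardinality `n = 10^5`, 50 replicates, median relative error ≤ 5 %;
weighted recovery over 100 pairs (uniform and geometric multiplicity laws)
against the brute-force `J_P`; superregister match rates over a
`J × P ∈ {0.3, 0.6, 0.9} × {1, 2, 4}` grid with 5 replicate pairs per cell
at 3 binomial standard errors (few enough registers that the ~1 %
collision drift stays inside the band it belongs to — it is part of the
measured quantity); KNN agreement on a 500-sketch, 50-cluster panel
(within-cluster J = 0.9, three table levels); ANI recovery on ten 1 Mbp
pairs at 1 % mutation within ±0.005 of 0.99. Problem sizes are chosen so
the whole suite runs in a few minutes on one core.

## Numerical and degenerate-input choices

Uniform variates exclude 0/1 by construction; Kahan summation bounds
spacing accumulation error; `b → 1` degeneracy is clamped with a warning;
the Jaccard of two empty sets is defined as 1 with a warning; containment
of an empty reference set raises; densifying a fully empty sketch raises;
comparing sketches with mismatched headers raises. DNA `k` defaults to 31
(odd, avoiding palindromic self-reverse-complement k-mers) although 32
two-bit bases would fit; protein k-mers are base-|Σ| packed so the default
`k` is the largest with `|Σ|^k ≤ 2^64` (20 letters → 14; 14 → 16; 8 → 21;
6 → 24). Ambiguous residues invalidate every window containing them. The
shipped reduced-alphabet partitions (14/8/6 classes; Murphy-style 8,
Dayhoff 6, and a 14-class refinement of the 8-class grouping) are defaults
and can be replaced by any user table.
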