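"""Numba kernels for sketch construction and k-mer encoding.

Everything here operates on plain numpy arrays so the surrounding modules can
stay readable; the kernels are the only performance-critical code in the
package. All randomness is counter-based (splitmix64 streams seeded from the
item hash), so a given item produces bitwise-identical draws in every sketch.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64_1 = np.uint64(1)
PHI = np.uint64(0x9E3779B97F4A7C15)
MIX1 = np.uint64(0xBF58476D1CE4E5B9)
MIX2 = np.uint64(0x94D049BB133111EB)
SH30 = np.uint64(30)
SH27 = np.uint64(27)
SH31 = np.uint64(31)
SH11 = np.uint64(11)
#: salt mixed into the one-permutation value draw so the register-selection
#: bits and the value bits come from independent avalanche passes
OP_SALT = np.uint64(0xD6E8FEB86659FD93)
INV_2_53 = 2.0 ** -53

#: scale of the integral-representation logarithm: 1.42/(2 ln 2) * ln 2
FAST_LOG_COEF = 0.71
#: worst-case multiplicative overestimation of -fast_ln(u) for u in (0,1)
FAST_LOG_GUARD = 1.42


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> SH30)) * MIX1
    z = (z ^ (z >> SH27)) * MIX2
    return z ^ (z >> SH31)


@njit(cache=True)
def _mix64_jit(z):
    return _mix64(z)


def mix64_py(x: int) -> int:
    """splitmix64 finalizer (Python wrapper over the jitted scalar)."""
    return int(_mix64_jit(np.uint64(x)))


@njit(cache=True)
def hash_codes_kernel(codes, salt):
    out = np.empty(codes.shape[0], dtype=np.uint64)
    for i in range(codes.shape[0]):
        out[i] = _mix64(codes[i] ^ salt)
    return out


@njit(cache=True, inline="always")
def _fast_ln(x):
    # exponent-plus-mantissa approximation of log2, scaled so that the
    # multiplicative overestimate of -fast_ln(u), u<1, never exceeds 1.42
    mant, exp2 = math.frexp(x)
    return FAST_LOG_COEF * (exp2 - 2.0 + 2.0 * mant)


@njit(cache=True)
def fast_ln_scalar(x):
    return _fast_ln(x)


@njit(cache=True)
def fast_ln_array(xs):
    out = np.empty(xs.shape[0], dtype=np.float64)
    for i in range(xs.shape[0]):
        out[i] = _fast_ln(xs[i])
    return out


@njit(cache=True, inline="always")
def _item_state(item_hash, m):
    return _mix64(item_hash ^ _mix64(np.uint64(m) * PHI))


@njit(cache=True, inline="always")
def _u53(bits):
    return (np.float64(bits >> SH11) + 0.5) * INV_2_53


@njit(cache=True, inline="always")
def _tree_update(regs, tree, m, j):
    # tournament tree: internal nodes tree[1..m-1], leaves are the registers
    i = (m + j) >> 1
    while i >= 1:
        left = 2 * i
        right = left + 1
        lv = tree[left] if left < m else regs[left - m]
        rv = tree[right] if right < m else regs[right - m]
        v = lv if lv >= rv else rv
        if tree[i] == v:
            break
        tree[i] = v
        i >>= 1
    return tree[1]


@njit(cache=True)
def full_update_batch(regs, tree, perm, rbuf, hashes, weights, use_fast, iters):
    """Add a batch of items to a full-update sketch (register array + tree).

    regs: float64[m] minimum draws (inf = empty); tree: float64[m] tournament
    internal nodes (tree[0] unused); perm/rbuf: int64[m] scratch for the lazy
    Fisher-Yates shuffle; weights: float64[n] per-item rates; iters: int64[n]
    records the number of inner-loop iterations per update.
    """
    m = regs.shape[0]
    n = hashes.shape[0]
    for t in range(n):
        w = weights[t]
        state = _item_state(hashes[t], m)
        kmax = tree[1] if m > 1 else regs[0]
        rv = 0.0
        comp = 0.0
        used = 0
        it = 0
        for j in range(m):
            it += 1
            state = state + PHI
            u = _u53(_mix64(state))
            denom = (m - j) * w
            if use_fast:
                ft = -_fast_ln(u) / denom
                if (rv + ft) / FAST_LOG_GUARD > kmax:
                    break
            term = -math.log(u) / denom
            # Kahan-compensated accumulation of the exponential spacings
            y = term - comp
            s = rv + y
            comp = (s - rv) - y
            rv = s
            if rv > kmax:
                break
            state = state + PHI
            r = j + np.int64(_mix64(state) % np.uint64(m - j))
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp
            rbuf[j] = r
            used = j + 1
            i = perm[j]
            if rv < regs[i]:
                regs[i] = rv
                if m > 1:
                    kmax = _tree_update(regs, tree, m, i)
                else:
                    kmax = rv
        iters[t] = it
        # undo the partial Fisher-Yates shuffle (identity restored in reverse)
        for j in range(used - 1, -1, -1):
            r = rbuf[j]
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp


@njit(cache=True)
def item_draws_kernel(item_hash, m, w, count):
    """First `count` (draw value, register index) pairs for one item.

    Mirrors full_update_batch's stream exactly; tests assert the two agree.
    """
    vals = np.empty(count, dtype=np.float64)
    idxs = np.empty(count, dtype=np.int64)
    perm = np.arange(m, dtype=np.int64)
    state = _item_state(item_hash, m)
    rv = 0.0
    comp = 0.0
    for j in range(count):
        state = state + PHI
        u = _u53(_mix64(state))
        term = -math.log(u) / ((m - j) * w)
        y = term - comp
        s = rv + y
        comp = (s - rv) - y
        rv = s
        state = state + PHI
        r = j + np.int64(_mix64(state) % np.uint64(m - j))
        tmp = perm[j]
        perm[j] = perm[r]
        perm[r] = tmp
        vals[j] = rv
        idxs[j] = perm[j]
    return vals, idxs


@njit(cache=True)
def one_perm_update_batch(regs, hashes, log2m):
    """One-permutation updates: high hash bits pick the register, a re-mixed
    copy of the hash provides the unit-rate exponential value."""
    shift = np.uint64(64 - log2m)
    for t in range(hashes.shape[0]):
        h = hashes[t]
        i = 0 if log2m == 0 else np.int64(h >> shift)
        u = _u53(_mix64(h + OP_SALT))
        v = -math.log(u)
        if v < regs[i]:
            regs[i] = v


@njit(cache=True)
def dna_kmer_codes_kernel(symbols, k):
    """Canonical 2-bit DNA k-mer codes (A=0,C=1,G=2,T=3, MSB-first).

    symbols: uint8 array with 0..3 for bases and 255 for anything else;
    invalid symbols reset the window. Emits min(code, revcomp-code).
    """
    n = symbols.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64)
    out = np.empty(n - k + 1, dtype=np.uint64)
    mask = np.uint64(0xFFFFFFFFFFFFFFFF) >> np.uint64(64 - 2 * k)
    rcshift = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    three = np.uint64(3)
    fwd = np.uint64(0)
    rc = np.uint64(0)
    run = 0
    cnt = 0
    for pos in range(n):
        c = symbols[pos]
        if c > 3:
            run = 0
            fwd = np.uint64(0)
            rc = np.uint64(0)
            continue
        cc = np.uint64(c)
        fwd = ((fwd << two) | cc) & mask
        rc = (rc >> two) | ((three - cc) << rcshift)
        run += 1
        if run >= k:
            out[cnt] = fwd if fwd <= rc else rc
            cnt += 1
    return out[:cnt]


@njit(cache=True)
def radix_kmer_codes_kernel(symbols, k, radix):
    """Base-`radix` packed k-mer codes for non-DNA alphabets (no strand
    canonicalization); invalid symbols (255) reset the window."""
    n = symbols.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64)
    out = np.empty(n - k + 1, dtype=np.uint64)
    r = np.uint64(radix)
    top = np.uint64(1)
    for _ in range(k - 1):
        top = top * r
    window = np.empty(k, dtype=np.uint64)
    code = np.uint64(0)
    run = 0
    cnt = 0
    wpos = 0
    for pos in range(n):
        c = symbols[pos]
        if c >= radix:
            run = 0
            code = np.uint64(0)
            wpos = 0
            continue
        cc = np.uint64(c)
        if run >= k:
            code = code - window[wpos] * top
        window[wpos] = cc
        wpos = (wpos + 1) % k
        code = code * r + cc
        run += 1
        if run >= k:
            out[cnt] = code
            cnt += 1
    return out[:cnt]
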