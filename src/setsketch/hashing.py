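"""64-bit avalanche hashing shared by every input kind.

All item identities (k-mer codes, string keys from tabular input) pass through
the same splitmix64 finalizer so that identical items produce identical
register draws in every sketch, which joint estimation requires.
"""

from __future__ import annotations

import numpy as np

from ._kernels import hash_codes_kernel, mix64_py

MASK64 = (1 << 64) - 1
#: splitmix64 stream increment (golden-ratio constant)
PHI64 = 0x9E3779B97F4A7C15


def mix64(x: int) -> int:
    """splitmix64 finalizer of a 64-bit integer (pure-Python reference)."""
    return mix64_py(x & MASK64)


def seed_salt(seed: int) -> int:
    """Derive the per-invocation hashing salt from a user seed."""
    return mix64((seed & MASK64) * PHI64 & MASK64)


def hash_codes(codes: np.ndarray, seed: int = 0) -> np.ndarray:
    """Hash an array of 64-bit item codes into avalanche-mixed item hashes."""
    codes = np.ascontiguousarray(codes, dtype=np.uint64)
    return hash_codes_kernel(codes, np.uint64(seed_salt(seed)))


def hash_string(key: str, seed: int = 0) -> int:
    """Hash a text key to a 64-bit code: FNV-1a fold, then the same finalizer."""
    h = 0xCBF29CE484222325
    for byte in key.encode("utf-8"):
        h = ((h ^ byte) * 0x100000001B3) & MASK64
    return mix64(h ^ seed_salt(seed))
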