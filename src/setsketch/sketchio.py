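"""Binary sketch file format.

Little-endian header followed by the register block. The header fully
determines comparability; readers refuse mismatched magic/version and
truncated files. Only 8-bit registers are written; the width field exists so
readers can reject other widths explicitly.

Layout: magic "DSK2" (4s), version (u32), register width in bits (u8),
m (u64), k (u32), alphabet id (u8), flags (u8: weighted|one_perm|densified|
finalized), seed (u64), a (f64), b (f64), q (u32), then m register bytes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from . import alphabets
from .core import MODE_FULL, MODE_ONE_PERM, FinalSketch, SketchParams

MAGIC = b"DSK2"
VERSION = 1
_HEADER = struct.Struct("<4sIBQIBBQddI")

FLAG_WEIGHTED = 1
FLAG_ONE_PERM = 2
FLAG_DENSIFIED = 4
FLAG_FINALIZED = 8


class SketchFormatError(ValueError):
    """Unreadable or incompatible sketch file."""


def write_sketch(path: str | Path, sketch: FinalSketch) -> Path:
    if sketch.params.register_width != 8:
        raise SketchFormatError("only 8-bit registers are written")
    flags = FLAG_FINALIZED
    if sketch.weighted:
        flags |= FLAG_WEIGHTED
    if sketch.mode == MODE_ONE_PERM:
        flags |= FLAG_ONE_PERM
    if sketch.densified:
        flags |= FLAG_DENSIFIED
    header = _HEADER.pack(
        MAGIC,
        VERSION,
        sketch.params.register_width,
        sketch.m,
        sketch.k,
        alphabets.ALPHABET_IDS.get(sketch.alphabet, 255),
        flags,
        sketch.seed & (2**64 - 1),
        sketch.params.a,
        sketch.params.b,
        sketch.params.q,
    )
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sketch.registers.astype(np.uint8).tobytes())
    return path


def read_sketch(path: str | Path) -> FinalSketch:
    data = Path(path).read_bytes()
    if len(data) < _HEADER.size:
        raise SketchFormatError(f"{path}: truncated header")
    magic, version, width, m, k, alpha_id, flags, seed, a, b, q = _HEADER.unpack_from(
        data
    )
    if magic != MAGIC:
        raise SketchFormatError(f"{path}: bad magic {magic!r}")
    if version != VERSION:
        raise SketchFormatError(f"{path}: unsupported version {version}")
    if width != 8:
        raise SketchFormatError(f"{path}: unsupported register width {width}")
    if m == 0:
        raise SketchFormatError(f"{path}: header-only file (m = 0)")
    if len(data) != _HEADER.size + m:
        raise SketchFormatError(f"{path}: register block truncated")
    regs = np.frombuffer(data, dtype=np.uint8, offset=_HEADER.size).astype(np.int64)
    return FinalSketch(
        registers=regs,
        params=SketchParams(a=a, b=b, q=q, register_width=width),
        m=int(m),
        seed=int(seed),
        k=int(k),
        alphabet=alphabets.ALPHABET_FROM_ID.get(alpha_id, ""),
        mode=MODE_ONE_PERM if flags & FLAG_ONE_PERM else MODE_FULL,
        weighted=bool(flags & FLAG_WEIGHTED),
        densified=bool(flags & FLAG_DENSIFIED),
    )


def is_sketch_file(path: str | Path) -> bool:
    try:
        with open(path, "rb") as fh:
            return fh.read(4) == MAGIC
    except OSError:
        return False
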