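"""Sequence alphabets and reduced amino-acid classes.

The reduced alphabets merge chemically similar residues so that distant
homologs still share k-mers. The 8-class partition follows Murphy et al.'s
widely used grouping, the 6-class partition the classic Dayhoff groups, and
the 14-class partition refines the 8-class one by splitting the large
hydrophobic/acidic classes. All three are defaults only: any partition can be
supplied as a two-column TSV (residue<TAB>class representative) and loaded
with :func:`load_reduction_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

DNA = "DNA2"
PROTEIN20 = "protein20"
PROTEIN14 = "protein14"
PROTEIN8 = "protein8"
PROTEIN6 = "protein6"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_GROUPS = {
    PROTEIN14: ["LVIM", "C", "A", "G", "S", "T", "P", "F", "WY", "E", "Q", "DN", "KR", "H"],
    PROTEIN8: ["LVIMC", "AG", "ST", "P", "FYW", "EDNQ", "KR", "H"],
    PROTEIN6: ["LVIMC", "AGSTP", "FWY", "EDNQ", "KR", "H"],
}


def reduction_map(alphabet: str) -> dict[str, str]:
    """Residue -> class-representative map for a reduced protein alphabet."""
    if alphabet == PROTEIN20:
        return {aa: aa for aa in AMINO_ACIDS}
    if alphabet not in _GROUPS:
        raise ValueError(f"unknown reduced alphabet {alphabet!r}")
    table: dict[str, str] = {}
    for group in _GROUPS[alphabet]:
        for residue in group:
            table[residue] = group[0]
    return table


def load_reduction_table(path: str | Path) -> dict[str, str]:
    """User-supplied partition: TSV rows of residue<TAB>class representative."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or len(parts[0]) != 1 or len(parts[1]) != 1:
            raise ValueError(f"{path}:{lineno}: expected residue<TAB>representative")
        table[parts[0].upper()] = parts[1].upper()
    return table


@dataclass(frozen=True)
class AlphabetInfo:
    name: str
    size: int
    canonicalize: bool


ALPHABETS = {
    DNA: AlphabetInfo(DNA, 4, True),
    PROTEIN20: AlphabetInfo(PROTEIN20, 20, False),
    PROTEIN14: AlphabetInfo(PROTEIN14, 14, False),
    PROTEIN8: AlphabetInfo(PROTEIN8, 8, False),
    PROTEIN6: AlphabetInfo(PROTEIN6, 6, False),
}

#: stable one-byte ids used in the sketch file header
ALPHABET_IDS = {DNA: 0, PROTEIN20: 1, PROTEIN14: 2, PROTEIN8: 3, PROTEIN6: 4}
ALPHABET_FROM_ID = {v: k for k, v in ALPHABET_IDS.items()}
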