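"""Sequence scanning for the Class-3 minor-site NLS motif.

Class-3 NLSs carry the eight-residue signature KRx(W/F/Y)xxAF: the KR pair
anchors the P1'/P2' pockets, the aromatic at the fourth position stacks in
the P4' pocket, and the AF tail provides the P7'/P8' contacts.  Patterns
are ordered per-position constraints; the bracket syntax ``KRx[WFY]xxAF``
uses uppercase letters as literals, ``x`` as a wildcard over the 20
standard residues, and ``[...]`` for alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import ContractError, FormatError

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "CLASS3",
    "parse_pattern",
    "scan",
    "scan_fasta",
]

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    """Ordered position constraints; ``None`` marks a wildcard position."""

    constraints: tuple[frozenset[str] | None, ...]
    text: str = ""

    def __post_init__(self):
        if not self.constraints:
            raise ContractError("empty motif pattern")
        for c in self.constraints:
            if c is not None and (not c or not c <= STANDARD_AA):
                raise ContractError(f"invalid position constraint {c!r}")

    def __len__(self) -> int:
        return len(self.constraints)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.constraints):
            return False
        for ch, constraint in zip(window, self.constraints):
            if constraint is None:
                if ch not in STANDARD_AA:  # wildcards never match X/B/Z/*
                    return False
            elif ch not in constraint:
                return False
        return True


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    start: int  # 1-based
    end: int  # inclusive, start + len(pattern) - 1
    substring: str
    aromatic: str  # identity of the W/F/Y position (4th), '' if wildcard


def parse_pattern(text: str) -> MotifPattern:
    """Parse bracket syntax, e.g. ``KRx[WFY]xxAF``."""
    constraints: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "x":
            constraints.append(None)
            i += 1
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ContractError(f"unclosed '[' in pattern {text!r}")
            constraints.append(frozenset(text[i + 1:j].upper()))
            i = j + 1
        elif ch.isalpha():
            constraints.append(frozenset(ch.upper()))
            i += 1
        else:
            raise ContractError(f"unexpected character {ch!r} in {text!r}")
    return MotifPattern(tuple(constraints), text)


#: the Class-3 signature KRx(W/F/Y)xxAF
CLASS3 = parse_pattern("KRx[WFY]xxAF")
#: index (0-based) of the aromatic position in the Class-3 motif
_AROMATIC_POS = 3


def scan(sequence: str, pattern: MotifPattern = CLASS3,
         sequence_id: str = "") -> list[MotifMatch]:
    """All (overlapping) windows matching the pattern, ascending start,
    1-based coordinates.  Input is uppercased; wildcard positions match
    only the 20 standard letters."""
    seq = sequence.upper()
    plen = len(pattern)
    out = []
    for i in range(len(seq) - plen + 1):
        window = seq[i:i + plen]
        if pattern.matches(window):
            aromatic = ""
            if (_AROMATIC_POS < plen
                    and pattern.constraints[_AROMATIC_POS] is not None
                    and len(pattern.constraints[_AROMATIC_POS]) > 1):
                aromatic = window[_AROMATIC_POS]
            out.append(MotifMatch(sequence_id, i + 1, i + plen,
                                  window, aromatic))
    return out


def _validate_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}, line {lineno}: expected a '>' header before "
                    f"sequence data")
            return
    raise FormatError(f"{path}: empty FASTA file")


def scan_fasta(path: str | Path, pattern: MotifPattern = CLASS3
               ) -> tuple[list[MotifMatch], int]:
    """Scan every record of a FASTA file.

    Returns (all matches, number of records with at least one match).
    """
    path = Path(path)
    _validate_fasta(path)
    matches: list[MotifMatch] = []
    n_carriers = 0
    for record in SeqIO.parse(str(path), "fasta"):
        hits = scan(str(record.seq), pattern, sequence_id=record.id)
        matches.extend(hits)
        if hits:
            n_carriers += 1
    return matches, n_carriers


def count_carriers(sequences: Iterable[str],
                   pattern: MotifPattern = CLASS3) -> int:
    """Number of sequences containing at least one match."""
    return sum(1 for s in sequences if scan(s, pattern))
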