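"""P/P' pocket nomenclature for the importin α NLS-binding sites.

The receptor presents two peptide-binding grooves.  At the **minor site**
the pocket formed by two conserved tryptophans (mouse numbering W399 and
W357) is called P2'; the peptide residue occupying it is the P2' residue,
the preceding residue is P1' and residues downstream are P3', P4', ....
At the **major site** the pocket between W231 and W184 is called P3 (W142
lines P5 further along), with P1, P2 upstream and P4, P5, P6 downstream.

This module locates the anchor residue of a bound peptide geometrically,
indexes peptide positions relative to it, classifies minor-site KR
occupancy (P1' = K, P2' = R), and tabulates the packaged survey of
peptide-bound importin α crystal structures by those rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .chem import TRP_RING_ATOMS
from .errors import ContractError, OccupancyError
from .structure import ComplexStructure, Residue, ResidueKey

__all__ = [
    "PocketDefinition",
    "PositionAssignment",
    "Table1Record",
    "KRCall",
    "MOUSE_POCKETS",
    "find_anchor_residue",
    "assign_positions",
    "classify_kr_p1p2",
    "classify_assignment_kr",
    "load_table1",
    "tabulate_table1",
    "CATEGORIES",
]

CATEGORIES = ("major_only", "two_copies", "bipartite", "minor_only")

#: label index of the anchor pocket: minor anchor is P2', major anchor is P3
ANCHOR_INDEX = {"minor": 2, "major": 3}
#: valid label index span per site (P0'..P8' minor, P1..P6 major)
LABEL_SPAN = {"minor": (0, 8), "major": (1, 6)}


def position_label(site: str, index: int) -> str:
    return f"P{index}'" if site == "minor" else f"P{index}"


@dataclass(frozen=True)
class PocketDefinition:
    """Anchor pocket of one binding site, in the receptor's own numbering."""

    site: str  # "minor" or "major"
    pocket_trps: tuple[int, int]  # residue numbers of the two pocket Trps
    extra_trps: tuple[int, ...] = ()  # e.g. W142 lining P5 at the major site
    numbering_species: str = "mouse"

    @property
    def anchor_label(self) -> str:
        return position_label(self.site, ANCHOR_INDEX[self.site])


#: pocket tryptophans in mouse importin α numbering
MOUSE_POCKETS = {
    "minor": PocketDefinition("minor", (399, 357)),
    "major": PocketDefinition("major", (231, 184), extra_trps=(142,)),
}


@dataclass
class PositionAssignment:
    """Mapping of pocket labels to peptide residues of one chain."""

    site: str
    mapping: dict[str, ResidueKey]
    peptide_chain: str
    omitted: list[str] = field(default_factory=list)

    def residue(self, structure: ComplexStructure, label: str) -> Residue:
        return structure.residue(self.mapping[label])


@dataclass(frozen=True)
class Table1Record:
    """One row of the packaged crystal-structure survey."""

    pdb_id: str
    category: str
    peptide: str
    minor_seq: str  # P1'..P5' letters, '?' = not resolved, '' = site empty
    major_seq: str  # P1..P6 letters
    species: str


@dataclass(frozen=True)
class KRCall:
    """Result of the KR-at-P1'P2' classification."""

    value: bool
    indeterminate: bool = False

    def __bool__(self) -> bool:
        return self.value


# ---------------------------------------------------------------------------
# anchor detection and position assignment
# ---------------------------------------------------------------------------

def _pocket_ring_coords(structure: ComplexStructure, receptor_chain: str,
                        res_seq: int) -> np.ndarray:
    res = structure.find_residue(receptor_chain, res_seq)
    if res is None or res.res_name != "TRP":
        raise ContractError(
            f"pocket residue {receptor_chain}:{res_seq} is not a TRP "
            f"in {structure.id}")
    missing = [a for a in TRP_RING_ATOMS if a not in res.atoms]
    if missing:
        raise ContractError(
            f"pocket TRP {receptor_chain}:{res_seq} missing ring atoms "
            f"{missing}")
    return res.coords(TRP_RING_ATOMS)


def find_anchor_residue(structure: ComplexStructure,
                        pocket: PocketDefinition,
                        receptor_chain: str | None = None,
                        peptide_chains: list[str] | None = None,
                        max_ring_distance: float = 6.0) -> Residue:
    """Locate the peptide residue occupying the anchor pocket.

    The anchor is the peptide residue minimizing the sum, over the two
    pocket tryptophans, of the minimum distance from its sidechain heavy
    atoms to the indole ring atoms; it must lie within ``max_ring_distance``
    Å of both rings, otherwise the site is considered unoccupied.
    """
    if receptor_chain is None:
        receptors = structure.chains_with_role("receptor")
        if not receptors:
            raise ContractError(f"no receptor chain in {structure.id}")
        receptor_chain = receptors[0]
    if peptide_chains is None:
        peptide_chains = structure.chains_with_role("peptide")
    if not peptide_chains:
        raise OccupancyError(f"{structure.id}: no peptide chain present")

    rings = [_pocket_ring_coords(structure, receptor_chain, seq)
             for seq in pocket.pocket_trps]

    best: tuple[float, Residue] | None = None
    for chain in peptide_chains:
        for res in structure.chain_residues(chain):
            side = res.sidechain_atoms()
            coords = (np.array([a.coords for a in side]) if side
                      else np.array([res.atoms["CA"].coords])
                      if "CA" in res.atoms else None)
            if coords is None:
                continue
            dmins = [float(cdist(coords, ring).min()) for ring in rings]
            if max(dmins) > max_ring_distance:
                continue
            score = sum(dmins)
            if best is None or score < best[0]:
                best = (score, res)
    if best is None:
        raise OccupancyError(
            f"{structure.id}: no peptide residue within {max_ring_distance} Å "
            f"of both pocket rings ({pocket.site} site unoccupied)")
    return best[1]


def assign_positions(structure: ComplexStructure,
                     anchor: Residue | ResidueKey,
                     site: str,
                     span: tuple[int, int] | None = None
                     ) -> PositionAssignment:
    """Index peptide residues around the anchor with P/P' labels.

    Minor site: anchor -> P2', anchor−1 -> P1', anchor+k -> P(k+2)'.
    Major site: anchor -> P3, anchor−1 -> P2, anchor+k -> P(3+k).
    Labels whose residue falls outside the chain are omitted (reported in
    ``omitted``); an anchor at a chain terminus is not an error.
    """
    if site not in ANCHOR_INDEX:
        raise ContractError(f"unknown site {site!r}")
    if not isinstance(anchor, Residue):
        anchor = structure.residue(tuple(anchor))
    chain_res = structure.chain_residues(anchor.chain_id)
    idx = next(i for i, r in enumerate(chain_res) if r.key == anchor.key)
    base = ANCHOR_INDEX[site]
    lo, hi = span if span is not None else LABEL_SPAN[site]
    mapping: dict[str, ResidueKey] = {}
    omitted: list[str] = []
    for k in range(lo, hi + 1):
        offset = k - base
        j = idx + offset
        label = position_label(site, k)
        if 0 <= j < len(chain_res):
            mapping[label] = chain_res[j].key
        else:
            omitted.append(label)
    return PositionAssignment(site, mapping, anchor.chain_id, omitted)


# ---------------------------------------------------------------------------
# KR classification and the packaged survey table
# ---------------------------------------------------------------------------

def classify_kr_p1p2(minor_seq: str) -> KRCall:
    """True iff the printed minor-site string has K at P1' and R at P2'.

    The printed strings are left-aligned at P1' (first letter = P1').
    Unresolved positions ('?') make the call indeterminate -> False.
    """
    s = minor_seq.strip().upper()
    if len(s) < 2:
        return KRCall(False, indeterminate=True)
    p1, p2 = s[0], s[1]
    if "?" in (p1, p2):
        return KRCall(False, indeterminate=True)
    return KRCall(p1 == "K" and p2 == "R")


def classify_assignment_kr(structure: ComplexStructure,
                           assignment: PositionAssignment) -> KRCall:
    """Structure-based KR call from an actual minor-site assignment."""
    if assignment.site != "minor":
        raise ContractError("KR classification applies to the minor site")
    letters = []
    for label in ("P1'", "P2'"):
        key = assignment.mapping.get(label)
        if key is None:
            return KRCall(False, indeterminate=True)
        letters.append(structure.residue(key).one_letter)
    return KRCall(letters[0] == "K" and letters[1] == "R")


def load_table1() -> list[Table1Record]:
    """Load the packaged survey of peptide-bound importin α PDB entries."""
    path = resources.files("nlsgeom").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna("")
    return [Table1Record(r.pdb_id, r.category, r.peptide,
                         r.minor_seq, r.major_seq, r.species)
            for r in df.itertuples()]


def tabulate_table1(records: list[Table1Record]
                    ) -> dict[str, dict[str, int]]:
    """Per-category totals and KR-at-P1'P2' counts."""
    counts = {c: {"n_total": 0, "n_kr": 0, "n_indeterminate": 0}
              for c in CATEGORIES}
    for rec in records:
        if rec.category not in counts:
            counts[rec.category] = {"n_total": 0, "n_kr": 0,
                                    "n_indeterminate": 0}
        bucket = counts[rec.category]
        bucket["n_total"] += 1
        call = classify_kr_p1p2(rec.minor_seq)
        if call.value:
            bucket["n_kr"] += 1
        if call.indeterminate and rec.minor_seq.strip():
            bucket["n_indeterminate"] += 1
    return counts
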