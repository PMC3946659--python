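"""PDB structure I/O and in-memory model.

Coordinate files are parsed with gemmi and converted into a light-weight
:class:`ComplexStructure` that records, for every residue, its PDB identity
(chain, residue number, insertion code, residue name) and its atoms after
alternate-location resolution.  Chains are tagged with a *role* — receptor,
peptide or other — either supplied by the caller or auto-assigned (the
longest chain is the receptor; remaining chains of at most 30 residues are
peptides, as NLS peptides are short compared to the armadillo-repeat
domain).

Altloc resolution keeps, per (chain, res_seq, icode, atom_name), the
location with the highest occupancy; ties are broken toward the
lexicographically first altloc identifier, so parsing is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import FormatError, IntegrityError, LookupError_

__all__ = [
    "AtomRecord",
    "Residue",
    "ResidueKey",
    "ComplexStructure",
    "read_structure",
    "read_models",
    "write_structure",
    "extract_sequence",
    "select_atoms",
    "coords_of",
    "THREE_TO_ONE",
]

#: mapping of the 20 standard residues to one-letter codes; everything else
#: (phosphoserine SEP, unknown ligands, ...) becomes 'X'
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: backbone heavy atoms; everything else heavy is "sidechain" (CB included)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

MAX_PEPTIDE_CHAIN_LEN = 30

ResidueKey = tuple[str, int, str]  # (chain_id, res_seq, icode)


@dataclass
class AtomRecord:
    """One atom after altloc resolution."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hydrogen: bool = False
    het: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise IntegrityError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"occupancy {self.occupancy} outside [0,1] for atom "
                f"{self.name}; clamping",
                stacklevel=2,
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)


@dataclass
class Residue:
    """A residue with its resolved atoms, keyed by atom name."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms.values() if not a.is_hydrogen]

    def sidechain_atoms(self) -> list[AtomRecord]:
        """Heavy atoms excluding the backbone (CB included)."""
        return [
            a
            for a in self.atoms.values()
            if not a.is_hydrogen and a.name not in BACKBONE_ATOMS
        ]

    def coords(self, atom_names: Iterable[str]) -> np.ndarray:
        return np.array([self.atoms[n].coords for n in atom_names])


@dataclass
class ComplexStructure:
    """An ordered collection of residues plus chain-role annotations."""

    id: str
    residues: list[Residue]
    chain_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self._index: dict[ResidueKey, Residue] = {}
        for res in self.residues:
            if res.key in self._index:
                raise IntegrityError(f"duplicate residue {res.key} in {self.id}")
            self._index[res.key] = res
        if not self.chain_roles:
            self.chain_roles = _auto_roles(self.residues)

    # -- lookups ---------------------------------------------------------
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self.residues:
            seen.setdefault(res.chain_id, None)
        return list(seen)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        out = [r for r in self.residues if r.chain_id == chain_id]
        if not out:
            raise LookupError_(f"chain {chain_id!r} not found in {self.id}")
        return out

    def chains_with_role(self, role: str) -> list[str]:
        return [c for c in self.chains() if self.chain_roles.get(c) == role]

    def residue(self, key: ResidueKey) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise LookupError_(f"residue {key} not found in {self.id}") from None

    def get_residue(self, key: ResidueKey) -> Residue | None:
        return self._index.get(key)

    def find_residue(self, chain_id: str, res_seq: int) -> Residue | None:
        return self._index.get((chain_id, res_seq, ""))

    # -- geometry --------------------------------------------------------
    def transformed(self, transform) -> "ComplexStructure":
        """Return a deep copy with ``transform`` applied to every atom."""
        new_residues = []
        for res in self.residues:
            atoms = {
                n: replace(a, coords=transform.apply(a.coords))
                for n, a in res.atoms.items()
            }
            new_residues.append(replace(res, atoms=atoms))
        return ComplexStructure(self.id, new_residues, dict(self.chain_roles))

    def copy(self) -> "ComplexStructure":
        new_residues = [
            replace(r, atoms={n: replace(a, coords=a.coords.copy())
                              for n, a in r.atoms.items()})
            for r in self.residues
        ]
        return ComplexStructure(self.id, new_residues, dict(self.chain_roles))


def _auto_roles(residues: Sequence[Residue]) -> dict[str, str]:
    sizes: dict[str, int] = {}
    for res in residues:
        sizes[res.chain_id] = sizes.get(res.chain_id, 0) + 1
    if not sizes:
        return {}
    receptor = max(sizes, key=lambda c: (sizes[c], c))
    roles = {}
    for chain, n in sizes.items():
        if chain == receptor:
            roles[chain] = "receptor"
        elif n <= MAX_PEPTIDE_CHAIN_LEN:
            roles[chain] = "peptide"
        else:
            roles[chain] = "other"
    return roles


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _resolve_altlocs(groups: dict[str, list]) -> dict[str, AtomRecord]:
    """Keep the highest-occupancy location per atom name (tie -> first altloc)."""
    resolved: dict[str, AtomRecord] = {}
    for name, candidates in groups.items():
        best = min(candidates, key=lambda a: (-a.occupancy, a.altloc))
        resolved[name] = best
    return resolved


def _convert_model(model: gemmi.Model, struct_id: str,
                   chain_roles: Mapping[str, str] | None) -> ComplexStructure:
    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            groups: dict[str, list[AtomRecord]] = {}
            het = gres.het_flag == "H"
            for atom in gres:
                rec = AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                    occupancy=atom.occ,
                    bfactor=atom.b_iso,
                    is_hydrogen=atom.is_hydrogen(),
                    het=het,
                )
                groups.setdefault(atom.name, []).append(rec)
            if not groups:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    res_seq=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    res_name=gres.name,
                    atoms=_resolve_altlocs(groups),
                )
            )
    return ComplexStructure(struct_id, residues,
                            dict(chain_roles) if chain_roles else {})


def read_models(path: str | Path,
                chain_roles: Mapping[str, str] | None = None
                ) -> list[ComplexStructure]:
    """Read a PDB file; each MODEL block becomes one :class:`ComplexStructure`."""
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    structures = []
    for i, model in enumerate(st):
        sid = path.stem if len(st) == 1 else f"{path.stem}/model{model.num or i + 1}"
        cs = _convert_model(model, sid, chain_roles)
        if cs.residues:
            structures.append(cs)
    if not structures:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return structures


def read_structure(path: str | Path,
                   chain_roles: Mapping[str, str] | None = None
                   ) -> ComplexStructure:
    """Read a single-model PDB file (first model of a multi-model file)."""
    return read_models(path, chain_roles)[0]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _to_gemmi(structures: Sequence[ComplexStructure], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for i, cs in enumerate(structures):
        model = gemmi.Model(i + 1)
        for chain_id in cs.chains():
            chain = gemmi.Chain(chain_id)
            for res in cs.chain_residues(chain_id):
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.res_seq, res.icode or " ")
                gres.het_flag = "H" if any(a.het for a in res.atoms.values()) else "A"
                for atom in res.atoms.values():
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or "X")
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.bfactor
                    if atom.altloc:
                        ga.altloc = atom.altloc
                    gres.add_atom(ga)
                chain.add_residue(gres)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: ComplexStructure | Sequence[ComplexStructure],
                    path: str | Path) -> None:
    """Write one structure (or a sequence, as MODEL blocks) in PDB format."""
    if isinstance(structure, ComplexStructure):
        structures = [structure]
        name = structure.id
    else:
        structures = list(structure)
        name = structures[0].id if structures else "nlsgeom"
    st = _to_gemmi(structures, name)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# sequence and selection
# ---------------------------------------------------------------------------

def extract_sequence(structure: ComplexStructure, chain_id: str) -> str:
    """One-letter sequence of a chain in file order; non-standard residues -> X."""
    return "".join(r.one_letter for r in structure.chain_residues(chain_id))


def select_atoms(structure: ComplexStructure,
                 chains: Iterable[str] | None = None,
                 res_seqs: Iterable[int] | None = None,
                 res_names: Iterable[str] | None = None,
                 atom_names: Iterable[str] | None = None,
                 include_hydrogens: bool = True,
                 missing: list | None = None
                 ) -> list[tuple[Residue, AtomRecord]]:
    """Select atoms by chain / residue number / residue name / atom name.

    Atoms are returned in (chain, res_seq, icode, atom_name) order.  When
    ``atom_names`` is given, residues passing the other filters but missing
    one of those atoms are reported into ``missing`` (if provided) instead
    of raising.  An empty result is not an error.
    """
    chains = set(chains) if chains is not None else None
    res_seqs = set(res_seqs) if res_seqs is not None else None
    res_names = set(res_names) if res_names is not None else None
    wanted = list(atom_names) if atom_names is not None else None

    out: list[tuple[Residue, AtomRecord]] = []
    for res in structure.residues:
        if chains is not None and res.chain_id not in chains:
            continue
        if res_seqs is not None and res.res_seq not in res_seqs:
            continue
        if res_names is not None and res.res_name not in res_names:
            continue
        if wanted is None:
            names = sorted(res.atoms)
        else:
            names = []
            for n in wanted:
                if n in res.atoms:
                    names.append(n)
                elif missing is not None:
                    missing.append((res.key, n))
            names.sort()
        for n in names:
            atom = res.atoms[n]
            if atom.is_hydrogen and not include_hydrogens:
                continue
            out.append((res, atom))
    out.sort(key=lambda pair: (pair[0].chain_id, pair[0].res_seq,
                               pair[0].icode, pair[1].name))
    return out


def coords_of(selection: Sequence[tuple[Residue, AtomRecord]]) -> np.ndarray:
    """Stack the coordinates of a selection into an (n, 3) array."""
    if not selection:
        return np.zeros((0, 3))
    return np.array([atom.coords for _, atom in selection])
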