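"""Synthetic structures, ensembles, decoys and sequences with known truth.

Everything the analysis stages consume can be generated here without any
download: a toy receptor–peptide complex whose anchor residue is placed
between two pocket tryptophans; noisy superposable ensembles with
position-specific isotropic Gaussian coordinate noise plus optional rigid
jitter; docking-decoy sets with a constructed pass fraction; indole pairs
at requested centroid separation / interplanar angle / lateral offset; and
sequence sets with an exact number of motif carriers.  Toy structures are
geometrically valid PDB but not stereochemically refined — sufficient
because every in-scope analysis is purely geometric.  All generators are
deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .chem import TRP_FIVE_RING, TRP_SIX_RING
from .errors import ConstructionError, ContractError
from .filtering import FilterSpec
from .motifs import CLASS3, STANDARD_AA, MotifPattern
from .positions import PositionAssignment
from .structure import (AtomRecord, ComplexStructure, ONE_TO_THREE, Residue,
                        ResidueKey)
from .superpose import RigidTransform

__all__ = [
    "SyntheticEnsembleSpec",
    "make_toy_complex",
    "perturb_ensemble",
    "make_decoys",
    "make_stacked_indoles",
    "make_sequences",
    "write_fasta",
    "random_rigid_transform",
]

BOND = 1.39  # aromatic C-C bond length, Å


# ---------------------------------------------------------------------------
# idealized indole template (planar, in the xy-plane)
# ---------------------------------------------------------------------------

def _indole_template() -> dict[str, np.ndarray]:
    """Planar indole: six-membered ring centered at the origin, fused
    five-membered ring sharing the CD2-CE2 edge, plus in-plane CB/CA stubs."""
    atoms: dict[str, np.ndarray] = {}
    six_order = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")
    for k, name in enumerate(six_order):
        theta = math.radians(90.0 - 60.0 * k)
        atoms[name] = np.array([BOND * math.cos(theta),
                                BOND * math.sin(theta), 0.0])
    p_cd2, p_ce2 = atoms["CD2"], atoms["CE2"]
    mid = (p_cd2 + p_ce2) / 2.0
    u = mid / np.linalg.norm(mid)  # outward from hexagon center
    side = float(np.linalg.norm(p_ce2 - p_cd2))
    apothem = side / (2.0 * math.tan(math.pi / 5.0))
    radius = side / (2.0 * math.sin(math.pi / 5.0))
    center = mid + apothem * u
    a_cd2 = math.atan2(*(p_cd2 - center)[[1, 0]])
    a_ce2 = math.atan2(*(p_ce2 - center)[[1, 0]])
    step = (a_cd2 - a_ce2 + math.pi) % (2 * math.pi) - math.pi  # ±72°
    for k, name in enumerate(("NE1", "CD1", "CG"), start=1):
        theta = a_ce2 - k * step
        atoms[name] = center + radius * np.array([math.cos(theta),
                                                  math.sin(theta), 0.0])
    cg_dir = (atoms["CG"] - center) / np.linalg.norm(atoms["CG"] - center)
    atoms["CB"] = atoms["CG"] + 1.5 * cg_dir
    atoms["CA"] = atoms["CB"] + 1.53 * cg_dir
    return atoms


_INDOLE = _indole_template()


def _trp_residue(chain: str, res_seq: int,
                 placement) -> Residue:
    """A TRP residue from the indole template under a coordinate mapping."""
    atoms = {}
    for name, xy in _INDOLE.items():
        atoms[name] = AtomRecord(name=name, element=name[0],
                                 coords=placement(xy))
    return Residue(chain, res_seq, "", "TRP", atoms)


# ---------------------------------------------------------------------------
# stacked indole pairs
# ---------------------------------------------------------------------------

def make_stacked_indoles(centroid_distance: float,
                         interplanar_angle: float = 0.0,
                         lateral_offset: float = 0.0,
                         res_seqs: tuple[int, int] = (399, 357),
                         chain: str = "A") -> ComplexStructure:
    """Two TRP residues whose six-membered rings realize the requested
    centroid separation, interplanar angle (degrees) and lateral offset.

    Ring A lies in the xy-plane with its six-ring centroid at the origin
    (normal +z); ring B is rotated about the in-plane x-axis and its
    six-ring centroid placed at lateral offset along x and the remaining
    separation along z.
    """
    if centroid_distance <= 0:
        raise ConstructionError("centroid distance must be positive")
    if lateral_offset > centroid_distance:
        raise ConstructionError(
            f"offset {lateral_offset} exceeds centroid distance "
            f"{centroid_distance}")
    dz = math.sqrt(centroid_distance ** 2 - lateral_offset ** 2)
    rot = Rotation.from_euler("x", interplanar_angle, degrees=True).as_matrix()
    shift = np.array([lateral_offset, 0.0, dz])

    res_a = _trp_residue(chain, res_seqs[0], lambda xy: xy.copy())
    res_b = _trp_residue(chain, res_seqs[1], lambda xy: rot @ xy + shift)

    ring_names = set(TRP_SIX_RING) | set(TRP_FIVE_RING)
    pa = np.array([res_a.atoms[n].coords for n in ring_names])
    pb = np.array([res_b.atoms[n].coords for n in ring_names])
    dmin = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min()
    if dmin < 0.8:
        raise ConstructionError(
            f"rings overlap (closest atoms {dmin:.2f} Å apart)")
    return ComplexStructure("stacked_indoles", [res_a, res_b],
                            {chain: "receptor"})


# ---------------------------------------------------------------------------
# toy receptor-peptide complex
# ---------------------------------------------------------------------------

def _sidechain_atoms(letter: str, ca: np.ndarray) -> dict[str, np.ndarray]:
    """Schematic sidechain extending +z from Cα; full atoms for K/R/W/F/Y."""
    rel = {}
    if letter == "G":
        return rel
    rel["CB"] = (0.0, 0.0, 1.53)
    if letter == "K":
        rel.update({"CG": (0.0, 0.3, 2.8), "CD": (0.0, 0.0, 4.0),
                    "CE": (0.0, 0.3, 5.2), "NZ": (0.0, 0.0, 6.4)})
    elif letter == "R":
        rel.update({"CG": (0.0, 0.3, 2.8), "CD": (0.0, 0.0, 4.0),
                    "NE": (0.0, 0.3, 5.2), "CZ": (0.0, 0.0, 6.4),
                    "NH1": (0.9, 0.0, 7.3), "NH2": (-0.9, 0.0, 7.3)})
    elif letter == "W":
        # indole plane vertical (normal +y), six-ring centroid 3.5 Å above CA
        for name, xy in _INDOLE.items():
            if name in ("CA", "CB"):
                continue
            rel[name] = (xy[0], 0.0, 3.5 + xy[1])
    elif letter in ("F", "Y"):
        order = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        for k, name in enumerate(order):
            theta = math.radians(90.0 - 60.0 * k)
            rel[name] = (BOND * math.cos(theta), 0.0,
                         3.2 + BOND * math.sin(theta))
        if letter == "Y":
            rel["OH"] = (0.0, 0.0, 3.2 + BOND + 1.36)
    return {n: ca + np.asarray(v) for n, v in rel.items() if v is not None}


def _peptide_residue(chain: str, res_seq: int, letter: str,
                     ca: np.ndarray) -> Residue:
    atoms = {
        "N": AtomRecord("N", "N", ca + np.array([-1.2, 0.8, 0.2])),
        "CA": AtomRecord("CA", "C", ca.copy()),
        "C": AtomRecord("C", "C", ca + np.array([1.2, 0.8, -0.2])),
        "O": AtomRecord("O", "O", ca + np.array([1.4, 2.0, 0.2])),
    }
    for name, pos in _sidechain_atoms(letter, ca).items():
        atoms[name] = AtomRecord(name, name[0], pos)
    return Residue(chain, res_seq, "", ONE_TO_THREE.get(letter, "GLY"), atoms)


def default_anchor_index(sequence: str) -> int:
    """0-based index of the R of the first KR pair (the P2' anchor)."""
    i = sequence.upper().find("KR")
    if i < 0:
        raise ConstructionError(f"no KR pair in {sequence!r}")
    return i + 1


def make_toy_complex(seed: int = 0,
                     peptide_seq: str = "GSWAGRKRTWRDAF",
                     anchor_index: int | None = None,
                     ring_separation: float = 8.0,
                     ring_height: float = 5.8,
                     pocket_res_seqs: tuple[int, int] = (399, 357),
                     n_scaffold: int = 31,
                     receptor_chain: str = "A",
                     peptide_chain: str = "B",
                     extra_peptide_offset: np.ndarray | None = None
                     ) -> ComplexStructure:
    """Toy minor-site complex: two pocket TRPs sandwiching the anchor.

    The peptide runs along x with 3.8 Å Cα spacing and sidechains extending
    +z; the anchor residue (by default the R of the first KR pair) sits at
    x = 0 with its sidechain tip between the two pocket indole rings, which
    face each other across y at ``ring_separation``.  A zigzag glycine
    scaffold makes the receptor the longest chain and gives the ensemble
    fits a well-conditioned Cα set.  ``extra_peptide_offset`` adds a second,
    rigidly shifted peptide copy as chain after the first (for two-copy
    fixtures).
    """
    seq = peptide_seq.upper()
    if anchor_index is None:
        anchor_index = default_anchor_index(seq)
    if not 0 <= anchor_index < len(seq):
        raise ConstructionError("anchor index outside the peptide")
    if ring_separation <= 0:
        raise ConstructionError("ring separation must be positive")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []

    # receptor scaffold: three glycines lining the peptide groove (so a
    # 5 Å binding shell has enough Cα atoms for a fit), then a
    # non-collinear trace away from the site
    for i in range(n_scaffold):
        if i < 3:
            ca = np.array([4.0 * (i - 1), 4.5, 0.3 * i])
        else:
            ca = np.array([3.5 * (i - n_scaffold / 2),
                           14.0 + 1.5 * math.sin(i),
                           1.2 * math.cos(i)])
        ca = ca + rng.normal(0.0, 0.01, 3)
        residues.append(_peptide_residue(receptor_chain, i + 1, "G", ca))

    # pocket tryptophans: parallel rings facing each other across y
    half = ring_separation / 2.0
    for res_seq, y in zip(pocket_res_seqs, (-half, +half)):
        def place(xy, y=y):
            # template xy-plane mapped to the xz-plane at height ring_height
            return np.array([xy[0], y, ring_height + xy[1]])
        residues.append(_trp_residue(receptor_chain, res_seq, place))

    # peptide chain(s)
    chains = [(peptide_chain, np.zeros(3))]
    if extra_peptide_offset is not None:
        next_chain = chr(ord(peptide_chain) + 1)
        chains.append((next_chain, np.asarray(extra_peptide_offset, float)))
    for chain_id, offset in chains:
        for i, letter in enumerate(seq):
            ca = np.array([3.8 * (i - anchor_index), 0.0, 0.0]) + offset
            residues.append(_peptide_residue(chain_id, i + 1, letter, ca))

    roles = {receptor_chain: "receptor"}
    for chain_id, _ in chains:
        roles[chain_id] = "peptide"
    return ComplexStructure("toy_complex", residues, roles)


# ---------------------------------------------------------------------------
# noisy ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Recipe for a superposable ensemble with known coordinate noise."""

    n_structures: int
    sigma: float  # Å, per coordinate, isotropic Gaussian
    monitored_atoms: tuple[tuple[ResidueKey, str], ...]
    rigid_jitter: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ContractError("sigma must be >= 0")
        if self.n_structures < 2:
            raise ContractError("need at least 2 structures")


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 15.0) -> RigidTransform:
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    R = Rotation.from_quat(quat).as_matrix()
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform(R, t)


def perturb_ensemble(base: ComplexStructure,
                     spec: SyntheticEnsembleSpec
                     ) -> dict[str, ComplexStructure]:
    """Copies of ``base`` with iid Gaussian noise on the monitored atoms
    (fit atoms untouched), each under an arbitrary proper rigid transform
    when ``rigid_jitter`` is set.  Reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    out: dict[str, ComplexStructure] = {}
    for i in range(spec.n_structures):
        copy = base.copy()
        copy.id = f"{base.id}_s{i:03d}"
        for key, atom_name in spec.monitored_atoms:
            res = copy.get_residue(tuple(key))
            if res is None or atom_name not in res.atoms:
                raise ContractError(
                    f"monitored atom {key}:{atom_name} not in base structure")
            res.atoms[atom_name].coords = (
                res.atoms[atom_name].coords + rng.normal(0.0, spec.sigma, 3)
                if spec.sigma > 0 else res.atoms[atom_name].coords)
        if spec.rigid_jitter:
            copy = copy.transformed(random_rigid_transform(rng))
            copy.id = f"{base.id}_s{i:03d}"
        out[copy.id] = copy
    return out


# ---------------------------------------------------------------------------
# decoy sets for the distance filter
# ---------------------------------------------------------------------------

def make_decoys(base: ComplexStructure, n: int, inside_fraction: float,
                spec: FilterSpec, assignment: PositionAssignment,
                receptor_chain: str | None = None,
                seed: int = 0
                ) -> tuple[dict[str, ComplexStructure], dict[str, bool]]:
    """Decoy ensemble with exactly ⌊inside_fraction·n⌋ models passing.

    Passing models have every monitored atom strictly inside its cutoff;
    the rest have at least one monitored atom strictly outside.  Returns
    (models, truth) with truth[model_id] = should_pass.
    """
    if not 0.0 <= inside_fraction <= 1.0:
        raise ContractError("inside_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if receptor_chain is None:
        receptors = base.chains_with_role("receptor")
        receptor_chain = receptors[0] if receptors else base.chains()[0]
    n_inside = int(math.floor(inside_fraction * n))
    inside_flags = np.zeros(n, dtype=bool)
    inside_flags[:n_inside] = True
    rng.shuffle(inside_flags)

    models: dict[str, ComplexStructure] = {}
    truth: dict[str, bool] = {}
    for i, inside in enumerate(inside_flags):
        model = base.copy()
        model_id = f"decoy{i:05d}"
        model.id = model_id
        n_crit = len(spec.criteria)
        if inside:
            violate = np.zeros(n_crit, dtype=bool)
        else:
            violate = rng.random(n_crit) < 0.4
            if not violate.any():
                violate[rng.integers(n_crit)] = True
        for criterion, bad in zip(spec.criteria, violate):
            if criterion.is_receptor:
                res = model.find_residue(receptor_chain,
                                         criterion.receptor_res_seq)
            else:
                key = assignment.mapping.get(criterion.label)
                res = model.get_residue(key) if key else None
            if res is None or criterion.atom_name not in res.atoms:
                raise ContractError(
                    f"base cannot resolve {criterion.label}:"
                    f"{criterion.atom_name}")
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = (criterion.cutoff * (1.05 + rng.random()) if bad
                 else criterion.cutoff * 0.9 * rng.random())
            res.atoms[criterion.atom_name].coords = criterion.centroid + r * u
        models[model_id] = model
        truth[model_id] = bool(inside)
    return models, truth


# ---------------------------------------------------------------------------
# motif-bearing sequence sets
# ---------------------------------------------------------------------------

_AA = sorted(STANDARD_AA)


def _brute_force_has_match(seq: str, pattern: MotifPattern) -> bool:
    # independent of motifs.scan on purpose: plain per-window check
    plen = len(pattern)
    for i in range(len(seq) - plen + 1):
        ok = True
        for j in range(plen):
            constraint = pattern.constraints[j]
            ch = seq[i + j]
            if constraint is None:
                if ch not in STANDARD_AA:
                    ok = False
                    break
            elif ch not in constraint:
                ok = False
                break
        if ok:
            return True
    return False


def make_sequences(n: int, length: int, k_carriers: int, seed: int = 0,
                   pattern: MotifPattern = CLASS3
                   ) -> tuple[list[tuple[str, str]], dict[str, bool]]:
    """``n`` random sequences of which exactly ``k_carriers`` contain the
    motif (injected at a random position); non-carriers are verified
    motif-free before emission."""
    if k_carriers > n:
        raise ContractError("k_carriers cannot exceed n")
    if length < len(pattern):
        raise ContractError("sequences shorter than the pattern")
    rng = np.random.default_rng(seed)
    carrier_flags = np.zeros(n, dtype=bool)
    carrier_flags[:k_carriers] = True
    rng.shuffle(carrier_flags)
    records: list[tuple[str, str]] = []
    truth: dict[str, bool] = {}
    for i, carrier in enumerate(carrier_flags):
        while True:
            seq = "".join(rng.choice(_AA) for _ in range(length))
            if carrier:
                realization = "".join(
                    rng.choice(sorted(c)) if c is not None else rng.choice(_AA)
                    for c in pattern.constraints)
                pos = int(rng.integers(0, length - len(pattern) + 1))
                seq = seq[:pos] + realization + seq[pos + len(pattern):]
                if _brute_force_has_match(seq, pattern):
                    break
            else:
                if not _brute_force_has_match(seq, pattern):
                    break
        seq_id = f"seq{i:04d}"
        records.append((seq_id, seq))
        truth[seq_id] = bool(carrier)
    return records, truth


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
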