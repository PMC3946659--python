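"""Rigid-body least-squares superposition and distance utilities.

The Kabsch algorithm is implemented directly (SVD of the covariance of the
centered point sets, with the reflection branch excluded) because optimal
proper-rigid superposition is the primitive every downstream analysis rests
on; tests cross-check it against an independent library routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ContractError, GeometryError
from .structure import ComplexStructure, ResidueKey

__all__ = [
    "RigidTransform",
    "kabsch_fit",
    "rmsd",
    "superpose_on_subset",
    "residues_within",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8:
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) <= 0:
            raise GeometryError("rotation matrix is a reflection")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square deviation of paired coordinates; no fitting."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ContractError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if A.size == 0:
        raise ContractError("empty coordinate sets")
    if A.ndim == 1:
        A, B = A[None, :], B[None, :]
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray
               ) -> tuple[RigidTransform, float]:
    """Least-squares proper-rigid fit of ``moving`` onto ``fixed``.

    Returns the transform and the fitted RMSD.  Requires at least three
    non-collinear points; a reflection is never returned.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ContractError(
            f"point sets differ in shape: {moving.shape} vs {fixed.shape}")
    n = moving.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 points for a rigid fit, got {n}")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    P = moving - cm
    Q = fixed - cf
    # collinearity check on both point clouds
    for X, label in ((P, "moving"), (Q, "fixed")):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise GeometryError(f"{label} points are (nearly) collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(moving), fixed)


def superpose_on_subset(model: ComplexStructure,
                        reference: ComplexStructure,
                        atom_keys: list[tuple[str, int, str, str]],
                        report: list | None = None
                        ) -> tuple[ComplexStructure, float, RigidTransform]:
    """Fit ``model`` onto ``reference`` using the paired atoms in ``atom_keys``.

    ``atom_keys`` are (chain, res_seq, icode, atom_name) tuples resolved in
    both structures; atoms missing on either side are dropped pairwise (and
    reported).  Returns the transformed model, the subset RMSD and the
    transform itself.
    """
    mov, fix = [], []
    for chain, seq, icode, aname in atom_keys:
        rm = model.get_residue((chain, seq, icode))
        rf = reference.get_residue((chain, seq, icode))
        am = rm.atoms.get(aname) if rm else None
        af = rf.atoms.get(aname) if rf else None
        if am is None or af is None:
            if report is not None:
                report.append((chain, seq, icode, aname))
            continue
        mov.append(am.coords)
        fix.append(af.coords)
    if len(mov) < 3:
        raise GeometryError(
            f"only {len(mov)} paired atoms resolvable; need >= 3")
    transform, fit_rmsd = kabsch_fit(np.array(mov), np.array(fix))
    return model.transformed(transform), fit_rmsd, transform


def residues_within(structure: ComplexStructure,
                    source_chains: set[str] | list[str],
                    cutoff: float) -> list[ResidueKey]:
    """Residues (outside ``source_chains``) whose minimum heavy-atom distance
    to any heavy atom of the source chains is <= ``cutoff`` Å.

    This is the binding-site "shell" selection: e.g. receptor residues
    within 5 Å of the bound peptide.
    """
    if cutoff <= 0:
        raise ContractError("cutoff must be positive")
    source_chains = set(source_chains)
    src = []
    for res in structure.residues:
        if res.chain_id in source_chains:
            src.extend(a.coords for a in res.heavy_atoms())
    if not src:
        return []
    tree = cKDTree(np.array(src))
    shell: list[ResidueKey] = []
    for res in structure.residues:
        if res.chain_id in source_chains:
            continue
        coords = [a.coords for a in res.heavy_atoms()]
        if not coords:
            continue
        dmin = float(np.min(tree.query(np.array(coords))[0]))
        if dmin <= cutoff:
            shell.append(res.key)
    return shell
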