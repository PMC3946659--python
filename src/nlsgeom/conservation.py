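"""Geometric-conservation statistics over superimposed structure ensembles.

Given a collection of receptor–peptide crystal structures, every entry is
expressed in the frame of one reference entry by least-squares fitting of
the Cα atoms of mutually sequence-aligned receptor residues.  The
conservation of a monitored atom (say, the P2' arginine Cα, or the Cζ3 of
a pocket tryptophan) is then summarized as the distances of its copies to
their common centroid, reported as mean ± sample standard deviation.

For isotropic per-coordinate Gaussian noise of width σ the distance of a
point to the sample centroid of n points follows a scaled χ(3)
distribution with mean 2√(2/π)·σ·√(1−1/n) ≈ 1.5958·σ·√(1−1/n); this
closed form drives the parameter-recovery tests and lets a measured
dispersion be converted back into an equivalent σ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentError, GeometryError, StatisticsError
from .positions import PositionAssignment
from .structure import ComplexStructure, ResidueKey, extract_sequence
from .superpose import RigidTransform, kabsch_fit, rmsd

__all__ = [
    "CorrespondenceMap",
    "DispersionStats",
    "EnsembleSuperposition",
    "build_correspondence",
    "identity_correspondence",
    "superpose_ensemble",
    "dispersion_from_coords",
    "dispersion",
    "dispersion_receptor",
    "pairwise_max_rmsd",
    "CHI3_MEAN_COEFF",
    "expected_dispersion_mean",
    "estimate_sigma",
]

#: mean of the χ distribution with 3 degrees of freedom, E|N(0,I₃)| = 2√(2/π)
CHI3_MEAN_COEFF = 2.0 * math.sqrt(2.0 / math.pi)


def expected_dispersion_mean(sigma: float, n: int) -> float:
    """Expected mean distance-to-centroid for iid isotropic noise σ, n entries."""
    return CHI3_MEAN_COEFF * sigma * math.sqrt(1.0 - 1.0 / n)


def estimate_sigma(mean_distance: float, n: int) -> float:
    """Invert :func:`expected_dispersion_mean` to recover the noise width."""
    return mean_distance / (CHI3_MEAN_COEFF * math.sqrt(1.0 - 1.0 / n))


# ---------------------------------------------------------------------------
# residue correspondence across entries
# ---------------------------------------------------------------------------

@dataclass
class CorrespondenceMap:
    """Reference-residue -> entry-residue maps from pairwise global alignment."""

    reference_id: str
    maps: dict[str, dict[ResidueKey, ResidueKey]]
    coverage: dict[str, float]

    def resolve(self, entry_id: str, ref_key: ResidueKey) -> ResidueKey | None:
        return self.maps[entry_id].get(ref_key)


def _receptor_chain(structure: ComplexStructure) -> str:
    receptors = structure.chains_with_role("receptor")
    if not receptors:
        raise AlignmentError(f"{structure.id}: no receptor chain")
    return receptors[0]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    # terminal gaps free: entries are domain fragments of varying span
    aligner.end_gap_score = 0.0
    return aligner


def build_correspondence(entries: Mapping[str, ComplexStructure],
                         reference: ComplexStructure,
                         min_coverage: float = 0.2,
                         warn_coverage: float = 0.5) -> CorrespondenceMap:
    """Map reference receptor residues onto each entry by global alignment.

    Coverage is the aligned (non-gap) fraction of the reference receptor
    sequence; entries under ``min_coverage`` raise, entries under
    ``warn_coverage`` warn.
    """
    ref_chain = _receptor_chain(reference)
    ref_residues = reference.chain_residues(ref_chain)
    ref_seq = extract_sequence(reference, ref_chain)
    aligner = _make_aligner()

    maps: dict[str, dict[ResidueKey, ResidueKey]] = {}
    coverage: dict[str, float] = {}
    for entry_id, entry in entries.items():
        chain = _receptor_chain(entry)
        residues = entry.chain_residues(chain)
        seq = extract_sequence(entry, chain)
        if entry.id == reference.id and seq == ref_seq:
            mapping = {r.key: e.key for r, e in zip(ref_residues, residues)}
            cov = 1.0
        else:
            aln = aligner.align(ref_seq, seq)[0]
            mapping = {}
            n_identical = 0
            for (rs, re), (qs, qe) in zip(*aln.aligned):
                for k in range(re - rs):
                    mapping[ref_residues[rs + k].key] = residues[qs + k].key
                    if ref_seq[rs + k] == seq[qs + k]:
                        n_identical += 1
            cov = n_identical / len(ref_seq) if ref_seq else 0.0
        if cov < min_coverage:
            raise AlignmentError(
                f"{entry_id}: receptor alignment coverage {cov:.2f} below "
                f"{min_coverage:.2f}; sequences appear unrelated")
        if cov < warn_coverage:
            warnings.warn(
                f"{entry_id}: low receptor alignment coverage {cov:.2f}",
                stacklevel=2)
        maps[entry_id] = mapping
        coverage[entry_id] = cov
    return CorrespondenceMap(reference.id, maps, coverage)


def identity_correspondence(entries: Mapping[str, ComplexStructure],
                            reference: ComplexStructure) -> CorrespondenceMap:
    """Correspondence for ensembles sharing the reference's numbering
    (synthetic ensembles, docking models of one complex)."""
    keys = [r.key for r in reference.residues]
    maps = {}
    coverage = {}
    for entry_id, entry in entries.items():
        mapping = {k: k for k in keys if entry.get_residue(k) is not None}
        maps[entry_id] = mapping
        coverage[entry_id] = len(mapping) / len(keys) if keys else 0.0
    return CorrespondenceMap(reference.id, maps, coverage)


# ---------------------------------------------------------------------------
# ensemble superposition
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSuperposition:
    """Entries expressed in the reference frame plus the fit bookkeeping."""

    reference_id: str
    superposed: dict[str, ComplexStructure]
    transforms: dict[str, RigidTransform]
    fit_keys: list[tuple[ResidueKey, str]]  # (reference residue key, atom)
    fit_rmsd: dict[str, float]
    rmsd_matrix: np.ndarray  # pairwise over fit atoms, in the common frame
    entry_ids: list[str] = field(default_factory=list)


def _common_fit_keys(entries: Mapping[str, ComplexStructure],
                     reference: ComplexStructure,
                     correspondence: CorrespondenceMap,
                     fit_atoms: Iterable[str]) -> list[tuple[ResidueKey, str]]:
    fit_atoms = list(fit_atoms)
    ref_chain = _receptor_chain(reference)
    keys = []
    for res in reference.chain_residues(ref_chain):
        for atom in fit_atoms:
            if atom not in res.atoms:
                continue
            ok = True
            for entry_id, entry in entries.items():
                ek = correspondence.resolve(entry_id, res.key)
                if ek is None:
                    ok = False
                    break
                eres = entry.get_residue(ek)
                if eres is None or atom not in eres.atoms:
                    ok = False
                    break
            if ok:
                keys.append((res.key, atom))
    return keys


def _entry_coords(entry: ComplexStructure, entry_id: str,
                  correspondence: CorrespondenceMap,
                  fit_keys: list[tuple[ResidueKey, str]]) -> np.ndarray:
    out = []
    for ref_key, atom in fit_keys:
        ek = correspondence.resolve(entry_id, ref_key)
        out.append(entry.residue(ek).atoms[atom].coords)
    return np.array(out)


def superpose_ensemble(entries: Mapping[str, ComplexStructure],
                       reference: ComplexStructure,
                       correspondence: CorrespondenceMap | None = None,
                       fit_atoms: Iterable[str] = ("CA",)
                       ) -> EnsembleSuperposition:
    """Fit every entry onto the reference over mutually aligned fit atoms.

    The pairwise RMSD matrix is computed over the same atom set in the
    common frame (no pairwise re-fitting; see :func:`pairwise_max_rmsd`
    for optimally re-fitted pair RMSDs).
    """
    if len(entries) < 2:
        raise StatisticsError("need at least 2 entries for an ensemble")
    if correspondence is None:
        correspondence = identity_correspondence(entries, reference)
    fit_keys = _common_fit_keys(entries, reference, correspondence, fit_atoms)
    if len(fit_keys) < 3:
        raise GeometryError(
            f"only {len(fit_keys)} mutually aligned fit atoms; need >= 3")
    ref_coords = np.array([reference.residue(k).atoms[a].coords
                           for k, a in fit_keys])
    superposed, transforms, fit_rmsd = {}, {}, {}
    fitted_coords = {}
    for entry_id, entry in entries.items():
        mov = _entry_coords(entry, entry_id, correspondence, fit_keys)
        transform, r = kabsch_fit(mov, ref_coords)
        transforms[entry_id] = transform
        fit_rmsd[entry_id] = r
        superposed[entry_id] = entry.transformed(transform)
        fitted_coords[entry_id] = transform.apply(mov)
    ids = list(entries)
    n = len(ids)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = rmsd(fitted_coords[ids[i]],
                                               fitted_coords[ids[j]])
    return EnsembleSuperposition(reference.id, superposed, transforms,
                                 fit_keys, fit_rmsd, matrix, ids)


def pairwise_max_rmsd(entries: Mapping[str, ComplexStructure],
                      reference: ComplexStructure,
                      correspondence: CorrespondenceMap | None = None,
                      fit_atoms: Iterable[str] = ("CA",)) -> float:
    """Maximum over entry pairs of the optimally superposed RMSD."""
    if correspondence is None:
        correspondence = identity_correspondence(entries, reference)
    fit_keys = _common_fit_keys(entries, reference, correspondence, fit_atoms)
    if len(fit_keys) < 3:
        raise GeometryError(
            f"only {len(fit_keys)} mutually aligned fit atoms; need >= 3")
    ids = list(entries)
    coords = {i: _entry_coords(entries[i], i, correspondence, fit_keys)
              for i in ids}
    worst = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            _, r = kabsch_fit(coords[ids[i]], coords[ids[j]])
            worst = max(worst, r)
    return worst


# ---------------------------------------------------------------------------
# dispersion statistics
# ---------------------------------------------------------------------------

@dataclass
class DispersionStats:
    """Distance-to-centroid summary for one monitored position/atom."""

    label: str
    atom_name: str
    n_entries: int
    centroid: np.ndarray
    distances: dict[str, float]
    mean: float
    sd: float
    skipped: list[str] = field(default_factory=list)


def dispersion_from_coords(points: np.ndarray,
                           ids: list[str] | None = None,
                           label: str = "",
                           atom_name: str = "") -> DispersionStats:
    """Core statistic: centroid, per-entry distances, mean and sample sd."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise StatisticsError(
            f"dispersion needs >= 2 contributing entries, got {n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    centroid = points.mean(axis=0)
    d = np.linalg.norm(points - centroid, axis=1)
    return DispersionStats(
        label=label, atom_name=atom_name, n_entries=n, centroid=centroid,
        distances=dict(zip(ids, d.tolist())),
        mean=float(d.mean()), sd=float(d.std(ddof=1)))


def dispersion(superposed: Mapping[str, ComplexStructure],
               assignments: Mapping[str, PositionAssignment],
               label: str, atom_name: str) -> DispersionStats:
    """Dispersion of a peptide-position atom across superposed entries.

    Entries whose assignment lacks the label, or whose residue lacks the
    atom, are skipped and listed in ``skipped``.
    """
    pts, ids, skipped = [], [], []
    for entry_id, entry in superposed.items():
        assignment = assignments.get(entry_id)
        key = assignment.mapping.get(label) if assignment else None
        res = entry.get_residue(key) if key else None
        atom = res.atoms.get(atom_name) if res else None
        if atom is None:
            skipped.append(entry_id)
            continue
        pts.append(atom.coords)
        ids.append(entry_id)
    stats = dispersion_from_coords(np.array(pts), ids, label, atom_name)
    stats.skipped = skipped
    return stats


def dispersion_receptor(superposed: Mapping[str, ComplexStructure],
                        correspondence: CorrespondenceMap,
                        ref_key: ResidueKey, atom_name: str,
                        label: str = "") -> DispersionStats:
    """Dispersion of a receptor atom (e.g. a pocket Trp Cζ3), resolved in
    each entry through the correspondence map."""
    pts, ids, skipped = [], [], []
    for entry_id, entry in superposed.items():
        key = correspondence.resolve(entry_id, ref_key)
        res = entry.get_residue(key) if key else None
        atom = res.atoms.get(atom_name) if res else None
        if atom is None:
            skipped.append(entry_id)
            continue
        pts.append(atom.coords)
        ids.append(entry_id)
    stats = dispersion_from_coords(np.array(pts), ids,
                                   label or str(ref_key), atom_name)
    stats.skipped = skipped
    return stats
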