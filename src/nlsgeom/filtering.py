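"""Distance-to-centroid filtering and clustering of docking-model ensembles.

Docking refinement produces thousands of candidate peptide poses.  Because
the anchor residues and their pocket tryptophans are geometrically
conserved across crystal structures, models in which those monitored atoms
stray too far from the crystallographic centroids can be discarded.  The
built-in presets carry the published cutoffs:

* minor site — 1.5 Å for the P1' K and P2' R Cα and sidechain Cε/Cζ atoms,
  2.0 Å for the W399 and W357 Cζ3 atoms;
* major site — 1.5 Å for the P1–P5 Cα atoms and 1.4 / 1.2 / 2.2 Å for the
  W231 / W184 / W142 Cζ3 atoms.

Surviving models are clustered by peptide Cα RMSD with a greedy
neighbor-count rule (the seed is the model with the most neighbors within
the cutoff; ties break to the lowest model index), and each cluster's seed
is its representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError
from .positions import PositionAssignment
from .structure import ComplexStructure
from .superpose import rmsd, superpose_on_subset

__all__ = [
    "FilterCriterion",
    "FilterSpec",
    "ModelFilterResult",
    "FilterReport",
    "ClusterResult",
    "MINOR_CUTOFFS",
    "MAJOR_CUTOFFS",
    "make_filter_spec",
    "apply_filter",
    "cluster_coords",
    "cluster_models",
]

#: (target label, atom, cutoff Å) — minor-site preset
MINOR_CUTOFFS = (
    ("P1'", "CA", 1.5),
    ("P1'", "CE", 1.5),
    ("P2'", "CA", 1.5),
    ("P2'", "CZ", 1.5),
    ("W399", "CZ3", 2.0),
    ("W357", "CZ3", 2.0),
)

#: (target label, atom, cutoff Å) — major-site preset
MAJOR_CUTOFFS = (
    ("P1", "CA", 1.5),
    ("P2", "CA", 1.5),
    ("P3", "CA", 1.5),
    ("P4", "CA", 1.5),
    ("P5", "CA", 1.5),
    ("W231", "CZ3", 1.4),
    ("W184", "CZ3", 1.2),
    ("W142", "CZ3", 2.2),
)

PRESET_CUTOFFS = {"minor": MINOR_CUTOFFS, "major": MAJOR_CUTOFFS}


@dataclass(frozen=True)
class FilterCriterion:
    """One monitored atom: its reference centroid and allowed displacement.

    ``label`` is either a peptide position label ("P1'", "P3", ...) resolved
    through a :class:`PositionAssignment`, or a receptor residue label of
    the form "W399" resolved by residue number in the receptor chain.
    """

    label: str
    atom_name: str
    centroid: np.ndarray
    cutoff: float

    def __post_init__(self):
        object.__setattr__(self, "centroid",
                           np.asarray(self.centroid, dtype=float))
        if self.cutoff <= 0:
            raise ContractError(f"cutoff must be positive, got {self.cutoff}")

    @property
    def is_receptor(self) -> bool:
        return not self.label.startswith("P")

    @property
    def receptor_res_seq(self) -> int:
        return int("".join(ch for ch in self.label if ch.isdigit()))

    @property
    def key(self) -> tuple[str, str]:
        return (self.label, self.atom_name)


@dataclass(frozen=True)
class FilterSpec:
    site: str
    criteria: tuple[FilterCriterion, ...]

    def __post_init__(self):
        if not self.criteria:
            raise ContractError("FilterSpec needs at least one criterion")


def make_filter_spec(site: str,
                     centroids: Mapping[tuple[str, str], np.ndarray],
                     cutoffs: Sequence[tuple[str, str, float]] | None = None
                     ) -> FilterSpec:
    """Build a spec from per-(label, atom) centroids; cutoffs default to the
    site preset."""
    if cutoffs is None:
        try:
            cutoffs = PRESET_CUTOFFS[site]
        except KeyError:
            raise ContractError(f"no preset for site {site!r}") from None
    criteria = []
    for label, atom, cutoff in cutoffs:
        if (label, atom) not in centroids:
            raise ContractError(f"no centroid supplied for ({label}, {atom})")
        criteria.append(FilterCriterion(label, atom,
                                        centroids[(label, atom)], cutoff))
    return FilterSpec(site, tuple(criteria))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class ModelFilterResult:
    model_id: str
    passed: bool
    distances: dict[tuple[str, str], float | None]
    failures: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    site: str
    results: list[ModelFilterResult]
    pass_fraction: float

    @property
    def passed_ids(self) -> list[str]:
        return [r.model_id for r in self.results if r.passed]


def _as_mapping(models) -> dict[str, ComplexStructure]:
    if isinstance(models, Mapping):
        return dict(models)
    return {getattr(m, "id", None) or f"model{i:05d}": m
            for i, m in enumerate(models)}


def _criterion_atom(model: ComplexStructure, criterion: FilterCriterion,
                    assignment: PositionAssignment,
                    receptor_chain: str):
    if criterion.is_receptor:
        res = model.find_residue(receptor_chain, criterion.receptor_res_seq)
    else:
        key = assignment.mapping.get(criterion.label)
        res = model.get_residue(key) if key else None
    if res is None:
        return None
    return res.atoms.get(criterion.atom_name)


def apply_filter(models, spec: FilterSpec,
                 assignment: PositionAssignment,
                 receptor_chain: str | None = None,
                 reference: ComplexStructure | None = None) -> FilterReport:
    """Pass/fail every model against the spec (inclusive boundary: a
    distance exactly equal to the cutoff passes).

    ``assignment`` resolves position labels (models are assumed to share
    the peptide numbering).  If ``reference`` is given, each model is first
    re-fitted onto the reference receptor Cα trace; otherwise models are
    taken as already superposed in the centroid frame.  A model missing a
    criterion atom fails with an explicit reason.
    """
    model_map = _as_mapping(models)
    if not model_map:
        raise ContractError("empty model ensemble")
    results = []
    for model_id, model in model_map.items():
        if receptor_chain is None:
            receptors = model.chains_with_role("receptor")
            chain = receptors[0] if receptors else model.chains()[0]
        else:
            chain = receptor_chain
        if reference is not None:
            fit_keys = [(r.chain_id, r.res_seq, r.icode, "CA")
                        for r in reference.chain_residues(chain)
                        if "CA" in r.atoms]
            model, _, _ = superpose_on_subset(model, reference, fit_keys)
        distances: dict[tuple[str, str], float | None] = {}
        failures: list[str] = []
        for criterion in spec.criteria:
            atom = _criterion_atom(model, criterion, assignment, chain)
            if atom is None:
                distances[criterion.key] = None
                failures.append(
                    f"{criterion.label}:{criterion.atom_name} missing")
                continue
            d = float(np.linalg.norm(atom.coords - criterion.centroid))
            distances[criterion.key] = d
            if d > criterion.cutoff:
                failures.append(
                    f"{criterion.label}:{criterion.atom_name} "
                    f"{d:.2f} Å > {criterion.cutoff} Å")
        results.append(ModelFilterResult(model_id, not failures,
                                         distances, failures))
    n_pass = sum(r.passed for r in results)
    return FilterReport(spec.site, results, n_pass / len(results))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    clusters: list[list[str]]  # partition of model ids, extraction order
    representatives: list[str]  # greedy seed of each cluster
    cutoff: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def largest(self) -> list[str]:
        return max(self.clusters, key=len)

    @property
    def largest_representative(self) -> str:
        i = int(np.argmax(self.sizes))
        return self.representatives[i]


def cluster_coords(coords: Sequence[np.ndarray], cutoff: float,
                   ids: Sequence[str] | None = None) -> ClusterResult:
    """Greedy neighbor-count clustering on raw coordinate sets.

    Repeatedly: count, for each remaining model, its neighbors within the
    RMSD cutoff (inclusive); seed = most neighbors, ties to the lowest
    index; the seed and its neighbors form a cluster and are removed.
    """
    n = len(coords)
    if n == 0:
        raise ContractError("no models to cluster")
    if ids is None:
        ids = [f"model{i:05d}" for i in range(n)]
    shapes = {np.asarray(c).shape for c in coords}
    if len(shapes) != 1:
        raise ContractError(f"models differ in atom count: {sorted(shapes)}")
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = rmsd(coords[i], coords[j])
    remaining = list(range(n))
    clusters, representatives = [], []
    while remaining:
        counts = {i: sum(1 for j in remaining
                         if j != i and matrix[i, j] <= cutoff)
                  for i in remaining}
        seed = min(remaining, key=lambda i: (-counts[i], i))
        members = [seed] + [j for j in remaining
                            if j != seed and matrix[seed, j] <= cutoff]
        members.sort()
        clusters.append([ids[i] for i in members])
        representatives.append(ids[seed])
        remaining = [i for i in remaining if i not in set(members)]
    return ClusterResult(clusters, representatives, cutoff)


def cluster_models(models,
                   atom_keys: Sequence[tuple[str, int, str, str]],
                   cutoff: float = 2.0) -> ClusterResult:
    """Cluster structure models by RMSD over the given atoms (typically the
    peptide Cα trace).  All models must resolve the full atom set."""
    model_map = _as_mapping(models)
    if not model_map:
        raise ContractError("no models to cluster")
    coords = []
    for model_id, model in model_map.items():
        pts = []
        for chain, seq, icode, aname in atom_keys:
            res = model.get_residue((chain, seq, icode))
            atom = res.atoms.get(aname) if res else None
            if atom is None:
                raise ContractError(
                    f"{model_id}: missing atom {(chain, seq, icode, aname)}")
            pts.append(atom.coords)
        coords.append(np.array(pts))
    return cluster_coords(coords, cutoff, ids=list(model_map))
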