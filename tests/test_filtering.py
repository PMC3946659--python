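"""Distance filtering of model ensembles and greedy clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlsgeom.errors import ContractError
from nlsgeom.filtering import (FilterCriterion, FilterSpec, MAJOR_CUTOFFS,
                               MINOR_CUTOFFS, apply_filter, cluster_coords,
                               cluster_models, make_filter_spec)
from nlsgeom.positions import MOUSE_POCKETS, assign_positions, \
    find_anchor_residue
from nlsgeom.synthetic import make_decoys, make_toy_complex, \
    random_rigid_transform


@pytest.fixture
def setup():
    base = make_toy_complex()
    anchor = find_anchor_residue(base, MOUSE_POCKETS["minor"])
    assignment = assign_positions(base, anchor, "minor")
    centroids = {}
    for label, atom, _ in MINOR_CUTOFFS:
        crit = FilterCriterion(label, atom, np.zeros(3), 1.0)
        res = (base.find_residue("A", crit.receptor_res_seq)
               if crit.is_receptor
               else base.get_residue(assignment.mapping[label]))
        centroids[(label, atom)] = res.atoms[atom].coords.copy()
    spec = make_filter_spec("minor", centroids)
    return base, assignment, spec


class TestPresets:
    def test_minor_preset_cutoffs(self):
        cuts = {(l, a): c for l, a, c in MINOR_CUTOFFS}
        assert cuts[("P1'", "CA")] == 1.5
        assert cuts[("P2'", "CZ")] == 1.5
        assert cuts[("W399", "CZ3")] == 2.0
        assert cuts[("W357", "CZ3")] == 2.0
        assert len(cuts) == 6

    def test_major_preset_cutoffs(self):
        cuts = {(l, a): c for l, a, c in MAJOR_CUTOFFS}
        assert all(cuts[(f"P{i}", "CA")] == 1.5 for i in range(1, 6))
        assert cuts[("W231", "CZ3")] == 1.4
        assert cuts[("W184", "CZ3")] == 1.2
        assert cuts[("W142", "CZ3")] == 2.2

    def test_empty_spec_rejected(self):
        with pytest.raises(ContractError):
            FilterSpec("minor", ())


class TestApplyFilter:
    def test_model_at_centroids_passes(self, setup):
        base, assignment, spec = setup
        report = apply_filter({"m": base}, spec, assignment)
        assert report.pass_fraction == 1.0

    def test_displacement_beyond_cutoff_fails_naming_criterion(self, setup):
        base, assignment, spec = setup
        model = base.copy()
        p1 = model.get_residue(assignment.mapping["P1'"])
        p1.atoms["CA"].coords = p1.atoms["CA"].coords + np.array([1.6, 0, 0])
        report = apply_filter({"m": model}, spec, assignment)
        result = report.results[0]
        assert not result.passed
        assert any("P1':CA" in f for f in result.failures)
        assert len(result.failures) == 1

    def test_boundary_distance_equal_to_cutoff_passes(self, setup):
        base, assignment, spec = setup
        model = base.copy()
        p1 = model.get_residue(assignment.mapping["P1'"])
        centroid = dict((c.key, c) for c in spec.criteria)[("P1'", "CA")]
        p1.atoms["CA"].coords = centroid.centroid + np.array([1.5, 0.0, 0.0])
        report = apply_filter({"m": model}, spec, assignment)
        assert report.results[0].passed
        assert report.results[0].distances[("P1'", "CA")] == \
            pytest.approx(1.5, abs=1e-12)

    def test_missing_atom_fails_with_reason(self, setup):
        base, assignment, spec = setup
        model = base.copy()
        del model.get_residue(assignment.mapping["P1'"]).atoms["CE"]
        report = apply_filter({"m": model}, spec, assignment)
        assert not report.results[0].passed
        assert any("missing" in f for f in report.results[0].failures)

    def test_empty_ensemble_raises(self, setup):
        _, assignment, spec = setup
        with pytest.raises(ContractError):
            apply_filter({}, spec, assignment)

    @pytest.mark.parametrize("fraction,n", [(0.0, 40), (0.3, 100), (1.0, 40)])
    def test_constructed_pass_fraction_recovered(self, setup, fraction, n):
        base, assignment, spec = setup
        models, truth = make_decoys(base, n, fraction, spec, assignment,
                                    seed=11)
        report = apply_filter(models, spec, assignment)
        assert report.pass_fraction == pytest.approx(fraction)
        for result in report.results:
            assert result.passed == truth[result.model_id]

    def test_monotone_in_cutoffs(self, setup, rng):
        base, assignment, spec = setup
        models, _ = make_decoys(base, 50, 0.4, spec, assignment, seed=7)
        report = apply_filter(models, spec, assignment)
        wider = FilterSpec(spec.site, tuple(
            FilterCriterion(c.label, c.atom_name, c.centroid,
                            c.cutoff * (1.0 + rng.random()))
            for c in spec.criteria))
        report2 = apply_filter(models, wider, assignment)
        assert set(report.passed_ids) <= set(report2.passed_ids)

    def test_invariant_under_joint_rigid_transform(self, setup, rng):
        base, assignment, spec = setup
        models, _ = make_decoys(base, 20, 0.5, spec, assignment, seed=3)
        T = random_rigid_transform(rng)
        moved = {k: m.transformed(T) for k, m in models.items()}
        moved_spec = FilterSpec(spec.site, tuple(
            FilterCriterion(c.label, c.atom_name, T.apply(c.centroid),
                            c.cutoff) for c in spec.criteria))
        a = apply_filter(models, spec, assignment)
        b = apply_filter(moved, moved_spec, assignment)
        assert [r.passed for r in a.results] == [r.passed for r in b.results]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def greedy_oracle(coords, cutoff):
    """Independent brute-force realization of the greedy neighbor rule."""
    n = len(coords)

    def pair_rmsd(i, j):
        diff = np.asarray(coords[i]) - np.asarray(coords[j])
        return float(np.sqrt((diff ** 2).sum(axis=1).mean()))

    remaining = list(range(n))
    clusters = []
    while remaining:
        best_seed, best_count = None, -1
        for i in remaining:
            count = sum(1 for j in remaining
                        if j != i and pair_rmsd(i, j) <= cutoff)
            if count > best_count:
                best_seed, best_count = i, count
        members = sorted([best_seed] + [
            j for j in remaining
            if j != best_seed and pair_rmsd(best_seed, j) <= cutoff])
        clusters.append((best_seed, members))
        remaining = [i for i in remaining if i not in set(members)]
    return clusters


class TestClustering:
    def test_identical_models_form_one_cluster(self, rng):
        pts = rng.normal(size=(5, 3))
        result = cluster_coords([pts.copy() for _ in range(6)], cutoff=2.0)
        assert result.sizes == [6]
        assert result.representatives[0] in result.clusters[0]

    def test_two_separated_bundles(self, rng):
        base = rng.normal(size=(4, 3))
        coords = [base + rng.normal(0, 0.05, (4, 3)) for _ in range(5)]
        coords += [base + 100.0 + rng.normal(0, 0.05, (4, 3))
                   for _ in range(3)]
        result = cluster_coords(coords, cutoff=2.0)
        assert sorted(result.sizes, reverse=True) == [5, 3]
        assert len(result.largest) == 5

    def test_matches_bruteforce_greedy_oracle(self, rng):
        for case in range(50):
            n = int(rng.integers(1, 9))
            scale = rng.choice([0.5, 1.5, 4.0])
            coords = [rng.normal(scale=scale, size=(3, 3)) for _ in range(n)]
            cutoff = float(rng.uniform(0.5, 4.0))
            result = cluster_coords(coords, cutoff)
            oracle = greedy_oracle(coords, cutoff)
            got = [sorted(int(m[5:]) for m in c) for c in result.clusters]
            assert got == [members for _, members in oracle], f"case {case}"
            reps = [int(r[5:]) for r in result.representatives]
            assert reps == [seed for seed, _ in oracle]

    def test_partition_invariants(self, rng):
        coords = [rng.normal(scale=2.0, size=(4, 3)) for _ in range(12)]
        result = cluster_coords(coords, cutoff=2.5)
        all_ids = sorted(i for c in result.clusters for i in c)
        assert len(all_ids) == 12 and len(set(all_ids)) == 12
        for cluster, rep in zip(result.clusters, result.representatives):
            assert rep in cluster

    def test_atom_set_mismatch_raises(self, rng):
        with pytest.raises(ContractError):
            cluster_coords([rng.normal(size=(4, 3)),
                            rng.normal(size=(5, 3))], cutoff=1.0)

    def test_cluster_models_on_structures(self, setup):
        base, assignment, spec = setup
        models, _ = make_decoys(base, 10, 1.0, spec, assignment, seed=2)
        atom_keys = [(r.chain_id, r.res_seq, r.icode, "CA")
                     for r in base.chain_residues("B")]
        result = cluster_models(models, atom_keys, cutoff=5.0)
        assert sum(result.sizes) == 10
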