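"""Chromophore extraction, distances, networks, superposition, gain/loss."""

import numpy as np
import pytest

from lhckit.chromophore_network import (
    Transform, build_network, closest_pair, compare_chromophores,
    edge_to_edge, extract_chromophores, mg_mg, superpose,
)
from lhckit.membrane_geometry import MembraneFrame
from lhckit.structure_io import AtomSite, MolecularModel
from lhckit.synthetic_data import (
    MacrocyclePlacement, SceneSpec, make_scene, core_belt_scene,
)

from conftest import random_rigid


def scene_with_rings(centers, kinds=None, seed=0, **kw):
    kinds = kinds or ["chl_a"] * len(centers)
    spec = SceneSpec(bundles=[], macrocycles=[
        MacrocyclePlacement(center=c, kind=k) for c, k in zip(centers, kinds)],
        seed=seed)
    return make_scene(spec, **kw)[0]


@pytest.fixture
def frame():
    return MembraneFrame(np.array([0, 0, 1.0]), np.zeros(3), 1)


class TestExtraction:
    def test_sides_and_kinds(self, ring_pair_scene, frame):
        model, _, _ = ring_pair_scene
        chroms = extract_chromophores(model, frame)
        assert [c.kind for c in chroms] == ["chl_a", "chl_a", "chl_c"]
        assert [c.side for c in chroms] == ["stromal", "stromal", "lumenal"]
        assert all(c.metal_position is not None for c in chroms)

    def test_no_hetero_empty(self, three_helix_bundle, frame):
        model, _ = three_helix_bundle
        assert extract_chromophores(model, frame) == []

    def test_near_midplane_unassigned(self, frame):
        model = scene_with_rings([(0, 0, 1.0)])
        c, = extract_chromophores(model, frame)
        assert c.side == "unassigned"

    def test_missing_metal_warns_uses_centroid(self, frame):
        model = scene_with_rings([(0, 0, 8.0)])
        atoms = [a for a in model.atoms if a.atom_name != "MG"]
        with pytest.warns(UserWarning, match="Mg"):
            c, = extract_chromophores(MolecularModel("x", atoms), frame)
        assert c.metal_position is None
        assert c.side == "stromal"

    def test_uncatalogued_reported(self, frame):
        model = scene_with_rings([(0, 0, 8.0)])
        extra = [AtomSite("z", "XYZ", 99, " ", f"O{i}", "O",
                          np.array([30.0 + i, 0, 0]), is_hetero=True)
                 for i in range(3)]
        with pytest.warns(UserWarning, match="XYZ"):
            chroms = extract_chromophores(
                MolecularModel("x", model.atoms + extra), frame)
        assert len(chroms) == 1

    def test_waters_skipped(self, frame):
        atoms = [AtomSite("w", "HOH", i + 1, " ", "O", "O",
                          np.array([i * 3.0, 0, 0]), is_hetero=True)
                 for i in range(4)]
        assert extract_chromophores(MolecularModel("w", atoms), frame) == []

    def test_phytol_tail_excluded(self, frame):
        model = scene_with_rings([(0, 0, 8.0)])
        tail = [AtomSite("z", "CLA", 1, " ", f"C{i}", "C",
                         np.array([5.0 + i, 0, 8.0]), is_hetero=True)
                for i in range(1, 6)]
        c, = extract_chromophores(MolecularModel("x", model.atoms + tail),
                                  frame)
        assert not any(n in c.atom_names for n in ("C1", "C2", "C5"))


class TestDistances:
    def test_shared_atom_zero(self, frame):
        m = scene_with_rings([(0, 0, 8.0)])
        c, = extract_chromophores(m, frame)
        c2 = c.transformed(Transform(np.eye(3), np.array([6.6, 0, 0])))
        c2.residue_seq = 99
        # rings touch edge-on: leftmost atom of c2 at rightmost of c
        assert edge_to_edge(c, c2) == pytest.approx(0.0, abs=1e-9)

    def test_self_distance_undefined(self, frame):
        m = scene_with_rings([(0, 0, 8.0)])
        c, = extract_chromophores(m, frame)
        with pytest.raises(ValueError):
            edge_to_edge(c, c)

    def test_constrained_pair_six_angstrom(self, ring_pair_scene, frame):
        model, truth, _ = ring_pair_scene
        chroms = extract_chromophores(model, frame)
        d = edge_to_edge(chroms[0], chroms[1])
        assert d == pytest.approx(6.0, abs=1e-3)
        # brute-force pairwise oracle
        brute = min(np.linalg.norm(p - q)
                    for p in chroms[0].macrocycle_xyz
                    for q in chroms[1].macrocycle_xyz)
        assert d == pytest.approx(brute, abs=1e-9)
        assert truth["pairs"][0]["edge_to_edge_A"] == pytest.approx(6.0,
                                                                    abs=1e-3)

    def test_metal_distance(self, frame):
        m = scene_with_rings([(0, 0, 8.0), (12, 0, 8.0)])
        a, b = extract_chromophores(m, frame)
        assert mg_mg(a, b) == pytest.approx(12.0, abs=1e-6)

    def test_metal_required(self, frame):
        m = scene_with_rings([(0, 0, 8.0), (12, 0, 8.0)])
        a, b = extract_chromophores(m, frame)
        b.metal_position = None
        with pytest.raises(ValueError):
            mg_mg(a, b)

    def test_edge_le_mgmg(self, frame):
        rng = np.random.default_rng(8)
        centers = [(float(x), float(y), float(rng.uniform(-8, 8)))
                   for x in np.arange(0, 40, 10) for y in np.arange(0, 40, 10)]
        m = scene_with_rings(centers, check_clashes=False)
        chroms = extract_chromophores(m, frame)
        for i in range(len(chroms)):
            for j in range(i + 1, len(chroms)):
                assert (edge_to_edge(chroms[i], chroms[j])
                        <= mg_mg(chroms[i], chroms[j]) + 1e-9)

    def test_rigid_invariance(self, ring_pair_scene, frame):
        model, _, _ = ring_pair_scene
        chroms = extract_chromophores(model, frame)
        d0 = edge_to_edge(chroms[0], chroms[1])
        g0 = mg_mg(chroms[0], chroms[1])
        rng = np.random.default_rng(3)
        for _ in range(5):
            R, t = random_rigid(rng)
            T = Transform(R, t)
            a, b = chroms[0].transformed(T), chroms[1].transformed(T)
            assert edge_to_edge(a, b) == pytest.approx(d0, abs=1e-6)
            assert mg_mg(a, b) == pytest.approx(g0, abs=1e-6)


class TestNetwork:
    def test_far_pair_no_edges(self, frame):
        m = scene_with_rings([(0, 0, 8.0), (27, 0, 8.0)])  # edge-to-edge 20.4
        chroms = extract_chromophores(m, frame)
        assert build_network(chroms, cutoff=15.0).edges == []

    def test_strict_vs_inclusive(self, frame):
        m = scene_with_rings([(0, 0, 8.0), (21.6, 0, 8.0)])  # edge-to-edge 15
        chroms = extract_chromophores(m, frame)
        d = edge_to_edge(chroms[0], chroms[1])
        assert d == pytest.approx(15.0, abs=1e-9)
        assert len(build_network(chroms, cutoff=15.0).edges) == 1
        assert build_network(chroms, cutoff=15.0, strict=True).edges == []

    def test_side_filter(self, ring_pair_scene, frame):
        model, _, _ = ring_pair_scene
        chroms = extract_chromophores(model, frame)
        net = build_network(chroms, cutoff=50.0, side_filter="stromal")
        assert len(net.chromophores) == 2

    def test_edges_equal_brute_force(self, frame):
        rng = np.random.default_rng(21)
        centers = []
        for x in np.arange(0, 60, 12):
            for y in np.arange(0, 60, 12):
                centers.append((x + rng.uniform(-1.5, 1.5),
                                y + rng.uniform(-1.5, 1.5),
                                rng.uniform(-8, 8)))
        m = scene_with_rings(centers, check_clashes=False)
        chroms = extract_chromophores(m, frame)
        net = build_network(chroms, cutoff=15.0)
        got = {frozenset((e.a, e.b)) for e in net.edges}
        expect = set()
        for i in range(len(chroms)):
            for j in range(i + 1, len(chroms)):
                if edge_to_edge(chroms[i], chroms[j]) <= 15.0:
                    expect.add(frozenset((chroms[i].chrom_id,
                                          chroms[j].chrom_id)))
        assert got == expect


class TestClosestPair:
    def test_singletons(self, frame):
        m = scene_with_rings([(0, 0, 8.0), (30, 0, 8.0)])
        a, b = extract_chromophores(m, frame)
        pair = closest_pair([a], [b])
        assert {pair.a, pair.b} == {a.chrom_id, b.chrom_id}

    def test_brute_force_recovery_and_exclusion(self, frame):
        rng = np.random.default_rng(17)
        centers = [(float(10 * i + rng.uniform(-2, 2)), 0.0, 8.0)
                   for i in range(6)]
        m = scene_with_rings(centers, check_clashes=False)
        chroms = extract_chromophores(m, frame)
        ga, gb = chroms[:3], chroms[3:]
        pair = closest_pair(ga, gb)
        brute = min(((edge_to_edge(x, y), x.chrom_id, y.chrom_id)
                     for x in ga for y in gb))
        assert pair.edge_to_edge == pytest.approx(brute[0], abs=1e-9)
        # excluding the winner moves to the next-nearest pair
        pair2 = closest_pair(ga, gb, exclude=[pair.a if pair.a in
                                              {c.chrom_id for c in ga}
                                              else pair.b])
        assert pair2.edge_to_edge >= pair.edge_to_edge

    def test_empty_after_exclusion(self, frame):
        m = scene_with_rings([(0, 0, 8.0), (30, 0, 8.0)])
        a, b = extract_chromophores(m, frame)
        with pytest.raises(ValueError):
            closest_pair([a], [b], exclude=[b.chrom_id])


class TestSuperpose:
    def test_identity(self, core_belt):
        model, _, _ = core_belt
        T, rmsd = superpose(model, model, {c: c for c in model.chain_ids})
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(T.as_matrix(), np.eye(4), atol=1e-9)

    def test_random_rotation_recovered(self, core_belt):
        model, _, _ = core_belt
        rng = np.random.default_rng(33)
        R, t = random_rigid(rng)
        moved = model.transformed(R, t)
        T, rmsd = superpose(moved, model, {c: c for c in model.chain_ids})
        assert rmsd < 1e-6
        assert np.abs(T.rotation @ R - np.eye(3)).max() < 1e-9

    def test_offset_numbering_fallback(self, core_belt):
        model, _, _ = core_belt
        shifted = [AtomSite(a.chain_id, a.residue_name, a.residue_seq + 100,
                            a.insertion_code, a.atom_name, a.element,
                            a.position, a.occupancy, a.b_factor, a.is_hetero)
                   for a in model.atoms]
        moved = MolecularModel("s", shifted)
        T, rmsd = superpose(moved, model, {c: c for c in model.chain_ids})
        assert rmsd < 1e-6

    def test_too_few_atoms(self, three_helix_bundle):
        model, _ = three_helix_bundle
        tiny = MolecularModel("t", model.atoms[:5])
        with pytest.raises(ValueError, match="20"):
            superpose(tiny, tiny, {"A": "A"})

    def test_transform_algebra(self):
        rng = np.random.default_rng(1)
        R, t = random_rigid(rng)
        T = Transform(R, t)
        x = rng.uniform(-10, 10, (7, 3))
        assert np.allclose(T.inverse().apply(T.apply(x)), x, atol=1e-9)
        assert np.allclose(T.compose(T.inverse()).as_matrix(), np.eye(4),
                           atol=1e-9)


class TestCompare:
    def test_identical_regions(self, ring_pair_scene, frame):
        model, _, _ = ring_pair_scene
        chroms = extract_chromophores(model, frame)
        rep = compare_chromophores(chroms, chroms)
        assert len(rep.matched) == len(chroms)
        assert rep.lost == [] and rep.gained == []

    def test_constructed_loss_and_gain(self, frame):
        parent = scene_with_rings([(12 * k, 0, 6.0) for k in range(5)])
        ref = extract_chromophores(parent, frame)
        child = scene_with_rings([(12 * k, 0, 6.0) for k in range(3)]
                                 + [(0, 20, 6.0)])
        qry = extract_chromophores(child, frame)
        rep = compare_chromophores(ref, qry, match_cutoff=5.0)
        assert len(rep.lost) == 2
        assert len(rep.gained) == 1
        assert len(rep.matched) == 3

    def test_partial_injection_and_conservation(self, frame):
        rng = np.random.default_rng(5)
        ref = extract_chromophores(
            scene_with_rings([(10 * k, 0, 6.0) for k in range(6)]), frame)
        qry = extract_chromophores(
            scene_with_rings([(10 * k + rng.uniform(-2, 2), 0, 6.0)
                              for k in range(6)], check_clashes=False), frame)
        rep = compare_chromophores(ref, qry, match_cutoff=4.0)
        seen_ref = [a for a, _, _ in rep.matched] + rep.lost
        seen_qry = [b for _, b, _ in rep.matched] + rep.gained
        assert sorted(seen_ref) == sorted(c.chrom_id for c in ref)
        assert sorted(seen_qry) == sorted(c.chrom_id for c in qry)
        assert len(set(seen_ref)) == len(seen_ref)
        assert len(set(seen_qry)) == len(seen_qry)

    def test_empty_region_rejected(self, frame):
        chroms = extract_chromophores(
            scene_with_rings([(0, 0, 6.0)]), frame)
        with pytest.raises(ValueError):
            compare_chromophores(chroms, [])
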