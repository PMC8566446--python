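import numpy as np
import pytest

from conftest import make_morphology
from touchnet import detection
from touchnet.detection import (VoxelGrid, assign_neurons_to_hypervoxels,
                                axon_density_touch, detect_gap_junctions,
                                detect_touches, hypervoxel_of,
                                order_hypervoxels)
from touchnet.errors import ValidationError
from touchnet.metrics import make_grid_fixture
from touchnet.placement import NeuronPlacement, PlacementResult
from touchnet.swc import AXON, BASAL_DENDRITE, SOMA

UM = 1e-6
VOX = 3 * UM


def fine_step_voxels(p0, p1, voxel_size, steps_per_voxel=50):
    """Fine-stepping oracle: voxels containing sampled points."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    n = max(2, int(length / voxel_size * steps_per_voxel) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None] + ts[:, None] * (p1 - p0)[None]
    return {tuple(v) for v in np.floor(pts / voxel_size).astype(int)}


def slab_clip_voxels(p0, p1, voxel_size):
    """Exact oracle: every voxel whose box the segment intersects with a
    non-degenerate parameter interval (closed-form slab clipping)."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    lo = np.floor(np.minimum(p0, p1) / voxel_size).astype(int)
    hi = np.floor(np.maximum(p0, p1) / voxel_size).astype(int)
    d = p1 - p0
    out = set()
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                bmin = np.array([i, j, k]) * voxel_size
                bmax = bmin + voxel_size
                t0, t1 = 0.0, 1.0
                ok = True
                for ax in range(3):
                    if abs(d[ax]) < 1e-30:
                        if not bmin[ax] <= p0[ax] < bmax[ax]:
                            ok = False
                            break
                        continue
                    ta = (bmin[ax] - p0[ax]) / d[ax]
                    tb = (bmax[ax] - p0[ax]) / d[ax]
                    t0 = max(t0, min(ta, tb))
                    t1 = min(t1, max(ta, tb))
                if ok and t0 < t1:
                    out.add((i, j, k))
    return out


class TestRasterizeSegment:
    def test_axis_aligned_marks_expected_voxels(self):
        g = VoxelGrid(voxel_size=VOX)
        # 9 um segment starting at a voxel centre spans 4 voxels along x
        p0 = np.array([1.5, 1.5, 1.5]) * UM
        p1 = p0 + np.array([9, 0, 0]) * UM
        g.rasterize_segment(p0, p1, 0, "axon", 1)
        assert sorted(g.axon) == [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]

    def test_zero_length_segment_single_voxel(self):
        g = VoxelGrid(voxel_size=VOX)
        p = np.array([4.0, 4.0, 4.0]) * UM
        g.rasterize_segment(p, p, 0, "dendrite", 1)
        assert list(g.dend) == [(1, 1, 1)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracles_on_random_segments(self, seed):
        rng = np.random.default_rng(seed)
        g = VoxelGrid(voxel_size=VOX)
        for k in range(10):
            p0 = rng.uniform(-20, 20, 3) * UM
            p1 = rng.uniform(-20, 20, 3) * UM
            g.axon.clear()
            g.rasterize_segment(p0, p1, 0, "axon", 1)
            got = set(g.axon)
            # exact equality against the closed-form clipping oracle
            assert got == slab_clip_voxels(p0, p1, VOX)
            # the fine-stepping scheme converges to the same set from below
            assert fine_step_voxels(p0, p1, VOX) <= got

    def test_occupancy_records_path_distance(self):
        g = VoxelGrid(voxel_size=VOX)
        p0 = np.array([1.5, 1.5, 1.5]) * UM
        p1 = p0 + np.array([9, 0, 0]) * UM
        g.rasterize_segment(p0, p1, 0, "dendrite", 7, base_distance=10 * UM)
        # distance at each voxel = base + distance to the voxel's midpoint
        occ = g.dend[(2, 0, 0)][0]
        assert occ.section_id == 7
        assert occ.path_distance == pytest.approx((10 + 6) * UM)


class TestRasterizeSoma:
    def test_tiny_soma_single_voxel(self):
        g = VoxelGrid(voxel_size=VOX)
        g.rasterize_soma(np.array([1.5, 1.5, 1.5]) * UM, 0.5 * UM, 0)
        assert list(g.dend) == [(0, 0, 0)]

    def test_off_centre_tiny_soma(self):
        g = VoxelGrid(voxel_size=VOX)
        g.rasterize_soma(np.array([2.9, 0.1, 0.1]) * UM, 0.1 * UM, 0)
        assert list(g.dend) == [(0, 0, 0)]

    def test_matches_brute_force_centre_test(self):
        g = VoxelGrid(voxel_size=VOX)
        centre = np.array([4.0, 5.0, 6.0]) * UM
        radius = 6 * UM
        g.rasterize_soma(centre, radius, 0)
        marked = set(g.dend)
        brute = set()
        for i in range(-5, 8):
            for j in range(-5, 8):
                for k in range(-5, 8):
                    c = (np.array([i, j, k]) + 0.5) * VOX
                    if np.linalg.norm(c - centre) <= radius:
                        brute.add((i, j, k))
        assert marked == brute

    def test_invalid_radius(self):
        g = VoxelGrid(voxel_size=VOX)
        with pytest.raises(ValidationError):
            g.rasterize_soma(np.zeros(3), 0.0, 0)


def two_neuron_placement(pre_morph, post_morph, pre_pos, post_pos,
                         pre_type="src", post_type="tgt"):
    neurons = [
        NeuronPlacement(0, "pre", pre_type, np.asarray(pre_pos), np.eye(3),
                        "v"),
        NeuronPlacement(1, "post", post_type, np.asarray(post_pos), np.eye(3),
                        "v"),
    ]
    return (PlacementResult(neurons, np.zeros((0, 3))),
            {"pre": pre_morph, "post": post_morph})


class TestDetectTouches:
    def test_perpendicular_crossing_one_synapse(self):
        # post dendrite along x at row y=z=1.5 um; pre axon descends in y
        # and crosses it at x = 46.5 um, far from both somas
        post = make_morphology([(1, SOMA, -30, 0, 0, 1, -1),
                                (2, BASAL_DENDRITE, 30, 0, 0, 1, 1)])
        pre = make_morphology([(1, SOMA, 0, 60, 0, 1, -1),
                               (2, AXON, 0, 55, 0, 0.5, 1),
                               (3, AXON, 0, -30, 0, 0.5, 2)])
        placement, morphs = two_neuron_placement(
            pre, post, [46.5 * UM, 1.5 * UM, 1.5 * UM],
            [31.5 * UM, 1.5 * UM, 1.5 * UM])
        syn, _ = detection.detect_network(placement, morphs, [("src", "tgt")])
        assert len(syn) == 1
        s = syn[0]
        assert (s.pre_id, s.post_id, s.voxel) == (0, 1, (15, 0, 0))
        np.testing.assert_allclose(s.position,
                                   np.array([46.5, 1.5, 1.5]) * UM)

    def test_parallel_neurites_far_apart_no_synapse(self):
        post = make_morphology([(1, SOMA, -30, 0, 0, 1, -1),
                                (2, BASAL_DENDRITE, 30, 0, 0, 1, 1)])
        pre = make_morphology([(1, SOMA, -30, 0, 0, 1, -1),
                               (2, AXON, 30, 0, 0, 0.5, 1)])
        placement, morphs = two_neuron_placement(
            pre, post, [100 * UM, 10 * UM, 100 * UM],
            [100 * UM, 0.0, 100 * UM])
        syn, _ = detection.detect_network(placement, morphs, [("src", "tgt")])
        assert syn == []

    def test_grid_fixture_four_per_pair(self):
        fx = make_grid_fixture(100, 4)
        syn = fx.detect()
        assert len(syn) == 400
        per_pair = {}
        for s in syn:
            per_pair[s.pair] = per_pair.get(s.pair, 0) + 1
        assert set(per_pair.values()) == {4}
        assert len(per_pair) == 100

    def test_disallowed_pair_ignored(self):
        fx = make_grid_fixture(3, 2)
        types = {n.id: n.neuron_type for n in fx.placement.neurons}
        grid = detection.build_grid(fx.placement, fx.morphologies,
                                    fx.origin, fx.voxel_size)
        assert detect_touches(grid, [("tgt", "src")], types) == []

    def test_relabelling_permutes_synapses(self):
        fx = make_grid_fixture(5, 3)
        syn0 = {(s.pre_id, s.post_id, s.voxel) for s in fx.detect()}
        # relabel neurons with a fixed permutation
        perm = {n.id: (n.id + 1) % 10 for n in fx.placement.neurons}
        for n in fx.placement.neurons:
            n.id = perm[n.id]
        syn1 = {(s.pre_id, s.post_id, s.voxel) for s in fx.detect()}
        assert syn1 == {(perm[a], perm[b], v) for a, b, v in syn0}


class TestGapJunctions:
    def crossing_dendrites(self):
        a = make_morphology([(1, SOMA, -30, 0, 0, 1, -1),
                             (2, BASAL_DENDRITE, 30, 0, 0, 1, 1)])
        b = make_morphology([(1, SOMA, 0, -30, 0, 1, -1),
                             (2, BASAL_DENDRITE, 0, 30, 0, 1, 1)])
        neurons = [
            NeuronPlacement(0, "a", "fs", np.array([31.5, 1.5, 1.5]) * UM,
                            np.eye(3), "v"),
            NeuronPlacement(1, "b", "fs", np.array([1.5, 31.5, 1.5]) * UM,
                            np.eye(3), "v"),
        ]
        placement = PlacementResult(neurons, np.zeros((0, 3)))
        return placement, {"a": a, "b": b}

    def test_crossing_dendrites_one_junction(self):
        placement, morphs = self.crossing_dendrites()
        _, gjs = detection.detect_network(placement, morphs, [],
                                          gap_junction_pairs=[("fs", "fs")])
        # the two dendrites cross in exactly one voxel at the origin corner
        crossing = [j for j in gjs if j.voxel == (0, 0, 0)]
        assert len(crossing) == 1
        assert (crossing[0].neuron_a, crossing[0].neuron_b) == (0, 1)

    def test_unordered_pair_stored_once(self):
        placement, morphs = self.crossing_dendrites()
        _, gjs = detection.detect_network(placement, morphs, [],
                                          gap_junction_pairs=[("fs", "fs")])
        keys = [(j.neuron_a, j.neuron_b, j.voxel) for j in gjs]
        assert len(keys) == len(set(keys))
        assert all(a < b for a, b, _ in keys)

    def test_brute_force_voxel_scan_equality(self):
        placement, morphs = self.crossing_dendrites()
        types = {n.id: n.neuron_type for n in placement.neurons}
        grid = detection.build_grid(placement, morphs, np.zeros(3), VOX)
        gjs = detect_gap_junctions(grid, [("fs", "fs")], types)
        expected = set()
        for voxel, occ in grid.dend.items():
            if 0 in occ and 1 in occ:
                expected.add((0, 1, voxel))
        assert {(j.neuron_a, j.neuron_b, j.voxel) for j in gjs} == expected


class TestHypervoxels:
    def one_neuron(self, morph, pos):
        neurons = [NeuronPlacement(0, "m", "t", np.asarray(pos), np.eye(3),
                                   "v")]
        return PlacementResult(neurons, np.zeros((0, 3))), {"m": morph}

    def test_contained_neuron_single_entry(self):
        m = make_morphology([(1, SOMA, 0, 0, 0, 1, -1),
                             (2, BASAL_DENDRITE, 10, 0, 0, 1, 1)])
        placement, morphs = self.one_neuron(m, np.full(3, 50 * UM))
        hv = assign_neurons_to_hypervoxels(placement, morphs, extent=100)
        assert list(hv) == [(0, 0, 0)]

    def test_face_crossing_two_entries(self):
        # hypervoxel edge at 100 voxels * 3 um = 300 um
        m = make_morphology([(1, SOMA, 0, 0, 0, 1, -1),
                             (2, BASAL_DENDRITE, 40, 0, 0, 1, 1)])
        placement, morphs = self.one_neuron(
            m, np.array([280 * UM, 50 * UM, 50 * UM]))
        hv = assign_neurons_to_hypervoxels(placement, morphs, extent=100)
        assert sorted(hv) == [(0, 0, 0), (1, 0, 0)]

    def test_eight_corner_span(self):
        m = make_morphology([(1, SOMA, 0, 0, 0, 1, -1),
                             (2, BASAL_DENDRITE, 20, 20, 20, 1, 1)])
        placement, morphs = self.one_neuron(
            m, np.array([290 * UM, 290 * UM, 290 * UM]))
        hv = assign_neurons_to_hypervoxels(placement, morphs, extent=100)
        assert len(hv) == 8

    def test_order_by_population_then_lattice(self):
        hv_map = {(2, 0, 0): [1], (0, 0, 0): [1, 2, 3], (1, 0, 0): [1, 2],
                  (0, 1, 0): [4, 5]}
        order = order_hypervoxels(hv_map)
        assert order == [(0, 0, 0), (0, 1, 0), (1, 0, 0), (2, 0, 0)]

    def test_empty_map(self):
        assert order_hypervoxels({}) == []

    def test_partition_independence_grid_fixture(self):
        fx = make_grid_fixture(30, 4)
        one = {(s.pre_id, s.post_id, s.voxel) for s in fx.detect()}
        split = {(s.pre_id, s.post_id, s.voxel)
                 for s in fx.detect(use_hypervoxels=True)}
        assert one == split

    def test_partition_independence_small_extent(self):
        # tiny hypervoxels force many boundary crossings
        fx = make_grid_fixture(10, 4)
        types = {n.id: n.neuron_type for n in fx.placement.neurons}
        syn, _ = detection.detect_network(
            fx.placement, fx.morphologies, fx.allowed_pairs,
            origin=fx.origin, voxel_size=fx.voxel_size,
            use_hypervoxels=True, hypervoxel_extent=4)
        one = {(s.pre_id, s.post_id, s.voxel) for s in fx.detect()}
        assert {(s.pre_id, s.post_id, s.voxel) for s in syn} == one

    def test_voxel_ownership_unique(self):
        for voxel in [(-1, 0, 5), (99, 100, 200), (-101, 50, 0)]:
            hv = hypervoxel_of(voxel, extent=100)
            assert all(hv[i] * 100 <= voxel[i] < (hv[i] + 1) * 100
                       for i in range(3))


class TestAxonDensityTouch:
    def fixture(self):
        post = make_morphology([(1, SOMA, -30, 0, 0, 1, -1),
                                (2, BASAL_DENDRITE, 300, 0, 0, 1, 1)])
        neurons = [
            NeuronPlacement(0, "post", "tgt",
                            np.array([31.5, 1.5, 1.5]) * UM, np.eye(3), "v"),
        ]
        placement = PlacementResult(neurons, np.zeros((0, 3)))
        grid = detection.build_grid(placement, {"post": post}, np.zeros(3),
                                    VOX)
        pre = NeuronPlacement(99, "pre", "src", np.zeros(3), np.eye(3), "v")
        types = {0: "tgt", 99: "src"}
        return pre, grid, types

    def test_zero_density_no_synapses(self):
        pre, grid, types = self.fixture()
        syn = axon_density_touch([pre], lambda r: 0.0, grid, types,
                                 [("src", "tgt")], rng_seed=0)
        assert syn == []

    def test_uniform_density_binomial_count(self):
        pre, grid, types = self.fixture()
        n_voxels = len(grid.dend)
        p = 0.4
        density = lambda r: p / VOX ** 3
        counts = [len(axon_density_touch([pre], density, grid, types,
                                         [("src", "tgt")], rng_seed=s))
                  for s in range(200)]
        mean = np.mean(counts)
        expect = n_voxels * p
        se = np.sqrt(n_voxels * p * (1 - p) / 200)
        assert abs(mean - expect) < 3 * se + 1e-9

    def test_shell_support(self):
        pre, grid, types = self.fixture()
        r0, r1 = 100 * UM, 150 * UM
        density = lambda r: (1.0 / VOX ** 3
                             if r0 <= np.linalg.norm(r) <= r1 else 0.0)
        syn = axon_density_touch([pre], density, grid, types,
                                 [("src", "tgt")], rng_seed=1)
        assert syn
        for s in syn:
            assert r0 <= np.linalg.norm(s.position - pre.position) <= r1

    def test_negative_density_rejected(self):
        pre, grid, types = self.fixture()
        with pytest.raises(ValidationError):
            axon_density_touch([pre], lambda r: -1.0, grid, types,
                               [("src", "tgt")], rng_seed=0)
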