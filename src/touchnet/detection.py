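"""Voxel-based touch detection of putative synapses and gap junctions.

Neurites are rasterized into cubic voxels (default 3 μm) using an exact
supercover line traversal — the limit of the "small steps along the
segment" scheme. Voxels co-occupied by an axon of one neuron and a
dendrite or soma of another (of an allowed type pair) yield one putative
synapse per (pre, post, voxel). Dendrite–dendrite co-occupancy yields gap
junctions. For parallel decomposition, voxels are grouped into hypervoxels
(default 100^3 voxels) with ownership by lattice floor division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

VOXEL_SIZE = 3e-6          #: metres
HYPERVOXEL_EXTENT = 100    #: voxels per hypervoxel side


@dataclass(frozen=True)
class Occupancy:
    neuron_id: int
    section_id: int      # child node id of the occupied segment (-1 for soma)
    offset: float        # fractional position along the segment
    path_distance: float # metres to the soma along the tree


@dataclass
class PutativeSynapse:
    pre_id: int
    post_id: int
    voxel: tuple
    position: np.ndarray          # voxel centre, metres
    section_id: int
    section_offset: float
    distance_to_soma: float       # post-synaptic path distance, metres

    @property
    def pair(self):
        return (self.pre_id, self.post_id)


@dataclass
class GapJunction:
    neuron_a: int
    neuron_b: int
    voxel: tuple
    position: np.ndarray
    section_a: int
    offset_a: float
    section_b: int
    offset_b: float


class VoxelGrid:
    """Sparse axon / dendrite voxel occupancy."""

    def __init__(self, origin=(0.0, 0.0, 0.0), voxel_size=VOXEL_SIZE):
        if voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")
        self.origin = np.asarray(origin, dtype=np.float64)
        self.voxel_size = float(voxel_size)
        self.axon = {}      # voxel -> {neuron_id: Occupancy}
        self.dend = {}      # voxel -> {neuron_id: Occupancy}
        self.voxel_filter = None   # optional predicate voxel -> bool

    def voxel_of(self, point):
        return tuple(np.floor((np.asarray(point) - self.origin)
                              / self.voxel_size).astype(np.int64))

    def voxel_centre(self, voxel):
        return self.origin + (np.asarray(voxel) + 0.5) * self.voxel_size

    def _store(self, table, voxel, occ):
        if self.voxel_filter is not None and not self.voxel_filter(voxel):
            return
        table.setdefault(voxel, {}).setdefault(occ.neuron_id, occ)

    # -- rasterization -----------------------------------------------------

    def rasterize_segment(self, p0, p1, neuron_id, kind, section_id,
                          base_distance=0.0):
        """Mark every voxel intersected by [p0, p1] (supercover traversal).

        ``base_distance`` is the path distance of p0 to the soma; the stored
        per-voxel distance is evaluated at the midpoint of the clipped
        sub-segment inside each voxel.
        """
        table = self.axon if kind == "axon" else self.dend
        seglen = float(np.linalg.norm(np.asarray(p1) - np.asarray(p0)))
        for voxel, t_in, t_out in _traverse(np.asarray(p0, dtype=float),
                                            np.asarray(p1, dtype=float),
                                            self.origin, self.voxel_size):
            t_mid = 0.5 * (t_in + t_out)
            self._store(table, voxel, Occupancy(
                neuron_id, section_id, t_mid, base_distance + t_mid * seglen))

    def rasterize_soma(self, centre, radius, neuron_id):
        """Mark voxels whose centres fall within the soma sphere (as dendrite)."""
        if radius <= 0:
            raise ValidationError("soma radius must be positive")
        centre = np.asarray(centre, dtype=float)
        lo = self.voxel_of(centre - radius)
        hi = self.voxel_of(centre + radius)
        own = self.voxel_of(centre)
        found = False
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    v = (i, j, k)
                    if np.linalg.norm(self.voxel_centre(v) - centre) <= radius:
                        self._store(self.dend, v, Occupancy(neuron_id, -1, 0.0, 0.0))
                        found = True
        if not found:
            # soma smaller than half a voxel: mark its containing voxel
            self._store(self.dend, own, Occupancy(neuron_id, -1, 0.0, 0.0))

    def rasterize_morphology(self, morph, neuron_id):
        """Rasterize a transformed morphology: axon, dendrites and soma."""
        dist = morph.path_distances()
        for kind in ("axon", "dendrite"):
            for prow, crow in morph.segments(kind):
                self.rasterize_segment(
                    morph.xyz[prow], morph.xyz[crow], neuron_id, kind,
                    int(morph.ids[crow]), base_distance=float(dist[prow]))
        self.rasterize_soma(morph.soma_center, max(morph.soma_radius, 1e-9),
                            neuron_id)


def _traverse(p0, p1, origin, h):
    """Amanatides–Woo voxel traversal; yields (voxel, t_entry, t_exit)."""
    a = (p0 - origin) / h
    b = (p1 - origin) / h
    cur = np.floor(a).astype(np.int64)
    end = np.floor(b).astype(np.int64)
    d = b - a
    t = 0.0
    step = np.sign(d).astype(np.int64)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] > 0:
            t_max[ax] = (cur[ax] + 1 - a[ax]) / d[ax]
            t_delta[ax] = 1.0 / d[ax]
        elif d[ax] < 0:
            t_max[ax] = (cur[ax] - a[ax]) / d[ax]
            t_delta[ax] = -1.0 / d[ax]
    guard = 0
    while True:
        ax = int(np.argmin(t_max))
        t_next = min(float(t_max[ax]), 1.0)
        yield tuple(cur), t, t_next
        if np.array_equal(cur, end) or t_next >= 1.0:
            return
        t = t_next
        cur[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        guard += 1
        if guard > 10_000_000:  # pragma: no cover
            raise RuntimeError("voxel traversal did not terminate")


# ---------------------------------------------------------------------------
# hypervoxels

def hypervoxel_of(voxel, extent=HYPERVOXEL_EXTENT):
    return tuple(int(math.floor(c / extent)) for c in voxel)


def assign_neurons_to_hypervoxels(placement, morphologies, origin=(0, 0, 0),
                                  voxel_size=VOXEL_SIZE,
                                  extent=HYPERVOXEL_EXTENT):
    """Map hypervoxel -> resident neuron ids, from segment bounding boxes."""
    origin = np.asarray(origin, dtype=float)
    out = {}
    for n in placement.neurons:
        morph = _transformed(morphologies, n)
        hvs = set()
        xyz = morph.xyz
        for prow, crow in morph.segments():
            lo = np.minimum(xyz[prow], xyz[crow])
            hi = np.maximum(xyz[prow], xyz[crow])
            vlo = np.floor((lo - origin) / voxel_size).astype(int)
            vhi = np.floor((hi - origin) / voxel_size).astype(int)
            hlo = np.floor(vlo / extent).astype(int)
            hhi = np.floor(vhi / extent).astype(int)
            for i in range(hlo[0], hhi[0] + 1):
                for j in range(hlo[1], hhi[1] + 1):
                    for k in range(hlo[2], hhi[2] + 1):
                        hvs.add((i, j, k))
        # soma extent
        c, r = morph.soma_center, morph.soma_radius
        vlo = np.floor((c - r - origin) / voxel_size).astype(int)
        vhi = np.floor((c + r - origin) / voxel_size).astype(int)
        for i in range(vlo[0] // extent, vhi[0] // extent + 1):
            for j in range(vlo[1] // extent, vhi[1] // extent + 1):
                for k in range(vlo[2] // extent, vhi[2] // extent + 1):
                    hvs.add((i, j, k))
        for hv in hvs:
            out.setdefault(hv, []).append(n.id)
    return out


def order_hypervoxels(hv_map):
    """Most-populated first; ties broken by lattice coordinates."""
    return sorted(hv_map, key=lambda hv: (-len(hv_map[hv]), hv))


def _transformed(morphologies, neuron):
    morph = morphologies[neuron.prototype]
    return morph.transform(neuron.rotation, neuron.position)


# ---------------------------------------------------------------------------
# detection

def build_grid(placement, morphologies, origin=(0, 0, 0),
               voxel_size=VOXEL_SIZE, voxel_filter=None, neuron_ids=None):
    grid = VoxelGrid(origin, voxel_size)
    grid.voxel_filter = voxel_filter
    for n in placement.neurons:
        if neuron_ids is not None and n.id not in neuron_ids:
            continue
        grid.rasterize_morphology(_transformed(morphologies, n), n.id)
    return grid


def detect_touches(grid, allowed_pairs, neuron_types):
    """Putative synapses from axon ∩ (dendrite ∪ soma) voxel co-occupancy."""
    allowed = set(allowed_pairs)
    synapses = []
    for voxel in sorted(set(grid.axon) & set(grid.dend)):
        for pre_id, pre_occ in sorted(grid.axon[voxel].items()):
            for post_id, post_occ in sorted(grid.dend[voxel].items()):
                if pre_id == post_id:
                    continue
                if (neuron_types[pre_id], neuron_types[post_id]) not in allowed:
                    continue
                synapses.append(PutativeSynapse(
                    pre_id, post_id, voxel, grid.voxel_centre(voxel),
                    post_occ.section_id, post_occ.offset,
                    post_occ.path_distance))
    return synapses


def detect_gap_junctions(grid, allowed_pairs, neuron_types):
    """Gap junctions from dendrite–dendrite co-occupancy (unordered, deduped)."""
    allowed = {tuple(sorted(p)) for p in allowed_pairs}
    out = []
    for voxel in sorted(grid.dend):
        occs = sorted(grid.dend[voxel].items())
        for i in range(len(occs)):
            for j in range(i + 1, len(occs)):
                a_id, a = occs[i]
                b_id, b = occs[j]
                key = tuple(sorted((neuron_types[a_id], neuron_types[b_id])))
                if key not in allowed:
                    continue
                if a_id > b_id:
                    a_id, b_id, a, b = b_id, a_id, b, a
                out.append(GapJunction(a_id, b_id, voxel,
                                       grid.voxel_centre(voxel),
                                       a.section_id, a.offset,
                                       b.section_id, b.offset))
    return out


def detect_network(placement, morphologies, allowed_pairs,
                   gap_junction_pairs=(), origin=(0, 0, 0),
                   voxel_size=VOXEL_SIZE, use_hypervoxels=False,
                   hypervoxel_extent=HYPERVOXEL_EXTENT):
    """Full detection: returns (synapses, gap_junctions).

    With ``use_hypervoxels`` the grid is decomposed into hypervoxels; each
    hypervoxel rasterizes only its resident neurons and keeps only the
    voxels it owns, so the union equals the single-grid result exactly.
    """
    neuron_types = {n.id: n.neuron_type for n in placement.neurons}
    if not use_hypervoxels:
        grid = build_grid(placement, morphologies, origin, voxel_size)
        return (detect_touches(grid, allowed_pairs, neuron_types),
                detect_gap_junctions(grid, gap_junction_pairs, neuron_types))

    hv_map = assign_neurons_to_hypervoxels(
        placement, morphologies, origin, voxel_size, hypervoxel_extent)
    synapses, gjs = [], []
    for hv in order_hypervoxels(hv_map):
        owner = (lambda hv: lambda v: hypervoxel_of(v, hypervoxel_extent) == hv)(hv)
        grid = build_grid(placement, morphologies, origin, voxel_size,
                          voxel_filter=owner, neuron_ids=set(hv_map[hv]))
        synapses.extend(detect_touches(grid, allowed_pairs, neuron_types))
        gjs.extend(detect_gap_junctions(grid, gap_junction_pairs, neuron_types))
    return synapses, gjs


def axon_density_touch(pre_neurons, density, grid, neuron_types,
                       allowed_pairs, rng_seed=0):
    """Probabilistic synapses for neurons whose axon is a density cloud.

    For each dendrite-occupied voxel of an allowed postsynaptic neuron, a
    synapse is drawn with probability ``min(1, density(r) * voxel_volume)``
    where r is the voxel centre relative to the presynaptic soma.
    """
    allowed = set(allowed_pairs)
    vol = grid.voxel_size ** 3
    out = []
    for pre in pre_neurons:
        rng = np.random.default_rng(
            np.random.SeedSequence((rng_seed, pre.id)))
        for voxel in sorted(grid.dend):
            centre = grid.voxel_centre(voxel)
            for post_id, occ in sorted(grid.dend[voxel].items()):
                if post_id == pre.id:
                    continue
                if (pre.neuron_type, neuron_types[post_id]) not in allowed:
                    continue
                d = float(density(centre - pre.position))
                if d < 0:
                    raise ValidationError("axon density evaluated negative")
                if rng.random() < min(1.0, d * vol):
                    out.append(PutativeSynapse(
                        pre.id, post_id, voxel, centre,
                        occ.section_id, occ.offset, occ.path_distance))
    return out
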