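"""Connectivity statistics and deterministic ball-and-stick test fixtures.

The fixture generators build fully specified micro-networks whose touch
detection outcome is known exactly: the grid fixture yields a fixed number
of putative synapses per directed pair, and the distance ladder places
synapses at a prescribed multiset of dendritic path distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import VOXEL_SIZE, detect_network
from .errors import TouchnetError, ValidationError
from .placement import NeuronPlacement, PlacementResult
from .swc import AXON, BASAL_DENDRITE, SOMA, Morphology

UM = 1e-6


# ---------------------------------------------------------------------------
# statistics

@dataclass
class ConnectivityCurve:
    bin_edges: np.ndarray        # metres
    connected: np.ndarray        # connected pairs per bin
    total: np.ndarray            # total pairs per bin

    @property
    def probability(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.connected / self.total, np.nan)


def connection_probability_vs_distance(placement, synapses, pre_type,
                                       post_type, bin_width=10 * UM):
    """Fraction of directed pairs with ≥1 synapse, binned by soma distance."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    pres = [n for n in placement.neurons if n.neuron_type == pre_type]
    posts = [n for n in placement.neurons if n.neuron_type == post_type]
    connected_pairs = {(s.pre_id, s.post_id) for s in synapses}
    dists, conn = [], []
    for a in pres:
        for b in posts:
            if a.id == b.id:
                continue
            dists.append(float(np.linalg.norm(a.position - b.position)))
            conn.append((a.id, b.id) in connected_pairs)
    if not dists:
        return ConnectivityCurve(np.zeros(1), np.zeros(0), np.zeros(0))
    dists = np.asarray(dists)
    conn = np.asarray(conn)
    edges = np.arange(0.0, dists.max() + bin_width, bin_width)
    total, _ = np.histogram(dists, bins=edges)
    connected, _ = np.histogram(dists[conn], bins=edges)
    return ConnectivityCurve(edges, connected, total)


def synapses_per_pair_histogram(synapses):
    """Histogram over connected pairs: synapse count -> number of pairs."""
    counts = {}
    for s in synapses:
        counts[s.pair] = counts.get(s.pair, 0) + 1
    hist = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def connected_neighbours_histogram(placement, synapses, post_type):
    """Distinct presynaptic partners per postsynaptic neuron of a type."""
    partners = {n.id: set() for n in placement.neurons
                if n.neuron_type == post_type}
    for s in synapses:
        if s.post_id in partners:
            partners[s.post_id].add(s.pre_id)
    hist = {}
    for ps in partners.values():
        hist[len(ps)] = hist.get(len(ps), 0) + 1
    return hist


def synapse_density(n_synapses, volume_mm3):
    """Synapses per cubic millimetre."""
    if volume_mm3 <= 0:
        raise ValidationError("volume must be positive")
    return n_synapses / volume_mm3


# ---------------------------------------------------------------------------
# fixtures

@dataclass
class Fixture:
    """A generated micro-network ready for touch detection."""

    morphologies: dict                 # prototype -> Morphology (local coords)
    placement: PlacementResult
    allowed_pairs: tuple               # ((pre type, post type), ...)
    origin: np.ndarray                 # detection grid origin, metres
    voxel_size: float = VOXEL_SIZE
    expected: dict = field(default_factory=dict)

    def detect(self, use_hypervoxels=False):
        syn, _ = detect_network(
            self.placement, self.morphologies, self.allowed_pairs,
            origin=self.origin, voxel_size=self.voxel_size,
            use_hypervoxels=use_hypervoxels)
        return syn


def _vox_centre(i, voxel_size):
    return (i + 0.5) * voxel_size


def _ball_and_stick(nodes):
    ids = list(range(1, len(nodes) + 1))
    tcs = [n[0] for n in nodes]
    xyz = [n[1] for n in nodes]
    radii = [n[2] for n in nodes]
    parents = [n[3] for n in nodes]
    return Morphology(ids, tcs, xyz, radii, parents)


def make_grid_fixture(pairs, synapses_per_pair, voxel_size=VOXEL_SIZE,
                      verify=False):
    """Directed pre→post pairs each touching in exactly ``synapses_per_pair``
    voxels; no other contacts.

    Each pair occupies an isolated block: the post neuron has a straight
    dendrite along x at voxel row z=5, the pre neuron's axon descends from
    above and runs inside the dendrite's voxel row for exactly
    ``synapses_per_pair`` voxels. All contact voxels sit away from both
    somas.
    """
    if pairs < 1 or synapses_per_pair < 1:
        raise ValidationError("counts must be >= 1")
    s = int(synapses_per_pair)
    vs = voxel_size
    c = lambda i: _vox_centre(i, vs)
    dend_end = 4 + s + 2

    # local morphologies, soma at origin
    post = _ball_and_stick([
        (SOMA, (0.0, 0.0, 0.0), 1 * UM, -1),
        (BASAL_DENDRITE, ((dend_end - 1) * vs, 0.0, 0.0), 0.5 * UM, 1),
    ])
    # pre soma sits 5 voxel rows above the dendrite row, axon drops at x
    # column 4 - 2 = offset 2 voxels left of the soma column, then runs +x
    pre = _ball_and_stick([
        (SOMA, (0.0, 0.0, 0.0), 1 * UM, -1),
        (AXON, (-2 * vs, 0.0, 0.0), 0.3 * UM, 1),
        (AXON, (-2 * vs, 0.0, -5 * vs), 0.3 * UM, 2),
        (AXON, ((s - 3) * vs, 0.0, -5 * vs), 0.3 * UM, 3),
    ])

    pitch = (dend_end + 10) * vs  # block spacing prevents cross-pair touches
    side = int(np.ceil(np.sqrt(pairs)))
    neurons = []
    for k in range(pairs):
        bx, by = divmod(k, side)
        base = np.array([bx * pitch * 3, by * pitch * 3, 0.0])
        post_pos = base + np.array([c(1), c(5), c(5)])
        pre_pos = base + np.array([c(6), c(5), c(10)])
        neurons.append(NeuronPlacement(
            id=k, prototype="pre", neuron_type="src", position=pre_pos,
            rotation=np.eye(3), volume_id="fixture"))
        neurons.append(NeuronPlacement(
            id=pairs + k, prototype="post", neuron_type="tgt",
            position=post_pos, rotation=np.eye(3), volume_id="fixture"))
    placement = PlacementResult(neurons, np.zeros((0, 3)))
    fixture = Fixture(
        morphologies={"pre": pre, "post": post},
        placement=placement,
        allowed_pairs=(("src", "tgt"),),
        origin=np.zeros(3),
        voxel_size=vs,
        expected={"n_synapses": pairs * s, "per_pair": s,
                  "pairs": [(k, pairs + k) for k in range(pairs)]},
    )
    if verify:
        _verify_grid(fixture)
    return fixture


def _verify_grid(fixture):
    syn = fixture.detect()
    per_pair = {}
    for s in syn:
        per_pair[s.pair] = per_pair.get(s.pair, 0) + 1
    want = fixture.expected
    if len(syn) != want["n_synapses"] or \
            sorted(per_pair) != sorted(map(tuple, want["pairs"])) or \
            set(per_pair.values()) != {want["per_pair"]}:
        raise TouchnetError("grid fixture failed its self-check")


def make_distance_ladder(distances_um=None, synapses_per_distance=20,
                         voxel_size=VOXEL_SIZE, verify=False):
    """Synapses at a prescribed multiset of dendritic path distances.

    Default distances are d = 56, 65, ..., 335 μm (alternating steps of
    9 and 21 μm). Each of ``synapses_per_distance`` replicas contributes
    one synapse at every distance: the post dendrite runs along x and the
    pre axon is a comb whose teeth drop into the dendrite's voxel row at
    the requested path distances, which are aligned to voxel centres.
    """
    if distances_um is None:
        distances_um = [56, 65, 86, 95, 116, 125, 146, 155, 176, 185, 206,
                        215, 236, 245, 266, 275, 296, 305, 326, 335]
    d = np.asarray(distances_um, dtype=float)
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValidationError("distances must be positive and increasing")
    vs = voxel_size
    vs_um = vs / UM
    c = lambda i: _vox_centre(i, vs)

    # soma x chosen so every distance lands exactly on a voxel centre of the
    # default 3 μm grid; verified below for custom distance lists
    x0_um = _vox_centre(int(np.floor(d[0] / vs_um)), vs_um) - d[0]
    contact_x_um = x0_um + d
    centres = (np.round(contact_x_um / vs_um - 0.5) + 0.5) * vs_um
    if not np.allclose(centres, contact_x_um, atol=1e-9):
        raise TouchnetError(
            "requested distances cannot all be aligned to voxel centres "
            "with this voxel size")

    dend_len = (d[-1] + 5 * vs_um) * UM
    post = _ball_and_stick([
        (SOMA, (0.0, 0.0, 0.0), 1 * UM, -1),
        (BASAL_DENDRITE, (dend_len, 0.0, 0.0), 0.5 * UM, 1),
    ])

    # pre: comb axon. Local soma at origin; spine along x five voxels above
    # the dendrite row, teeth dropping to the dendrite row at each distance.
    nodes = [(SOMA, (0.0, 0.0, 0.0), 1 * UM, -1)]
    parent = 1
    for dist in d:
        x_loc = (x0_um + dist) * UM  # relative to soma x, adjusted on placing
        nodes.append((AXON, (x_loc, 0.0, 0.0), 0.3 * UM, parent))
        parent = len(nodes)
        nodes.append((AXON, (x_loc, 0.0, -5 * vs), 0.3 * UM, parent))
    pre = _ball_and_stick(nodes)

    k = int(synapses_per_distance)
    pitch = 20 * vs
    neurons = []
    for r in range(k):
        y = c(5) + r * pitch
        post_pos = np.array([x0_um * UM, y, c(5)])
        pre_pos = np.array([0.0, y, c(10)])
        neurons.append(NeuronPlacement(
            id=r, prototype="pre", neuron_type="src", position=pre_pos,
            rotation=np.eye(3), volume_id="fixture"))
        neurons.append(NeuronPlacement(
            id=k + r, prototype="post", neuron_type="tgt", position=post_pos,
            rotation=np.eye(3), volume_id="fixture"))
    placement = PlacementResult(neurons, np.zeros((0, 3)))
    fixture = Fixture(
        morphologies={"pre": pre, "post": post},
        placement=placement,
        allowed_pairs=(("src", "tgt"),),
        origin=np.zeros(3),
        voxel_size=vs,
        expected={"distances_um": sorted(list(d) * k),
                  "n_synapses": len(d) * k},
    )
    if verify:
        syn = fixture.detect()
        got = sorted(s.distance_to_soma / UM for s in syn)
        want = fixture.expected["distances_um"]
        if len(got) != len(want) or \
                np.max(np.abs(np.array(got) - np.array(want))) > vs_um / 2:
            raise TouchnetError("distance ladder fixture failed its self-check")
    return fixture
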