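"""SWC neuron morphologies: parsing, writing, measurement, rigid transforms.

Coordinates are stored internally in metres; SWC files on disk are in
micrometres per the format convention. Node tables are kept in file order,
which is required to be topologically sorted (``parent_id < id`` or −1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SwcFormatError, ValidationError

UM = 1e-6  #: metres per micrometre

#: SWC type codes
SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4

DENDRITE_CODES = (BASAL_DENDRITE, APICAL_DENDRITE)


@dataclass
class SwcNode:
    """One row of an SWC table, in metres."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self):
        return np.array([self.x, self.y, self.z])


class Morphology:
    """A rooted neuron tree with soma / axon / dendrite partitions.

    Parameters
    ----------
    ids, type_codes, parents : int arrays, length N
    xyz : (N, 3) float array, metres
    radii : (N,) float array, metres
    """

    def __init__(self, ids, type_codes, xyz, radii, parents, validate=True,
                 allow_unknown_types=False):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.type_codes = np.asarray(type_codes, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=np.float64).reshape(-1, 3).copy()
        self.radii = np.asarray(radii, dtype=np.float64)
        self.parents = np.asarray(parents, dtype=np.int64)
        self._allow_unknown = allow_unknown_types
        self._rebuild_index()
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes, **kwargs):
        """Build from an iterable of :class:`SwcNode`."""
        nodes = list(nodes)
        return cls(
            [n.id for n in nodes],
            [n.type_code for n in nodes],
            [[n.x, n.y, n.z] for n in nodes],
            [n.radius for n in nodes],
            [n.parent_id for n in nodes],
            **kwargs,
        )

    def _rebuild_index(self):
        self.index = {int(i): row for row, i in enumerate(self.ids)}
        self.children = {int(i): [] for i in self.ids}
        for i, p in zip(self.ids, self.parents):
            if p != -1 and int(p) in self.children:
                self.children[int(p)].append(int(i))

    # -- validation -----------------------------------------------------------

    def validate(self):
        n = len(self.ids)
        if n == 0:
            raise ValidationError("empty morphology")
        if len(set(self.ids.tolist())) != n:
            raise ValidationError("duplicate node ids")
        if np.any(self.ids <= 0):
            raise ValidationError("node ids must be positive")
        if np.any(self.radii <= 0):
            raise ValidationError("radii must be positive")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise ValidationError(f"expected exactly one root, found {len(roots)}")
        for i, p in zip(self.ids, self.parents):
            if p == -1:
                continue
            if int(p) not in self.index:
                raise ValidationError(f"node {i}: parent {p} does not exist")
            if p >= i:
                raise ValidationError(
                    f"node {i}: parent {p} not before child (ids must be sorted)")
        known = {SOMA, AXON, *DENDRITE_CODES}
        bad = set(self.type_codes.tolist()) - known
        if bad and not self._allow_unknown:
            raise ValidationError(f"unknown SWC type codes {sorted(bad)} "
                                  "(pass allow_unknown_types=True to treat as dendrite)")
        # axon and dendrite must not descend from each other
        for i in self.ids:
            p = int(self.parents[self.index[int(i)]])
            if p == -1:
                continue
            tc, tp = self._kind(int(i)), self._kind(p)
            if {tc, tp} == {"axon", "dendrite"}:
                raise ValidationError(
                    f"node {i}: {tc} attached to {tp} parent")

    def _kind(self, node_id):
        tc = int(self.type_codes[self.index[node_id]])
        if tc == SOMA:
            return "soma"
        if tc == AXON:
            return "axon"
        return "dendrite"  # 3, 4 and (optionally) unknown codes

    # -- basic queries --------------------------------------------------------

    def __len__(self):
        return len(self.ids)

    @property
    def root_id(self):
        return int(self.ids[np.flatnonzero(self.parents == -1)[0]])

    def rows_of_kind(self, kind):
        """Row indices of soma / axon / dendrite nodes."""
        if kind == "soma":
            mask = self.type_codes == SOMA
        elif kind == "axon":
            mask = self.type_codes == AXON
        else:
            mask = (self.type_codes != SOMA) & (self.type_codes != AXON)
        return np.flatnonzero(mask)

    @property
    def soma_center(self):
        """Centroid of the soma points (multi-point somas collapse to a sphere)."""
        return self.xyz[self.rows_of_kind("soma")].mean(axis=0)

    @property
    def soma_radius(self):
        rows = self.rows_of_kind("soma")
        if len(rows) == 1:
            return float(self.radii[rows[0]])
        c = self.xyz[rows].mean(axis=0)
        return float(np.max(np.linalg.norm(self.xyz[rows] - c, axis=1)))

    def leaves(self):
        return [i for i, ch in self.children.items() if not ch]

    def subtree_ids(self, node_id):
        """All ids in the subtree rooted at ``node_id`` (inclusive), preorder."""
        out, stack = [], [node_id]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def segments(self, kind=None):
        """Yield (parent_row, child_row) for every parent–child edge.

        ``kind`` restricts to edges whose child is of that compartment kind.
        """
        for row, (i, p) in enumerate(zip(self.ids, self.parents)):
            if p == -1:
                continue
            if kind is not None and self._kind(int(i)) != kind:
                continue
            yield self.index[int(p)], row

    def segment_lengths(self, kind=None):
        rows = list(self.segments(kind))
        if not rows:
            return np.zeros(0)
        pr = np.array([a for a, _ in rows])
        cr = np.array([b for _, b in rows])
        return np.linalg.norm(self.xyz[cr] - self.xyz[pr], axis=1)

    def total_length(self, kind="dendrite"):
        """Total cable length of a compartment kind, metres."""
        return float(self.segment_lengths(kind).sum())

    def path_distance_to_soma(self, node_id):
        """Cable distance (metres) from ``node_id`` to the root along the tree."""
        if node_id not in self.index:
            raise KeyError(f"unknown node id {node_id}")
        d = 0.0
        i = node_id
        while True:
            row = self.index[i]
            p = int(self.parents[row])
            if p == -1:
                return d
            d += float(np.linalg.norm(self.xyz[row] - self.xyz[self.index[p]]))
            i = p

    def path_distances(self):
        """Vector of path distances to the root, one per node (metres)."""
        out = np.zeros(len(self.ids))
        for prow, crow in self.segments():
            out[crow] = out[prow] + np.linalg.norm(self.xyz[crow] - self.xyz[prow])
        return out

    # -- transforms -----------------------------------------------------------

    def copy(self):
        return Morphology(self.ids.copy(), self.type_codes.copy(), self.xyz.copy(),
                          self.radii.copy(), self.parents.copy(), validate=False,
                          allow_unknown_types=self._allow_unknown)

    def transform(self, rotation, translation):
        """Rigid transform: ``x -> R x + t``. Returns a new Morphology."""
        R = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or \
                not math.isclose(np.linalg.det(R), 1.0, abs_tol=1e-9):
            raise ValidationError("rotation must be orthonormal with determinant +1")
        m = self.copy()
        m.xyz = self.xyz @ R.T + t
        return m


# -- SWC I/O ------------------------------------------------------------------

def read_swc(path, allow_unknown_types=False):
    """Read an SWC file (μm on disk) into a :class:`Morphology` in metres."""
    path = Path(path)
    nodes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SwcFormatError(f"expected 7 columns, got {len(cols)}", lineno)
            try:
                nid, tc = int(cols[0]), int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                pid = int(cols[6])
            except ValueError as e:
                raise SwcFormatError(str(e), lineno) from None
            if pid == nid:
                raise SwcFormatError(f"node {nid} is its own parent", lineno)
            nodes.append(SwcNode(nid, tc, x * UM, y * UM, z * UM, r * UM, pid))
    if not nodes:
        raise SwcFormatError(f"no nodes in {path}")
    try:
        return Morphology.from_nodes(nodes, allow_unknown_types=allow_unknown_types)
    except ValidationError as e:
        raise SwcFormatError(str(e)) from None


def _fmt(v):
    # 6 significant digits keeps write -> read -> write bit-stable
    return f"{v:.6g}"


def write_swc(morphology, path):
    """Write a morphology to SWC (converting metres back to μm)."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    for row, nid in enumerate(morphology.ids):
        x, y, z = morphology.xyz[row] / UM
        r = morphology.radii[row] / UM
        lines.append(" ".join([
            str(int(nid)), str(int(morphology.type_codes[row])),
            _fmt(x), _fmt(y), _fmt(z), _fmt(r),
            str(int(morphology.parents[row])),
        ]))
    path.write_text("\n".join(lines) + "\n")


@dataclass
class NeuronPrototype:
    """A named, reusable single-neuron model description."""

    name: str
    neuron_type: str
    morphology_path: str = None
    parameter_set: str = None
    mechanism_set: str = None
    modulation_set: str = None
    is_virtual: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        # virtual neurons carry only an axon morphology and a spike train;
        # they never need parameter or mechanism sets
        if not self.is_virtual and self.parameter_set is None and \
                self.mechanism_set is None:
            pass  # metadata is opaque here; downstream simulators may require it
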