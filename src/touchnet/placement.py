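"""Constrained soma placement inside mesh- or cube-bounded volumes.

Somas are rejection-sampled uniformly in the (padded) bounding box; a
candidate is accepted when it lies inside the volume and no earlier soma —
accepted or padding — is closer than ``d_min``. Candidates outside the
volume that satisfy ``d_min`` are retained as padding so that the density
stays flat up to the border.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import PlacementError, TouchnetError, ValidationError

MAX_CONSECUTIVE_REJECTIONS = 1_000_000
PACKING_LIMIT = 0.3  # fraction of the volume occupied by d_min/2 spheres


# ---------------------------------------------------------------------------
# triangle meshes (Wavefront OBJ)

class TriMesh:
    """A triangle soup with vertex array (V,3) and face index array (F,3)."""

    def __init__(self, vertices, faces):
        self.vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) == 0:
            raise TouchnetError("mesh has no faces")

    @property
    def bounds(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    @property
    def triangles(self):
        return self.vertices[self.faces]

    def is_watertight(self):
        """True when every undirected edge is shared by exactly two faces."""
        edges = {}
        for f in self.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        return all(c == 2 for c in edges.values())


def load_obj(path):
    """Load a Wavefront OBJ file, fan-triangulating polygonal faces."""
    path = Path(path)
    verts, faces = [], []
    with open(path) as fh:
        for raw in fh:
            parts = raw.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(v) for v in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                for k in range(1, len(idx) - 1):
                    faces.append([idx[0], idx[k], idx[k + 1]])
    return TriMesh(verts, faces)


_RAY_DIR = np.array([0.5773502691896258, 0.5773502691896257, 0.5773502691896259])


def _ray_crossings(mesh, origins, direction=_RAY_DIR):
    """Number of ray–triangle intersections per origin (Möller–Trumbore)."""
    tri = mesh.triangles
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    d = direction / np.linalg.norm(direction)
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-14
    counts = np.zeros(len(origins), dtype=np.int64)
    inv = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    for k, o in enumerate(origins):
        s = o - v0
        u = np.einsum("ij,ij->i", s, h) * inv
        q = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        counts[k] = int(hit.sum())
    return counts


def _tri_box_overlap(tri, box_center, half):
    """Triangle vs axis-aligned-box separating-axis test (Akenine-Möller)."""
    v = tri - box_center
    # box face normals
    lo, hi = v.min(axis=0), v.max(axis=0)
    if np.any(lo > half) or np.any(hi < -half):
        return False
    e = np.array([v[1] - v[0], v[2] - v[1], v[0] - v[2]])
    n = np.cross(e[0], e[1])
    # triangle plane
    r = float(np.dot(half, np.abs(n)))
    s = float(np.dot(n, v[0]))
    if abs(s) > r:
        return False
    # nine cross-axis tests
    for i in range(3):
        for j in range(3):
            axis = np.zeros(3)
            axis[j] = 1.0
            a = np.cross(e[i], axis)
            if np.allclose(a, 0):
                continue
            p = v @ a
            rad = float(np.dot(half, np.abs(a)))
            if p.min() > rad or p.max() < -rad:
                return False
    return True


OUTSIDE, INSIDE, BORDER = 0, 1, 2


class MeshVoxelGrid:
    """Inside/outside/border labelling of a mesh on a regular grid."""

    def __init__(self, mesh, bin_width, strict=True):
        if bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if strict and not mesh.is_watertight():
            raise ValidationError(
                "mesh is not watertight; pass strict=False to proceed with "
                "ray-parity labelling anyway")
        self.mesh = mesh
        self.bin_width = float(bin_width)
        lo, hi = mesh.bounds
        self.origin = lo - bin_width
        self.shape = tuple(
            int(math.ceil(v)) for v in (hi - self.origin) / bin_width + 1)
        self.labels = np.zeros(self.shape, dtype=np.uint8)
        self.centre_inside = np.zeros(self.shape, dtype=bool)
        self._build()

    def _build(self):
        nx, ny, nz = self.shape
        bw = self.bin_width
        # border: voxels overlapping any triangle; tiny expansion so exact
        # face-on-boundary contact (axis-aligned meshes) counts as overlap
        half = np.full(3, bw / 2 * (1 + 1e-9) + 1e-12)
        for tri in self.mesh.triangles:
            lo = np.floor((tri.min(axis=0) - self.origin) / bw).astype(int)
            hi = np.floor((tri.max(axis=0) - self.origin) / bw).astype(int)
            lo = np.clip(lo, 0, np.array(self.shape) - 1)
            hi = np.clip(hi, 0, np.array(self.shape) - 1)
            for i in range(lo[0], hi[0] + 1):
                for j in range(lo[1], hi[1] + 1):
                    for k in range(lo[2], hi[2] + 1):
                        if self.labels[i, j, k] == BORDER:
                            continue
                        c = self.origin + (np.array([i, j, k]) + 0.5) * bw
                        if _tri_box_overlap(tri, c, half):
                            self.labels[i, j, k] = BORDER
        # inside: ray parity at voxel centres of the remaining voxels
        centres_z = self.origin[2] + (np.arange(nz) + 0.5) * bw
        tri = self.mesh.triangles
        v0 = tri[:, 0]
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        n = np.cross(e1, e2)
        # irrational sub-voxel jitter keeps rays off triangle edges and
        # diagonals of fan-triangulated quads (avoids parity double counts)
        jx, jy = 2 ** -0.5 * 1e-6, 3 ** -0.5 * 1e-6
        for i in range(nx):
            x = self.origin[0] + (i + 0.5 + jx) * bw
            for j in range(ny):
                y = self.origin[1] + (j + 0.5 + jy) * bw
                # intersect the +z column with every triangle
                zs = _column_crossings(v0, e1, e2, n, x, y)
                if zs.size == 0:
                    continue
                zs.sort()
                idx = np.searchsorted(zs, centres_z)
                inside = (zs.size - idx) % 2 == 1
                self.centre_inside[i, j] = inside
                col = self.labels[i, j]
                col[(col != BORDER) & inside] = INSIDE

    def label_at(self, point):
        ijk = np.floor((np.asarray(point) - self.origin) / self.bin_width).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(self.shape)):
            return OUTSIDE
        return int(self.labels[tuple(ijk)])

    def inside_volume(self):
        """Unbiased volume estimate: voxels whose centre lies inside."""
        return float(self.centre_inside.sum()) * self.bin_width ** 3


def _column_crossings(v0, e1, e2, n, x, y):
    """z values where the vertical line (x, y) crosses the triangles."""
    denom = n[:, 2]
    ok = np.abs(denom) > 1e-30
    px = x - v0[:, 0]
    py = y - v0[:, 1]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    ok &= np.abs(det) > 1e-30
    det_safe = np.where(ok, det, 1.0)
    u = (px * e2[:, 1] - py * e2[:, 0]) / det_safe
    v = (e1[:, 0] * py - e1[:, 1] * px) / det_safe
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
    z = v0[:, 2] + u * e1[:, 2] + v * e2[:, 2]
    return z[hit]


def voxelize_mesh(mesh, bin_width, strict=True):
    """Label a regular grid over the mesh as inside / outside / border."""
    return MeshVoxelGrid(mesh, bin_width, strict=strict)


def is_inside(grid, mesh, point):
    """Inside test via grid lookup; border voxels fall back to ray parity."""
    label = grid.label_at(point)
    if label == INSIDE:
        return True
    if label == OUTSIDE:
        return False
    return int(_ray_crossings(mesh, np.atleast_2d(point))[0]) % 2 == 1


# ---------------------------------------------------------------------------
# volume specifications

@dataclass
class VolumeSpec:
    """A named placement volume: a watertight mesh or an axis-aligned cube."""

    name: str
    type: str = "cube"               # 'mesh' | 'cube'
    d_min: float = 1.5e-5            # metres
    mesh_file: str = None
    mesh_bin_width: float = 1e-4
    side: float = 5e-4               # cube side, metres
    centre: tuple = (0.0, 0.0, 0.0)

    _mesh: TriMesh = field(default=None, repr=False, compare=False)
    _grid: MeshVoxelGrid = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.d_min < 0:
            raise ValidationError("d_min must be non-negative")
        if self.type not in ("mesh", "cube"):
            raise ValidationError(f"unknown volume type {self.type!r}")
        if self.type == "mesh":
            if self.mesh_file is None:
                raise ValidationError("mesh volume requires mesh_file")
            if self.mesh_bin_width <= 0:
                raise ValidationError("mesh_bin_width must be positive")

    def _ensure_mesh(self):
        if self._mesh is None:
            self._mesh = load_obj(self.mesh_file)
            self._grid = voxelize_mesh(self._mesh, self.mesh_bin_width)

    @property
    def bounds(self):
        if self.type == "cube":
            c = np.asarray(self.centre)
            h = self.side / 2
            return c - h, c + h
        self._ensure_mesh()
        return self._mesh.bounds

    def contains(self, point):
        if self.type == "cube":
            lo, hi = self.bounds
            p = np.asarray(point)
            return bool(np.all(p >= lo) and np.all(p < hi))
        self._ensure_mesh()
        return is_inside(self._grid, self._mesh, point)

    def volume(self):
        if self.type == "cube":
            return self.side ** 3
        self._ensure_mesh()
        return self._grid.inside_volume()


@dataclass
class PopulationUnitSpec:
    unit_id: int
    volume: str
    neuron_types: list
    fraction: float

    def __post_init__(self):
        if self.unit_id <= 0:
            raise ValidationError("unit_id must be a positive integer")
        if not 0 <= self.fraction <= 1:
            raise ValidationError("fraction must be in [0, 1]")


@dataclass
class NeuronPlacement:
    id: int
    prototype: str
    neuron_type: str
    position: np.ndarray
    rotation: np.ndarray
    volume_id: str
    population_unit: int = 0


@dataclass
class PlacementResult:
    neurons: list                    # of NeuronPlacement
    padding_positions: np.ndarray    # (M, 3) metres

    def __len__(self):
        return len(self.neurons)

    @property
    def positions(self):
        return np.array([n.position for n in self.neurons]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# placement proper

class _HashGrid:
    """Exact d_min neighbour queries via a spatial hash with cell = d_min."""

    def __init__(self, d_min):
        self.d = d_min
        self.cells = {}
        self.points = []

    def _key(self, p):
        return tuple(np.floor(p / self.d).astype(int)) if self.d > 0 else (0,)

    def too_close(self, p):
        if self.d <= 0:
            return False
        k = self._key(p)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    for idx in self.cells.get((k[0] + di, k[1] + dj, k[2] + dk), ()):
                        if np.linalg.norm(self.points[idx] - p) < self.d:
                            return True
        return False

    def add(self, p):
        self.points.append(p)
        self.cells.setdefault(self._key(p), []).append(len(self.points) - 1)


def sample_rotation(mode="random", rng=None):
    """Sample one rotation matrix: identity for 'none', uniform for 'random'."""
    if mode in ("none", None):
        return np.eye(3)
    if mode != "random":
        raise ValidationError(f"unknown rotation mode {mode!r}")
    rng = np.random.default_rng(rng)
    return Rotation.random(rng=rng).as_matrix()


def place_neurons(volume, counts, rng_seed=0, rotation_modes=None,
                  neuron_types=None, use_padding=True):
    """Place somas with minimum separation inside a volume.

    Parameters
    ----------
    volume : VolumeSpec
    counts : mapping prototype name -> number of somas
    rotation_modes : mapping prototype -> 'none' | 'random'
    neuron_types : mapping prototype -> type name (defaults to the prototype)
    use_padding : track out-of-volume candidates to keep border density flat
    """
    n_total = int(sum(counts.values()))
    if any(c < 0 for c in counts.values()):
        raise ValidationError("counts must be non-negative")
    d_min = volume.d_min
    vol = volume.volume()
    if d_min > 0 and n_total * (4 * math.pi / 3) * (d_min / 2) ** 3 > PACKING_LIMIT * vol:
        raise PlacementError(
            f"requested density infeasible: {n_total} somas at d_min={d_min} "
            f"exceed {PACKING_LIMIT:.0%} packing of {vol} m^3")

    rng = np.random.default_rng(rng_seed)
    # instantiate prototypes in random order across the id sequence
    protos = [p for p, c in sorted(counts.items()) for _ in range(int(c))]
    rng.shuffle(protos)

    lo, hi = volume.bounds
    lo = np.asarray(lo, dtype=float) - d_min
    hi = np.asarray(hi, dtype=float) + d_min

    grid = _HashGrid(d_min)
    accepted, padding = [], []
    rejections = 0
    while len(accepted) < n_total:
        p = rng.uniform(lo, hi)
        if grid.too_close(p):
            rejections += 1
            if rejections > MAX_CONSECUTIVE_REJECTIONS:
                raise PlacementError("placement stalled: too many rejections")
            continue
        rejections = 0
        if volume.contains(p):
            grid.add(p)
            accepted.append(p)
        elif use_padding:
            grid.add(p)
            padding.append(p)

    neurons = []
    for i, (proto, pos) in enumerate(zip(protos, accepted)):
        mode = (rotation_modes or {}).get(proto, "random")
        ntype = (neuron_types or {}).get(proto, proto)
        neurons.append(NeuronPlacement(
            id=i, prototype=proto, neuron_type=ntype, position=np.asarray(pos),
            rotation=sample_rotation(mode, rng), volume_id=volume.name))
    return PlacementResult(neurons, np.array(padding).reshape(-1, 3))


def assign_population_units(placement, units, rng_seed=0):
    """Assign neurons to population units with per-type fractions."""
    by_type = {}
    for u in units:
        for t in u.neuron_types:
            by_type.setdefault(t, []).append(u)
    for t, us in by_type.items():
        if sum(u.fraction for u in us) > 1 + 1e-12:
            raise ValidationError(f"unit fractions for type {t!r} sum above 1")
    rng = np.random.default_rng(rng_seed)
    for n in placement.neurons:
        us = by_type.get(n.neuron_type, [])
        r = rng.random()
        acc = 0.0
        n.population_unit = 0
        for u in us:
            acc += u.fraction
            if r < acc:
                n.population_unit = u.unit_id
                break
    return placement
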