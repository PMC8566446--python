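"""Shared fixtures: programmatic morphologies and meshes (no binary data)."""

import numpy as np
import pytest

from touchnet.placement import TriMesh
from touchnet.swc import AXON, BASAL_DENDRITE, SOMA, Morphology

UM = 1e-6


def make_morphology(rows):
    """rows: (id, type, x_um, y_um, z_um, r_um, parent)."""
    return Morphology(
        [r[0] for r in rows],
        [r[1] for r in rows],
        [[r[2] * UM, r[3] * UM, r[4] * UM] for r in rows],
        [r[5] * UM for r in rows],
        [r[6] for r in rows],
    )


def ball_and_stick(n_dend=5, n_axon=5, step_um=10.0):
    """Soma at origin, straight dendrite along +x, straight axon along -x."""
    rows = [(1, SOMA, 0, 0, 0, 5, -1)]
    parent = 1
    for k in range(1, n_dend + 1):
        rows.append((len(rows) + 1, BASAL_DENDRITE, k * step_um, 0, 0, 1, parent))
        parent = len(rows)
    parent = 1
    for k in range(1, n_axon + 1):
        rows.append((len(rows) + 1, AXON, -k * step_um, 0, 0, 0.5, parent))
        parent = len(rows)
    return make_morphology(rows)


def y_tree(step_um=10.0):
    """Soma with one dendrite that bifurcates into two branches."""
    rows = [
        (1, SOMA, 0, 0, 0, 5, -1),
        (2, BASAL_DENDRITE, step_um, 0, 0, 1, 1),
        (3, BASAL_DENDRITE, 2 * step_um, 0, 0, 1, 2),
        (4, BASAL_DENDRITE, 3 * step_um, step_um, 0, 1, 3),
        (5, BASAL_DENDRITE, 4 * step_um, 2 * step_um, 0, 1, 4),
        (6, BASAL_DENDRITE, 3 * step_um, -step_um, 0, 1, 3),
        (7, BASAL_DENDRITE, 4 * step_um, -2 * step_um, 0, 1, 6),
    ]
    return make_morphology(rows)


def random_tree(rng, n_nodes=20):
    """A random valid dendritic tree for property tests."""
    rows = [(1, SOMA, 0, 0, 0, 5, -1)]
    pos = {1: np.zeros(3)}
    for i in range(2, n_nodes + 2):
        parent = int(rng.integers(1, i))
        p = pos[parent] + rng.normal(scale=8.0, size=3)
        pos[i] = p
        rows.append((i, BASAL_DENDRITE, *np.round(p, 3), 1.0, parent))
    return make_morphology(rows)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()


# -- meshes -----------------------------------------------------------------

def cube_obj_text(side=1.0, origin=(0.0, 0.0, 0.0), quads=False):
    o = np.asarray(origin, dtype=float)
    v = [o + side * np.array([x, y, z])
         for x in (0, 1) for y in (0, 1) for z in (0, 1)]
    lines = [f"v {p[0]} {p[1]} {p[2]}" for p in v]
    quad_faces = [
        (1, 2, 4, 3), (5, 7, 8, 6),   # x faces
        (1, 5, 6, 2), (3, 4, 8, 7),   # y faces
        (1, 3, 7, 5), (2, 6, 8, 4),   # z faces
    ]
    for q in quad_faces:
        if quads:
            lines.append("f " + " ".join(str(i) for i in q))
        else:
            lines.append(f"f {q[0]} {q[1]} {q[2]}")
            lines.append(f"f {q[0]} {q[2]} {q[3]}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def cube_obj(tmp_path):
    path = tmp_path / "cube.obj"
    path.write_text(cube_obj_text())
    return path


def icosphere(radius=1.0, subdivisions=2):
    t = (1 + 5 ** 0.5) / 2
    verts = [np.array(p, dtype=float) for p in [
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]]]
    verts = [p / np.linalg.norm(p) for p in verts]
    faces = [[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
             [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
             [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
             [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]]
    for _ in range(subdivisions):
        cache = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = (verts[a] + verts[b]) / 2
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = new_faces
    return TriMesh(np.array(verts) * radius, faces)
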