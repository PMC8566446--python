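"""Repair and augmentation of SWC reconstructions.

Covers the typical slice-artefact corrections — z-jump repair (align /
split / tilt / join), grafting of cut neurites from intact donor branches,
shrinkage correction and unravelling — plus length-preserving random
variability (jitter / twist / rotate / scale3d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import RepairError, ValidationError
from .swc import Morphology

UM = 1e-6


@dataclass
class ZJump:
    """A presumed reconstruction discontinuity along the optical axis."""

    node_id: int
    dz: float            # signed z offset, metres
    threshold: float     # detection threshold used, metres


@dataclass
class CutPoint:
    """A terminal node lying on a slice face."""

    node_id: int
    face: str            # '+z' or '-z'


# ---------------------------------------------------------------------------
# tree helpers

def _rotation_between(u, v):
    """Rotation matrix mapping unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite vectors: rotate 180 degrees about any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_angle(perp, math.pi)
    axis = axis / s
    return _axis_angle(axis, math.atan2(s, c))


def _axis_angle(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _rotate_subtree(m, node_id, R, about):
    """Rigidly rotate the subtree rooted at node_id about point ``about``."""
    rows = [m.index[i] for i in m.subtree_ids(node_id)]
    m.xyz[rows] = (m.xyz[rows] - about) @ np.asarray(R).T + about


def branch_orders(m):
    """Centrifugal branch order per node id (increments at multifurcations)."""
    orders = {m.root_id: 0}
    stack = [m.root_id]
    while stack:
        i = stack.pop()
        ch = m.children[i]
        inc = 1 if len(ch) > 1 else 0
        for c in ch:
            orders[c] = orders[i] + inc
            stack.append(c)
    return orders


def sections(m, kind="dendrite"):
    """Maximal unbranched chains of the given kind.

    Returns a list of (anchor_id, [node ids]) where the anchor is the chain's
    parent (root or a branch point) and the chain ends at a leaf or branch
    point.
    """
    out = []
    for i in m.ids:
        i = int(i)
        p = int(m.parents[m.index[i]])
        if p == -1 or m._kind(i) != kind:
            continue
        # chain starts where the parent is a branch point, the root, or of
        # another compartment kind
        if m._kind(p) == kind and len(m.children[p]) == 1:
            continue
        chain = [i]
        while len(m.children[chain[-1]]) == 1:
            nxt = m.children[chain[-1]][0]
            if m._kind(nxt) != kind:
                break
            chain.append(nxt)
        out.append((p, chain))
    return out


def renumber(m):
    """Re-id nodes in preorder so that parent < child everywhere."""
    order = m.subtree_ids(m.root_id)
    newid = {old: k + 1 for k, old in enumerate(order)}
    rows = [m.index[i] for i in order]
    return Morphology(
        np.arange(1, len(order) + 1),
        m.type_codes[rows],
        m.xyz[rows],
        m.radii[rows],
        [newid[int(m.parents[r])] if m.parents[r] != -1 else -1 for r in rows],
    )


# ---------------------------------------------------------------------------
# z-jump repair

def detect_zjumps(m, dz_threshold=3 * UM):
    """Find parent→child steps dominated by a large z offset."""
    if dz_threshold <= 0:
        raise ValidationError("dz_threshold must be positive")
    jumps = []
    for prow, crow in m.segments():
        d = m.xyz[crow] - m.xyz[prow]
        dz = float(d[2])
        if abs(dz) > dz_threshold and math.hypot(d[0], d[1]) < abs(dz):
            jumps.append(ZJump(int(m.ids[crow]), dz, dz_threshold))
    return jumps


def repair_zjump(m, jump, method="align"):
    """Remove a z-jump. Methods: align | split | tilt | join."""
    if method not in ("align", "split", "tilt", "join"):
        raise ValidationError(f"unknown z-jump repair method {method!r}")
    m = m.copy()
    node = jump.node_id
    prow = m.index[int(m.parents[m.index[node]])]

    if method == "align":
        rows = [m.index[i] for i in m.subtree_ids(node)]
        m.xyz[rows, 2] -= jump.dz
        return m

    if method == "split":
        # taper the correction linearly along the jump node's section
        chain = [node]
        while len(m.children[chain[-1]]) == 1:
            chain.append(m.children[chain[-1]][0])
        k = len(chain)
        for j, nid in enumerate(chain):
            m.xyz[m.index[nid], 2] -= jump.dz * (k - j) / k
        return m

    if method == "tilt":
        # rotate the subtree about the jump's parent so the jump node comes
        # down to the parent's z level
        pa = m.xyz[prow]
        v = m.xyz[m.index[node]] - pa
        h = math.hypot(v[0], v[1])
        if h < 1e-12:
            target = np.array([np.linalg.norm(v), 0.0, 0.0])
        else:
            target = np.array([v[0], v[1], 0.0]) * (np.linalg.norm(v) / h)
        R = _rotation_between(v, target)
        _rotate_subtree(m, node, R, pa)
        return m

    # join: accept the offset as real; subdivide the jump segment so no
    # single step exceeds the detection threshold
    k = int(math.ceil(abs(jump.dz) / jump.threshold)) + 1
    pa, nd = m.xyz[prow], m.xyz[m.index[node]]
    nrow = m.index[node]
    new_id = int(m.ids.max())
    ids, tcs, xyz, radii, parents = (list(m.ids), list(m.type_codes),
                                     [list(p) for p in m.xyz], list(m.radii),
                                     list(m.parents))
    prev = int(m.parents[nrow])
    for j in range(1, k):
        new_id += 1
        t = j / k
        ids.append(new_id)
        tcs.append(int(m.type_codes[nrow]))
        xyz.append(list(pa + t * (nd - pa)))
        radii.append(float(m.radii[nrow]))
        parents.append(prev)
        prev = new_id
    parents[nrow] = prev
    out = Morphology(ids, tcs, xyz, radii, parents, validate=False)
    return renumber(out)


# ---------------------------------------------------------------------------
# cut-neurite repair

def detect_cut_points(m, z_tolerance=1 * UM):
    """Leaves lying within tolerance of the slice faces (global z extremes)."""
    zmax = float(m.xyz[:, 2].max())
    zmin = float(m.xyz[:, 2].min())
    cuts = []
    for leaf in sorted(m.leaves()):
        z = float(m.xyz[m.index[leaf], 2])
        if m._kind(leaf) == "soma":
            continue
        if zmax - z <= z_tolerance:
            cuts.append(CutPoint(leaf, "+z"))
        elif z - zmin <= z_tolerance:
            cuts.append(CutPoint(leaf, "-z"))
    return cuts


def repair_cut(m, cuts, rng_seed=0):
    """Extend cut leaves by grafting intact donor branches of equal order."""
    if not cuts:
        return m.copy()
    rng = np.random.default_rng(rng_seed)
    orders = branch_orders(m)
    cut_ids = {c.node_id for c in cuts}

    # donor branch starts: nodes opening a section whose subtree is intact
    donors = {}
    for anchor, chain in sections(m, "dendrite"):
        sub = set(m.subtree_ids(chain[0]))
        if sub & cut_ids:
            continue
        donors.setdefault(orders[chain[0]], []).append(chain[0])

    ids = list(m.ids)
    tcs = list(m.type_codes)
    xyz = [list(p) for p in m.xyz]
    radii = list(m.radii)
    parents = list(m.parents)
    next_id = int(m.ids.max())

    for cut in cuts:
        order = orders[cut.node_id]
        cands = donors.get(order)
        if not cands:
            raise RepairError(
                f"no intact donor branch of order {order} for cut leaf {cut.node_id}")
        donor = cands[rng.integers(len(cands))]
        drows = [m.index[i] for i in m.subtree_ids(donor)]
        anchor = m.xyz[m.index[int(m.parents[m.index[donor]])]]
        rel = m.xyz[drows] - anchor

        leaf_row = m.index[cut.node_id]
        leaf_pos = m.xyz[leaf_row]
        lp = int(m.parents[leaf_row])
        u_cut = leaf_pos - m.xyz[m.index[lp]]
        if np.linalg.norm(u_cut) < 1e-12:
            u_cut = np.array([0.0, 0.0, 1.0 if cut.face == "+z" else -1.0])
        u_donor = m.xyz[m.index[donor]] - anchor
        R = _rotation_between(u_donor, u_cut)
        placed = rel @ R.T + leaf_pos

        # mirror across the cut face so the graft folds back into the slice
        dzs = placed[:, 2] - leaf_pos[2]
        if (cut.face == "+z" and dzs.sum() > 0) or \
                (cut.face == "-z" and dzs.sum() < 0):
            placed[:, 2] = leaf_pos[2] - dzs

        remap = {}
        for k, drow in enumerate(drows):
            next_id += 1
            remap[int(m.ids[drow])] = next_id
            ids.append(next_id)
            tcs.append(int(m.type_codes[drow]))
            xyz.append(list(placed[k]))
            radii.append(float(m.radii[drow]))
            op = int(m.parents[drow])
            parents.append(cut.node_id if op not in remap else remap[op])

    out = Morphology(ids, tcs, xyz, radii, parents, validate=False)
    return renumber(out)


# ---------------------------------------------------------------------------
# shrinkage correction

def shrinkage_correct(m, xy_scale=1.0, z_scale=1.0):
    """Scale x,y by one factor and z by another; radii are untouched."""
    if xy_scale <= 0 or z_scale <= 0:
        raise ValidationError("scale factors must be positive")
    out = m.copy()
    out.xyz[:, 0] *= xy_scale
    out.xyz[:, 1] *= xy_scale
    out.xyz[:, 2] *= z_scale
    return out


def unravel(m, window=5):
    """Stretch contracted dendrites along their windowed principal axes.

    Each dendritic section is re-laid segment by segment: every segment keeps
    its exact length but takes the direction of the principal axis of the
    surrounding window of points (sign-aligned with the original segment).
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    out = m.copy()
    new_pos = {int(i): out.xyz[out.index[int(i)]].copy() for i in out.ids}

    # process sections root-outwards so anchors are final before their chains
    secs = sections(m, "dendrite")
    dist = m.path_distances()
    secs.sort(key=lambda s: dist[m.index[s[1][0]]])

    for anchor, chain in secs:
        pts = np.array([m.xyz[m.index[anchor]]] +
                       [m.xyz[m.index[i]] for i in chain])
        nseg = len(chain)
        cur = new_pos[anchor].copy()
        for j in range(nseg):
            seg = pts[j + 1] - pts[j]
            length = np.linalg.norm(seg)
            lo = max(0, j - window // 2)
            hi = min(len(pts), j + 1 + window // 2 + 1)
            wpts = pts[lo:hi]
            centred = wpts - wpts.mean(axis=0)
            cov = centred.T @ centred
            w, v = np.linalg.eigh(cov)
            axis = v[:, -1]
            if w[-1] < 1e-24 or length < 1e-12:
                direction = seg / length if length > 0 else np.zeros(3)
            else:
                if float(np.dot(axis, seg)) < 0:
                    axis = -axis
                direction = axis
            cur = cur + direction * length
            new_pos[chain[j]] = cur.copy()

    for i, p in new_pos.items():
        out.xyz[out.index[i]] = p
    return out


# ---------------------------------------------------------------------------
# random variability

def randomize(m, method, amplitude, rng_seed=0):
    """Apply random variability; jitter/twist/rotate conserve cable length.

    methods
    -------
    jitter : perpendicular node displacements (amplitude in metres) with
        exact per-segment length restoration
    twist : random subtree rotations about the parent branch axis at every
        dendritic bifurcation (amplitude in radians)
    rotate : random subtree rotations about random axes at bifurcations
    scale3d : uniform scale by a factor in [1-amplitude, 1+amplitude]
    """
    rng = np.random.default_rng(rng_seed)
    if method == "scale3d":
        if not 0 <= amplitude < 1:
            raise ValidationError("scale3d amplitude must be in [0, 1)")
        f = 1.0 + rng.uniform(-amplitude, amplitude) if amplitude > 0 else 1.0
        out = m.copy()
        c = m.soma_center
        out.xyz = (out.xyz - c) * f + c
        return out

    if method in ("twist", "rotate"):
        out = m.copy()
        for i in m.ids:
            i = int(i)
            ch = out.children[i]
            if len(ch) < 2 or out._kind(i) == "soma" and i == out.root_id:
                continue
            if not any(out._kind(c) == "dendrite" for c in ch):
                continue
            prow = int(out.parents[out.index[i]])
            here = out.xyz[out.index[i]]
            if method == "twist":
                if prow == -1:
                    continue
                axis = here - out.xyz[out.index[prow]]
                if np.linalg.norm(axis) < 1e-12:
                    continue
            for c in ch:
                if out._kind(c) != "dendrite":
                    continue
                if method == "rotate":
                    axis = rng.normal(size=3)
                angle = rng.uniform(-amplitude, amplitude)
                _rotate_subtree(out, c, _axis_angle(axis, angle), here)
        return out

    if method == "jitter":
        out = m.copy()
        dist = m.path_distances()
        # displace every non-soma node perpendicular to its segment, then
        # rebuild positions root-outwards restoring each segment length
        order = sorted((int(i) for i in m.ids),
                       key=lambda i: dist[m.index[i]])
        disp = {}
        for i in order:
            row = m.index[i]
            p = int(m.parents[row])
            if p == -1 or m._kind(i) == "soma":
                disp[i] = m.xyz[row].copy()
                continue
            seg = m.xyz[row] - m.xyz[m.index[p]]
            n = np.linalg.norm(seg)
            r = rng.normal(size=3)
            if n > 1e-12:
                r -= seg * (np.dot(r, seg) / n ** 2)
            rn = np.linalg.norm(r)
            if rn > 1e-12:
                r = r / rn * rng.uniform(0, amplitude)
            disp[i] = m.xyz[row] + r
        newp = {}
        for i in order:
            row = m.index[i]
            p = int(m.parents[row])
            if p == -1:
                newp[i] = m.xyz[row].copy()
                continue
            if m._kind(i) == "soma":
                newp[i] = m.xyz[row].copy()
                continue
            l0 = np.linalg.norm(m.xyz[row] - m.xyz[m.index[p]])
            d = disp[i] - newp[p]
            dn = np.linalg.norm(d)
            newp[i] = newp[p] + (d / dn * l0 if dn > 1e-12 else
                                 m.xyz[row] - m.xyz[m.index[p]])
        for i, p in newp.items():
            out.xyz[out.index[i]] = p
        return out

    raise ValidationError(f"unknown randomize method {method!r}")
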