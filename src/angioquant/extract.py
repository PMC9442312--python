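"""Skeletonization and measured-graph extraction from vessel masks.

The binary mask is thinned to one-voxel-wide 26-connected centerlines
(topology-preserving 3D thinning), junction voxels (>= 3 skeleton
neighbours) are clustered into junction nodes, branches are the maximal
junction-free paths between nodes, and each branch is measured: arc
length from the centerline polyline, chord length end-to-end, mean
diameter from the Euclidean distance transform of the mask sampled
along the centerline.  Spur branches shorter than a prune length are
treated as thinning artifacts and removed, and junction pairs closer
than a merge length are contracted, after which degree-2 nodes are
dissolved.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .graphs import Branch, VesselGraph
from .stacks import VesselMask

log = logging.getLogger(__name__)

# 26-connectivity half-neighbourhood (13 offsets)
_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
)


def skeletonize_mask(mask: VesselMask) -> np.ndarray:
    """One-voxel-wide 26-connected centerlines of the mask.

    Assumes a (near-)isotropic grid; a strongly anisotropic mask is
    accepted with a warning since 3D thinning treats voxels as cubes.
    """
    vs = mask.voxel_size_um
    if max(vs) / min(vs) > 1.5:
        log.warning("skeletonizing an anisotropic grid %s um; resample first", vs)
    if not mask.data.any():
        return np.zeros(mask.data.shape, bool)
    return skeletonize(mask.data).astype(bool)


def _voxel_adjacency(coords: np.ndarray):
    """Pairs (i, j) of 26-adjacent skeleton voxels, given (n, 3) coords."""
    key = {tuple(c): i for i, c in enumerate(coords)}
    pairs = []
    for off in _OFFSETS:
        for i, c in enumerate(coords):
            j = key.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                pairs.append((i, j))
    return pairs


def _voxel_adjacency_fast(skel: np.ndarray):
    """Vectorized 26-adjacency over a boolean skeleton volume.

    Returns (coords, neighbour lists) with voxel ids 0..n-1 in
    lexicographic (z, y, x) order.
    """
    coords = np.argwhere(skel)
    n = len(coords)
    ids = -np.ones(skel.shape, dtype=np.int64)
    ids[tuple(coords.T)] = np.arange(n)
    nbrs: list[list[int]] = [[] for _ in range(n)]
    shape = np.array(skel.shape)
    for off in _OFFSETS:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < shape), axis=1)
        src = np.flatnonzero(ok)
        tgt = ids[tuple(shifted[ok].T)]
        hit = tgt >= 0
        for a, b in zip(src[hit], tgt[hit]):
            nbrs[a].append(int(b))
            nbrs[int(b)].append(int(a))
    return coords, nbrs


def extract_graph(
    skeleton: np.ndarray,
    voxel_size_um,
    prune_um: float = 5.0,
    merge_junction_um: float | None = None,
    mask: VesselMask | None = None,
) -> VesselGraph:
    """Build a :class:`VesselGraph` from a skeleton volume.

    Parameters
    ----------
    prune_um
        Degree-1 branches with arc length below this are removed as
        skeletonization spurs (genuine sprouts are longer).
    merge_junction_um
        Junction-junction branches shorter than this are contracted into
        a single junction (junction clusters split by a few voxels of
        thinning jitter).  Defaults to ``prune_um``.
    mask
        When given, centerline polylines are refined against the mask:
        the skeleton's meander inside each junction blob (within one
        local radius of the node) is replaced by a straight exit, which
        removes a systematic arc-length inflation of short branches.
    """
    if merge_junction_um is None:
        merge_junction_um = prune_um
    dx, dy, dz = voxel_size_um
    scale_xyz = np.array([dx, dy, dz])
    nz, ny, nx = skeleton.shape
    domain = (nx * dx, ny * dy, nz * dz)
    coords, nbrs = _voxel_adjacency_fast(skeleton)
    n = len(coords)
    graph = VesselGraph(domain_size_um=domain)
    if n == 0:
        return graph
    deg = np.array([len(set(b)) for b in nbrs])
    nbrs = [sorted(set(b)) for b in nbrs]

    def pos_um(i):
        z, y, x = coords[i]
        return np.array([x * dx, y * dy, z * dz])

    junction = deg >= 3
    # cluster adjacent junction voxels
    cluster_of = -np.ones(n, dtype=np.int64)
    n_clusters = 0
    for i in np.flatnonzero(junction):
        if cluster_of[i] >= 0:
            continue
        stack = [i]
        cluster_of[i] = n_clusters
        while stack:
            v = stack.pop()
            for u in nbrs[v]:
                if junction[u] and cluster_of[u] < 0:
                    cluster_of[u] = n_clusters
                    stack.append(u)
        n_clusters += 1

    # node ids: clusters first, then endpoints / isolated voxels
    node_pos: dict[int, np.ndarray] = {}
    for c in range(n_clusters):
        members = np.flatnonzero(cluster_of == c)
        node_pos[c] = np.mean([pos_um(i) for i in members], axis=0)
    node_of_voxel = {}
    next_node = n_clusters
    for i in np.flatnonzero(junction):
        node_of_voxel[i] = cluster_of[i]
    for i in np.flatnonzero(deg == 1):
        node_of_voxel[i] = next_node
        node_pos[next_node] = pos_um(i)
        next_node += 1
    for i in np.flatnonzero(deg == 0):
        log.debug("isolated skeleton voxel at %s ignored", coords[i])

    graph.nodes = node_pos

    # trace branches
    visited_chain = np.zeros(n, dtype=bool)
    seen_direct = set()
    branches: list[Branch] = []
    bid = 0

    def add_branch(na, nb, poly):
        nonlocal bid
        branches.append(Branch(id=bid, node_a=na, node_b=nb, points=np.asarray(poly)))
        bid += 1

    node_voxels = sorted(node_of_voxel)
    for v in node_voxels:
        for u in nbrs[v]:
            if u in node_of_voxel:
                ca, cb = node_of_voxel[v], node_of_voxel[u]
                if ca == cb:
                    continue  # intra-cluster adjacency
                key = (min(v, u), max(v, u))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                add_branch(ca, cb, [node_pos[ca], pos_um(v), pos_um(u), node_pos[cb]])
                continue
            if visited_chain[u]:
                continue
            # walk the degree-2 chain
            chain = [v, u]
            visited_chain[u] = True
            prev, cur = v, u
            while cur not in node_of_voxel:
                nxt = [w for w in nbrs[cur] if w != prev]
                if not nxt:
                    break  # chain dead-ends at a degree-1... already node; safety
                # prefer unvisited continuation; at most one in a clean chain
                nxt = nxt[0] if len(nxt) == 1 else next(
                    (w for w in nxt if not visited_chain[w] or w in node_of_voxel), nxt[0]
                )
                prev, cur = cur, nxt
                chain.append(cur)
                if cur not in node_of_voxel:
                    if visited_chain[cur]:
                        break
                    visited_chain[cur] = True
            if chain[-1] in node_of_voxel:
                na, nb = node_of_voxel[chain[0]], node_of_voxel[chain[-1]]
                poly = [node_pos[na]] + [pos_um(i) for i in chain] + [node_pos[nb]]
                add_branch(na, nb, poly)

    # pure cycles: deg-2 voxels never visited
    for i in range(n):
        if deg[i] == 2 and not visited_chain[i] and i not in node_of_voxel:
            loop = [i]
            visited_chain[i] = True
            prev, cur = i, nbrs[i][0]
            while cur != i:
                loop.append(cur)
                visited_chain[cur] = True
                nxt = [w for w in nbrs[cur] if w != prev]
                prev, cur = cur, nxt[0]
            anchor = next_node
            node_pos[anchor] = pos_um(i)
            graph.nodes[anchor] = node_pos[anchor]
            next_node += 1
            poly = [pos_um(j) for j in loop] + [pos_um(i)]
            add_branch(anchor, anchor, poly)

    graph.branches = branches
    graph._drop_orphans()

    if mask is not None:
        _trim_junction_blobs(graph, mask, n_clusters)
    _smooth_polylines(graph)
    _clean_graph(graph, prune_um, merge_junction_um)
    if mask is not None:
        _extend_endpoints(graph, mask)
    return graph


def _extend_endpoints(graph: VesselGraph, mask: VesselMask) -> None:
    """Compensate thinning end-erosion: march each degree-1 endpoint
    along its final direction until the centerline exits the mask."""
    dx, dy, dz = mask.voxel_size_um
    shape = np.array(mask.data.shape)
    step = 0.5 * min(mask.voxel_size_um)

    def inside(p) -> bool:
        idx = np.round(p[::-1] / np.array([dz, dy, dx])).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        return bool(mask.data[idx[0], idx[1], idx[2]])

    deg = graph.degrees()
    for b in graph.branches:
        for node_id, at_start in ((b.node_a, True), (b.node_b, False)):
            if deg.get(node_id, 0) != 1:
                continue
            pts = b.points if not at_start else b.points[::-1]
            if len(pts) < 3:
                continue
            tail = pts[-1] - pts[max(0, len(pts) - 6)]
            norm = np.linalg.norm(tail)
            if norm == 0:
                continue
            u = tail / norm
            p = pts[-1].copy()
            added = []
            # erosion is at most a couple of tube radii
            max_march = 3.0 * max(b.mean_diameter_um, 4.0) if np.isfinite(b.mean_diameter_um) else 30.0
            travelled = 0.0
            while travelled < max_march:
                q = p + step * u
                if not inside(q):
                    break
                added.append(q)
                p = q
                travelled += step
            if added:
                ext = np.asarray(added)
                new_pts = np.vstack([pts, ext])
                b.points = new_pts[::-1] if at_start else new_pts
                graph.nodes[node_id] = b.points[0] if at_start else b.points[-1]


def _trim_junction_blobs(graph: VesselGraph, mask: VesselMask, n_clusters: int) -> None:
    """Replace each polyline's meander inside a junction blob by a
    straight exit from the node position."""
    dx, dy, dz = mask.voxel_size_um
    edt = ndimage.distance_transform_edt(mask.data, sampling=(dz, dy, dx))
    shape = np.array(mask.data.shape)

    def radius_at(p):
        idx = np.clip(np.round(p[::-1] / np.array([dz, dy, dx])).astype(int), 0, shape - 1)
        return float(edt[idx[0], idx[1], idx[2]])

    for b in graph.branches:
        if len(b.points) < 3:
            continue
        pts = b.points
        for node_id, from_start in ((b.node_a, True), (b.node_b, False)):
            if node_id >= n_clusters:
                continue  # free end, not a junction blob
            p0 = graph.nodes[node_id]
            r = radius_at(p0)
            if r <= 0:
                continue
            q = pts if from_start else pts[::-1]
            dist = np.linalg.norm(q - p0, axis=1)
            # first index beyond the blob; keep the node point itself
            outside = np.flatnonzero(dist > r)
            if len(outside) == 0 or outside[0] <= 1:
                continue
            k = int(outside[0])
            if len(q) - k < 2:
                continue
            q = np.vstack([p0, q[k:]])
            pts = q if from_start else q[::-1]
        b.points = pts


def _smooth_polylines(graph: VesselGraph, iterations: int = 2) -> None:
    """Damp the voxel staircase of traced centerlines (endpoints fixed)."""
    for b in graph.branches:
        pts = b.points
        if len(pts) < 4:
            continue
        for _ in range(iterations):
            pts = pts.copy()
            pts[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
        b.points = pts


def _clean_graph(graph: VesselGraph, prune_um: float, merge_um: float) -> None:
    for _ in range(200):
        changed = False
        # prune short spurs at degree-1 ends
        deg = graph.degrees()
        spurs = {
            b.id
            for b in graph.branches
            if b.arc_length_um < prune_um
            and (deg[b.node_a] == 1 or deg[b.node_b] == 1)
            and not (deg[b.node_a] == 1 and deg[b.node_b] == 1)  # keep isolated segments
        }
        if spurs:
            graph.branches = [b for b in graph.branches if b.id not in spurs]
            graph._drop_orphans()
            graph.dissolve_degree2()
            changed = True
        # tiny self-loops are thinning artifacts at thick junction blobs
        # (a genuine loop must run at least two branch lengths)
        loops = {
            b.id
            for b in graph.branches
            if b.node_a == b.node_b and b.arc_length_um < 2.0 * merge_um
        }
        if loops:
            graph.branches = [b for b in graph.branches if b.id not in loops]
            graph._drop_orphans()
            graph.dissolve_degree2()
            changed = True
        # contract short junction-junction branches
        deg = graph.degrees()
        for b in list(graph.branches):
            if (
                b.node_a != b.node_b
                and b.arc_length_um < merge_um
                and deg.get(b.node_a, 0) >= 3
                and deg.get(b.node_b, 0) >= 3
            ):
                graph.branches = [x for x in graph.branches if x.id != b.id]
                graph.merge_nodes(b.node_a, b.node_b)
                # re-anchor merged branch endpoints onto the new node position
                graph.dissolve_degree2()
                changed = True
                break
        if not changed:
            break


def estimate_diameters(graph: VesselGraph, mask: VesselMask) -> VesselGraph:
    """Per-branch arc-length-weighted mean diameter from the Euclidean
    distance transform of the mask.

    The diameter at a centerline point is twice the EDT value at the
    nearest voxel; points falling outside the mask (numerical jitter at
    junction centroids) take the nearest positive value along the same
    branch and are logged.
    """
    dx, dy, dz = mask.voxel_size_um
    edt = ndimage.distance_transform_edt(mask.data, sampling=(dz, dy, dx))
    shape = np.array(mask.data.shape)
    for b in graph.branches:
        pts = b.points
        idx = np.round(pts[:, ::-1] / np.array([dz, dy, dx])).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        d = 2.0 * edt[idx[:, 0], idx[:, 1], idx[:, 2]]
        if np.all(d == 0):
            log.debug("branch %d entirely outside mask; diameter = voxel size", b.id)
            b.mean_diameter_um = float(min(mask.voxel_size_um))
            continue
        if np.any(d == 0):
            good = d > 0
            d = np.interp(np.arange(len(d)), np.flatnonzero(good), d[good])
            log.debug("branch %d: %d centerline points outside mask", b.id, int((~good).sum()))
        if len(pts) < 2:
            b.mean_diameter_um = float(d[0])
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        w = np.zeros(len(pts))
        w[:-1] += seg / 2
        w[1:] += seg / 2
        # the EDT near a junction measures the junction blob, not the
        # vessel: drop points within one local radius of each end when
        # enough of the branch remains
        s_arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = s_arc[-1]
        r_a, r_b = d[0] / 2.0, d[-1] / 2.0
        if total > 3.0 * (r_a + r_b):
            keep = (s_arc >= r_a) & (s_arc <= total - r_b)
            if keep.sum() >= 2:
                d, w = d[keep], w[keep]
        if w.sum() == 0:
            b.mean_diameter_um = float(d.mean())
        else:
            b.mean_diameter_um = float(np.average(d, weights=w))
    return graph


def flag_sprouts(
    graph: VesselGraph,
    stack_bounds_um: tuple[float, float, float] | None = None,
    boundary_margin_um: float = 10.0,
) -> VesselGraph:
    """Mark branches with a blind end: a degree-1 end farther than the
    margin from every face of the stack."""
    if stack_bounds_um is None:
        stack_bounds_um = graph.domain_size_um
    if stack_bounds_um is None:
        raise ValueError("stack bounds unknown")
    lx, ly, lz = stack_bounds_um
    deg = graph.degrees()

    def interior(p):
        return (
            boundary_margin_um < p[0] < lx - boundary_margin_um
            and boundary_margin_um < p[1] < ly - boundary_margin_um
            and boundary_margin_um < p[2] < lz - boundary_margin_um
        )

    for b in graph.branches:
        b.sprout = any(
            deg[n] == 1 and interior(graph.nodes[n]) for n in (b.node_a, b.node_b)
        )
    return graph


def classify_branch_perfusion(
    graph: VesselGraph,
    perfusion: VesselMask,
    coverage_threshold: float = 0.5,
) -> VesselGraph:
    """A branch is perfused iff at least ``coverage_threshold`` of its
    centerline points fall inside the perfusion mask."""
    dx, dy, dz = perfusion.voxel_size_um
    shape = np.array(perfusion.data.shape)
    for b in graph.branches:
        idx = np.round(b.points[:, ::-1] / np.array([dz, dy, dx])).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        inside = perfusion.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        b.perfused = bool(inside.mean() >= coverage_threshold)
    return graph
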