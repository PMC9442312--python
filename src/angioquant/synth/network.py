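"""Procedural ground-truth vascular networks.

The generator grows a spatial graph on Poisson-placed junction points:
each junction connects to its nearest neighbours until it reaches degree
three, candidate tubes that would overlap an existing tube are rejected,
and terminal branches are then grown outward — either to the domain
boundary or ending blind inside the tissue (sprouts).  Centerlines are
given a sinusoidal perpendicular perturbation so branch tortuosity is
controllable and analytically known from the polyline itself.

Perfusion is assigned per branch by a logistic rule in diameter,
emulating the observation that small-calibre tumour vessels are the ones
most likely to carry no flow: P(non-perfused | d) = 1 / (1 + exp((d -
d0) / s)) with d0 = 25 um by default.  ``s = 0`` disables the rule (all
branches perfused).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..graphs import Branch, VesselGraph

log = logging.getLogger(__name__)


class InfeasibleDensityError(ValueError):
    """Requested junction density cannot be realized without overlap."""


@dataclass
class NetworkSpec:
    """Parameters of a procedural vascular network.

    Defaults describe a moderately dense tumour vascular bed imaged in a
    thin slab: ~150 junctions per mm^2 of projected area, branch lengths
    of order 100 um and vessel diameters of order 30 um.
    """

    domain_size_um: tuple[float, float, float] = (1000.0, 1000.0, 150.0)
    target_node_density_per_mm2: float = 150.0
    #: lognormal (mu, sigma) of branch length in um (log-scale parameters)
    branch_length_dist: tuple[float, float] = (math.log(120.0), 0.5)
    #: lognormal (mu, sigma) of branch mean diameter in um
    diameter_dist: tuple[float, float] = (math.log(30.0), 0.40)
    #: sinusoidal centerline perturbation amplitude as a fraction of chord
    tortuosity_amplitude: float = 0.05
    #: fraction of all branches that terminate blind inside the domain
    sprout_fraction: float = 0.2
    #: um scale of the logistic non-perfusion rule; 0 disables the rule
    nonperfused_diameter_scale_um: float = 5.0
    #: logistic midpoint: diameter at which P(non-perfused) = 0.5
    nonperfused_diameter_threshold_um: float = 25.0
    #: fraction of junction-junction branch count grown as terminal branches
    terminal_branch_fraction: float = 0.4
    #: minimum x-y junction separation; None -> derived from density
    min_junction_separation_um: float | None = None
    #: diameter clip range, um
    diameter_range_um: tuple[float, float] = (4.0, 45.0)
    #: sprout diameters are immature: scale factor on the diameter draw
    sprout_diameter_scale: float = 0.65
    #: clip range for blind (sprout) branch lengths, um
    sprout_length_range_um: tuple[float, float] = (25.0, 90.0)
    #: extra clearance between non-adjacent tube surfaces, um
    clearance_margin_um: float = 6.0
    #: minimum angle between branches leaving the same junction, degrees
    min_branch_angle_deg: float = 30.0
    #: let repair rounds progressively relax the clearance margin; keep
    #: False when the network must render with exactly matching topology
    repair_relax: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not np.isfinite(v) or v <= 0 for v in self.domain_size_um):
            raise ValueError("domain extents must be positive and finite")
        if self.target_node_density_per_mm2 <= 0:
            raise ValueError("target_node_density must be positive")
        for name in ("branch_length_dist", "diameter_dist"):
            mu, sigma = getattr(self, name)
            if not (np.isfinite(mu) and np.isfinite(sigma) and sigma >= 0):
                raise ValueError(f"{name} parameters must be finite, sigma >= 0")
        if not 0.0 <= self.sprout_fraction <= 1.0:
            raise ValueError("sprout_fraction must be in [0, 1]")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")
        if self.nonperfused_diameter_scale_um < 0:
            raise ValueError("nonperfused_diameter_scale_um must be >= 0")

    @property
    def projected_area_mm2(self) -> float:
        return self.domain_size_um[0] * self.domain_size_um[1] / 1e6

    def p_nonperfused(self, diameter_um: np.ndarray | float) -> np.ndarray | float:
        """Logistic probability of a branch being non-perfused given diameter."""
        s = self.nonperfused_diameter_scale_um
        if s == 0:  # rule disabled: everything perfused
            return np.zeros_like(np.asarray(diameter_um, float))
        d0 = self.nonperfused_diameter_threshold_um
        return 1.0 / (1.0 + np.exp((np.asarray(diameter_um, float) - d0) / s))


def mc38_like(seed: int = 0, **overrides) -> NetworkSpec:
    """Spec emulating a highly vascular colon-carcinoma (MC38-like) bed:
    dense branching, many small-calibre vessels, >40% of branches
    non-perfused."""
    params = dict(
        domain_size_um=(1000.0, 1000.0, 150.0),
        target_node_density_per_mm2=220.0,
        branch_length_dist=(math.log(90.0), 0.5),
        diameter_dist=(math.log(28.0), 0.50),
        sprout_fraction=0.25,
        seed=seed,
    )
    params.update(overrides)
    return NetworkSpec(**params)


def b16f10_like(seed: int = 0, **overrides) -> NetworkSpec:
    """Spec emulating a moderately vascular melanoma (B16F10-like) bed:
    sparser branching, larger vessels, ~30% non-perfused."""
    params = dict(
        domain_size_um=(1000.0, 1000.0, 150.0),
        target_node_density_per_mm2=110.0,
        branch_length_dist=(math.log(140.0), 0.45),
        diameter_dist=(math.log(33.0), 0.30),
        sprout_fraction=0.12,
        seed=seed,
    )
    params.update(overrides)
    return NetworkSpec(**params)


# ---------------------------------------------------------------------------


def _place_junctions(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson-count junctions with a minimum x-y separation (hard-core)."""
    lx, ly, lz = spec.domain_size_um
    lam = spec.target_node_density_per_mm2 * spec.projected_area_mm2
    n = int(rng.poisson(lam))
    if n == 0:
        return np.empty((0, 3))
    if spec.min_junction_separation_um is not None:
        sep = spec.min_junction_separation_um
    else:
        # half the mean nearest-neighbour distance of a Poisson process
        lam_um2 = spec.target_node_density_per_mm2 / 1e6
        sep = 0.25 / math.sqrt(lam_um2)
    margin_xy = min(0.05 * min(lx, ly), 25.0)
    margin_z = float(np.clip(0.25 * lz, 10.0, 40.0))
    if 2 * margin_z >= lz:
        margin_z = 0.25 * lz
    pts: list[np.ndarray] = []
    max_tries = 400
    for _ in range(n):
        for attempt in range(max_tries):
            p = np.array(
                [
                    rng.uniform(margin_xy, lx - margin_xy),
                    rng.uniform(margin_xy, ly - margin_xy),
                    rng.uniform(margin_z, lz - margin_z),
                ]
            )
            if not pts:
                break
            d = np.linalg.norm(np.asarray(pts)[:, :2] - p[:2], axis=1)
            if d.min() >= sep:
                break
        else:
            raise InfeasibleDensityError(
                f"could not place {n} junctions at separation {sep:.1f} um "
                f"in a {lx:.0f} x {ly:.0f} um domain"
            )
        pts.append(p)
    return np.asarray(pts)


def _sinusoidal_polyline(
    pa: np.ndarray,
    pb: np.ndarray,
    amplitude_frac: float,
    n_periods: int,
    perp_seedvec: np.ndarray,
    n_points: int | None = None,
) -> np.ndarray:
    """Polyline from pa to pb displaced by a*chord*sin(k*pi*t) along a
    perpendicular direction; displacement vanishes at both ends so the
    chord is exact and the arc length follows from the polyline."""
    chord_vec = pb - pa
    chord = np.linalg.norm(chord_vec)
    if chord == 0:
        return np.vstack([pa, pb])
    u = chord_vec / chord
    v = perp_seedvec - np.dot(perp_seedvec, u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        v = np.array([u[1], -u[0], 0.0])
        nv = np.linalg.norm(v)
        if nv < 1e-9:
            v = np.array([1.0, 0.0, 0.0])
            nv = 1.0
    v = v / nv
    if n_points is None:
        n_points = max(16, int(math.ceil(chord / 3.0)) + 1)
    t = np.linspace(0.0, 1.0, n_points)
    base = pa[None, :] + t[:, None] * chord_vec[None, :]
    disp = amplitude_frac * chord * np.sin(n_periods * math.pi * t)
    return base + disp[:, None] * v[None, :]


class _ClearanceIndex:
    """Accepted tube samples for overlap rejection.

    Two rules keep the rendered union's topology equal to the graph's:
    non-adjacent tubes must keep their surfaces ``margin`` apart, and
    tubes leaving the same junction must diverge by at least
    ``min_angle`` so they only touch inside the junction blob.
    """

    def __init__(self, min_angle_deg: float = 30.0) -> None:
        self.samples: list[np.ndarray] = []  # (n,3) per branch
        self.radii: list[float] = []
        self.node_pairs: list[tuple[int, int]] = []
        self.node_pos: dict[int, np.ndarray] = {}
        self.out_dirs: dict[int, list[np.ndarray]] = {}
        self.cos_max = math.cos(math.radians(min_angle_deg))
        self._tree = None
        self._all = None
        self._all_radius = None
        self._all_branch = None
        self._built_n = 0

    @staticmethod
    def _dir_at(pts: np.ndarray, node_pos: np.ndarray) -> np.ndarray:
        start_first = np.linalg.norm(pts[0] - node_pos) <= np.linalg.norm(pts[-1] - node_pos)
        v = (pts[-1] - pts[0]) if start_first else (pts[0] - pts[-1])
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def _rebuild(self):
        self._built_n = len(self.samples)
        if self._built_n:
            self._all = np.vstack(self.samples)
            self._all_radius = np.concatenate(
                [np.full(len(s), r) for s, r in zip(self.samples, self.radii)]
            )
            self._all_branch = np.concatenate(
                [np.full(len(s), i, dtype=int) for i, s in enumerate(self.samples)]
            )
            self._tree = cKDTree(self._all)
        else:
            self._tree = None

    def _violates(self, pts, s, branch_idx, node_set, req) -> bool:
        """True if any (candidate, existing) sample pair of this branch
        is closer than ``req`` outside the shared-junction funnel."""
        d = np.linalg.norm(pts[:, None, :] - s[None, :, :], axis=2)
        viol = d < req
        if not viol.any():
            return False
        shared = node_set & set(self.node_pairs[branch_idx])
        excl = 1.2 * req
        for sn in shared:
            # proximity is allowed only in the immediate junction funnel
            p0 = self.node_pos[sn]
            near_new = np.linalg.norm(pts - p0, axis=1) < excl
            near_old = np.linalg.norm(s - p0, axis=1) < excl
            viol &= ~np.outer(near_new, near_old)
        return bool(viol.any())

    @staticmethod
    def _coarsen(pts: np.ndarray) -> np.ndarray:
        """Clearance tests run on every other centerline sample (~6 um
        spacing); the clearance margin absorbs the sampling error."""
        if len(pts) <= 3:
            return pts
        out = pts[::2]
        if not np.array_equal(out[-1], pts[-1]):
            out = np.vstack([out, pts[-1]])
        return out

    def ok(
        self,
        pts: np.ndarray,
        radius: float,
        nodes: tuple[int, int],
        margin: float,
    ) -> bool:
        pts = self._coarsen(pts)
        # angular gate at shared junctions
        for n_id in set(nodes):
            if n_id in self.out_dirs and n_id in self.node_pos:
                d_new = self._dir_at(pts, self.node_pos[n_id])
                for d_old in self.out_dirs[n_id]:
                    if float(np.dot(d_new, d_old)) > self.cos_max:
                        return False
        if not self.samples:
            return True
        node_set = set(nodes)
        # branches added since the last tree rebuild: brute force
        for bi in range(self._built_n, len(self.samples)):
            req = radius + self.radii[bi] + margin
            if self._violates(pts, self.samples[bi], bi, node_set, req):
                return False
        if self._tree is not None:
            rmax = float(self._all_radius.max())
            hits = self._tree.query_ball_point(pts, radius + rmax + margin)
            flat = sorted({j for h in hits for j in h})
            if flat:
                cand_branches = sorted({int(self._all_branch[j]) for j in flat})
                for bi in cand_branches:
                    req = radius + self.radii[bi] + margin
                    if self._violates(pts, self.samples[bi], bi, node_set, req):
                        return False
        return True

    def rebuild_from(self, branches) -> None:
        """Re-sync with the live branch list after a cleanup removed
        branches, so their tubes stop blocking new placements."""
        self.samples = []
        self.radii = []
        self.node_pairs = []
        self.out_dirs = {}
        self._tree = None
        self._built_n = 0
        for b in branches:
            self.add(b.points, b.mean_diameter_um / 2.0, (b.node_a, b.node_b))

    def add(self, pts: np.ndarray, radius: float, nodes: tuple[int, int]) -> None:
        self.samples.append(self._coarsen(pts))
        self.radii.append(radius)
        self.node_pairs.append(nodes)
        # rebuild the tree only once enough new branches accumulated
        if len(self.samples) - self._built_n > 40:
            self._rebuild()
        for n_id in set(nodes):
            if n_id in self.node_pos:
                self.out_dirs.setdefault(n_id, []).append(self._dir_at(pts, self.node_pos[n_id]))


def generate_network(spec: NetworkSpec) -> VesselGraph:
    """Generate a ground-truth vascular graph from a :class:`NetworkSpec`.

    Every branch carries its centerline polyline (hence arc and chord
    length), a mean diameter, and perfused / sprout flags.  Raises
    :class:`InfeasibleDensityError` when the requested junction density
    cannot be placed without tube overlap.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.domain_size_um
    pts = _place_junctions(spec, rng)
    graph = VesselGraph(domain_size_um=spec.domain_size_um)
    for i, p in enumerate(pts):
        graph.nodes[i] = p
    index = _ClearanceIndex(spec.min_branch_angle_deg)
    index.node_pos = dict(graph.nodes)

    mu_d, sig_d = spec.diameter_dist
    dlo, dhi = spec.diameter_range_um

    def draw_diameter(scale: float = 1.0) -> float:
        return float(np.clip(scale * rng.lognormal(mu_d, sig_d), dlo, dhi))

    next_branch = 0
    edges: set[tuple[int, int]] = set()

    def add_branch(a: int, b: int, pts_ab: np.ndarray, diam: float, sprout: bool) -> None:
        nonlocal next_branch
        graph.branches.append(
            Branch(id=next_branch, node_a=a, node_b=b, points=pts_ab,
                   mean_diameter_um=diam, sprout=sprout)
        )
        index.add(pts_ab, diam / 2.0, (a, b))
        next_branch += 1

    # -- junction-to-junction skeleton ------------------------------------
    n_target = len(pts)
    pts_list = [np.asarray(p) for p in pts]
    mu_l, sig_l = spec.branch_length_dist
    lmax = math.exp(mu_l + 2.5 * sig_l)
    deg: dict[int, int] = {i: 0 for i in range(n_target)}

    def try_edge(i: int, j: int, length_cap: float, margin: float | None = None) -> bool:
        key = (min(i, j), max(i, j))
        if key in edges:
            return False
        if margin is None:
            margin = spec.clearance_margin_um
        chord = np.linalg.norm(pts_list[j] - pts_list[i])
        if chord > length_cap:
            return False
        diam = draw_diameter()
        # a rejected tube may pass with a different lateral phase
        for _ in range(2):
            poly = _sinusoidal_polyline(
                pts_list[i], pts_list[j], spec.tortuosity_amplitude,
                int(rng.integers(1, 4)), rng.normal(size=3),
            )
            np.clip(poly, [0, 0, 0], [lx, ly, lz], out=poly)
            if index.ok(poly, diam / 2.0, key, margin):
                edges.add(key)
                deg[i] = deg.get(i, 0) + 1
                deg[j] = deg.get(j, 0) + 1
                # an endpoint may have been dropped by an earlier cleanup
                graph.nodes.setdefault(key[0], pts_list[key[0]])
                graph.nodes.setdefault(key[1], pts_list[key[1]])
                add_branch(key[0], key[1], poly, diam, sprout=False)
                return True
        return False

    def connect_batch(indices, margin: float | None = None) -> None:
        if len(pts_list) < 2:
            return
        arr = np.asarray(pts_list)
        tree = cKDTree(arr)
        k1 = min(16, len(pts_list))
        k2 = min(20, len(pts_list))
        _, nn1 = tree.query(arr[indices], k=k1)
        for row, i in enumerate(indices):
            for j in np.atleast_1d(nn1[row])[1:]:
                if deg.get(i, 0) >= 3:
                    break
                try_edge(i, int(j), lmax, margin)
        _, nn2 = tree.query(arr[indices], k=k2)
        for row, i in enumerate(indices):
            for j in np.atleast_1d(nn2[row])[1:]:
                if deg.get(i, 0) >= 3:
                    break
                try_edge(i, int(j), 1.6 * lmax, margin)

    if n_target >= 2:
        connect_batch(list(range(n_target)))
        if _remove_accidental_stubs(graph):
            index.rebuild_from(graph.branches)
        # repair: clearance rejections can leave nodes below junction
        # grade; re-sample replacement sites so the realized junction
        # count keeps its Poisson draw
        sep = (
            spec.min_junction_separation_um
            if spec.min_junction_separation_um is not None
            else 0.25 / math.sqrt(spec.target_node_density_per_mm2 / 1e6)
        )
        margin_xy = min(0.05 * min(lx, ly), 25.0)
        margin_z = float(np.clip(0.25 * lz, 10.0, 40.0))
        if 2 * margin_z >= lz:
            margin_z = 0.25 * lz
        for round_k in range(20):
            deg = graph.degrees()
            n_now = sum(1 for d in deg.values() if d >= 3)
            deficit = n_target - n_now
            if deficit <= 0:
                break
            new_ids = []
            existing_xy = np.asarray(pts_list)[:, :2]
            for _ in range(deficit):
                for _try in range(60):
                    p = np.array([
                        rng.uniform(margin_xy, lx - margin_xy),
                        rng.uniform(margin_xy, ly - margin_xy),
                        rng.uniform(margin_z, lz - margin_z),
                    ])
                    sep_k = sep * (0.7 if (spec.repair_relax and round_k >= 4) else 1.0)
                    if len(existing_xy) == 0 or np.linalg.norm(
                        existing_xy - p[:2], axis=1
                    ).min() >= sep_k:
                        break
                else:
                    continue
                nid = len(pts_list)
                pts_list.append(p)
                existing_xy = np.vstack([existing_xy, p[:2]])
                graph.nodes[nid] = p
                index.node_pos[nid] = p
                new_ids.append(nid)
            if not new_ids:
                break
            margin_k = spec.clearance_margin_um
            if spec.repair_relax:
                margin_k = max(0.5, spec.clearance_margin_um * (1.0 - 0.15 * round_k))
                # crowded pockets also need a laxer divergence-angle gate
                index.cos_max = math.cos(
                    math.radians(max(8.0, spec.min_branch_angle_deg * (1.0 - 0.12 * round_k)))
                )
            connect_batch(new_ids, margin_k)
            if _remove_accidental_stubs(graph):
                index.rebuild_from(graph.branches)

        index.cos_max = math.cos(math.radians(spec.min_branch_angle_deg))
        # join stray components where clearance allows
        _connect_components(graph, spec, rng, index, edges, add_branch, draw_diameter)

    # drop interior blind stubs left by clearance rejection (only designated
    # sprouts may terminate blind)
    _remove_accidental_stubs(graph)

    n_jj = len(graph.branches)

    # -- terminal branches: boundary-terminating and sprouts ---------------
    if n_jj > 0:
        n_term = int(round(spec.terminal_branch_fraction * n_jj))
        sf = spec.sprout_fraction
        if sf > 0:
            # E[sprouts] = sf * (n_jj + n_term); solve for blind probability q
            need = math.ceil(sf * n_jj / max(1e-9, (0.95 - sf)))
            n_term = max(n_term, need)
        q = sf * (n_jj + n_term) / n_term if n_term else 0.0
        q = min(q, 1.0)
        _grow_terminals(graph, spec, rng, index, n_term, q, add_branch, draw_diameter)

    graph._drop_orphans()
    graph.dissolve_degree2()
    _remove_self_overlapping(graph)

    # -- perfusion flags ---------------------------------------------------
    for b in graph.branches:
        p_np = float(spec.p_nonperfused(b.mean_diameter_um))
        b.perfused = bool(rng.random() >= p_np)

    return graph


def _connect_components(graph, spec, rng, index, edges, add_branch, draw_diameter):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for b in graph.branches:
        g.add_edge(b.node_a, b.node_b)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) <= 1:
        return
    main = set(comps[0])
    lx, ly, lz = spec.domain_size_um
    for comp in comps[1:]:
        pairs = []
        for a in comp:
            for m in main:
                pairs.append((np.linalg.norm(graph.nodes[a] - graph.nodes[m]), a, m))
        pairs.sort()
        for _, a, m in pairs[:12]:
            key = (min(a, m), max(a, m))
            if key in edges:
                continue
            diam = draw_diameter()
            poly = _sinusoidal_polyline(
                graph.nodes[a], graph.nodes[m], spec.tortuosity_amplitude,
                int(rng.integers(1, 4)), rng.normal(size=3),
            )
            np.clip(poly, [0, 0, 0], [lx, ly, lz], out=poly)
            if index.ok(poly, diam / 2.0, key, spec.clearance_margin_um):
                edges.add(key)
                add_branch(key[0], key[1], poly, diam, sprout=False)
                break
        main |= set(comp)


def _remove_self_overlapping(graph: VesselGraph, margin_um: float = 4.0) -> None:
    """Remove branches whose centerline re-approaches itself within one
    tube diameter: their rendered tube would fuse with itself, so the
    polyline is not a valid ground-truth centerline."""
    while True:
        victim = None
        for b in graph.branches:
            pts = b.points
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            if s[-1] == 0:
                continue
            d_tube = b.mean_diameter_um if np.isfinite(b.mean_diameter_um) else 10.0
            window = 3.0 * d_tube
            dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
            smat = np.abs(s[:, None] - s[None, :])
            close = (smat > window) & (dmat < d_tube + margin_um)
            if close.any():
                victim = b
                break
        if victim is None:
            return
        graph.branches = [x for x in graph.branches if x.id != victim.id]
        graph._drop_orphans()
        _remove_accidental_stubs(graph)
        graph.dissolve_degree2()


def _remove_accidental_stubs(graph: VesselGraph, margin_um: float = 5.0) -> bool:
    """Delete branches ending blind in the domain interior that are not
    designated sprouts (boundary-terminating ends are legitimate).
    Returns True when any branch was removed."""
    if graph.domain_size_um is not None:
        lx, ly, lz = graph.domain_size_um

        def interior(p) -> bool:
            return (
                margin_um < p[0] < lx - margin_um
                and margin_um < p[1] < ly - margin_um
                and margin_um < p[2] < lz - margin_um
            )
    else:
        def interior(p) -> bool:
            return True

    removed_any = False
    changed = True
    while changed:
        changed = False
        deg = graph.degrees()
        stub_nodes = {
            n for n, d in deg.items() if d == 1 and interior(graph.nodes[n])
        }
        if not stub_nodes:
            break
        keep = []
        for b in graph.branches:
            if (b.node_a in stub_nodes or b.node_b in stub_nodes) and not b.sprout:
                changed = True
            else:
                keep.append(b)
        if changed:
            removed_any = True
            graph.branches = keep
            graph._drop_orphans()
    return removed_any

def _grow_terminals(graph, spec, rng, index, n_term, q, add_branch, draw_diameter):
    lx, ly, lz = spec.domain_size_um
    deg = graph.degrees()
    junctions = [n for n, d in deg.items() if d >= 3]
    if not junctions:
        return
    mu_l, sig_l = spec.branch_length_dist
    next_node = max(graph.nodes) + 1
    # blind endpoints must sit well inside the domain so sprout flagging by
    # boundary distance is unambiguous even after skeleton end-erosion
    safe = 30.0
    safe_z = min(25.0, 0.2 * lz)
    order = rng.permutation(junctions)
    # decide each terminal's type up front so placement failures cannot
    # bias the realized sprout share
    blind_flags = rng.random(n_term) < q
    placed = 0
    oi = 0
    attempts = 0
    while placed < n_term and attempts < 20 * n_term:
        attempts += 1
        host = int(order[oi % len(order)])
        oi += 1
        p0 = graph.nodes[host]
        blind = bool(blind_flags[placed])
        ok = False
        for _ in range(8):
            if blind:
                length = float(np.clip(0.5 * rng.lognormal(mu_l, sig_l), *spec.sprout_length_range_um))
                direction = rng.normal(size=3) * np.array([1.0, 1.0, 0.25])
                direction /= np.linalg.norm(direction)
                p1 = p0 + length * direction
                if not (
                    safe < p1[0] < lx - safe
                    and safe < p1[1] < ly - safe
                    and safe_z < p1[2] < lz - safe_z
                ):
                    continue
            else:
                # run to the nearest x-y face at least one sprout-length
                # away (very short terminals are indistinguishable from
                # thinning spurs), jittered tangentially
                min_run = spec.sprout_length_range_um[0]
                dists = [p0[0], lx - p0[0], p0[1], ly - p0[1]]
                usable = [d if d >= min_run else np.inf for d in dists]
                if not np.isfinite(min(usable)):
                    continue
                face = int(np.argmin(usable))
                p1 = p0.copy()
                if face == 0:
                    p1[0] = 0.0
                elif face == 1:
                    p1[0] = lx
                elif face == 2:
                    p1[1] = 0.0
                else:
                    p1[1] = ly
                tang = rng.uniform(-0.4, 0.4) * dists[face]
                if face in (0, 1):
                    p1[1] = np.clip(p1[1] + tang, 5.0, ly - 5.0)
                else:
                    p1[0] = np.clip(p1[0] + tang, 5.0, lx - 5.0)
                p1[2] = np.clip(p1[2] + rng.uniform(-10, 10), 5.0, lz - 5.0)
            diam = draw_diameter(spec.sprout_diameter_scale if blind else 1.0)
            poly = _sinusoidal_polyline(
                p0, p1, spec.tortuosity_amplitude, int(rng.integers(1, 3)),
                rng.normal(size=3),
            )
            np.clip(poly, [0, 0, 0], [lx, ly, lz], out=poly)
            if index.ok(poly, diam / 2.0, (host, next_node), spec.clearance_margin_um):
                ok = True
                break
        if not ok:
            continue
        graph.nodes[next_node] = p1
        index.node_pos[next_node] = p1
        add_branch(host, next_node, poly, diam, sprout=blind)
        next_node += 1
        placed += 1
    if placed < n_term:
        log.warning("placed %d of %d requested terminal branches", placed, n_term)
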