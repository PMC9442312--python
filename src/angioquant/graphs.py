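"""Spatial vessel graphs.

A :class:`VesselGraph` is the measured representation of a vascular
network: nodes are junctions (degree >= 3) or free ends (degree 1) with
positions in micrometres, branches are the junction-free vessel segments
between them, each carrying its centerline polyline, arc length, chord
length, mean diameter and the perfused / sprout flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class Branch:
    """One junction-free vessel segment.

    ``points`` is an ``(n, 3)`` polyline of (x, y, z) positions in um.
    ``node_a``/``node_b`` are end-node ids; a blind (sprout) end is still
    a node (degree 1).
    """

    id: int
    node_a: int
    node_b: int
    points: np.ndarray
    mean_diameter_um: float = float("nan")
    perfused: bool | None = None
    sprout: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    @property
    def arc_length_um(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length_um(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        chord = self.chord_length_um
        if chord == 0:
            return float("nan")
        return self.arc_length_um / chord


@dataclass
class VesselGraph:
    """Spatial graph of vessel branches.

    ``nodes`` maps node id -> (x, y, z) position in um.  Node degree is
    defined by incidence: it is always derived from the branch list.
    """

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    branches: list[Branch] = field(default_factory=list)
    domain_size_um: tuple[float, float, float] | None = None

    # -- topology ----------------------------------------------------------

    def degrees(self) -> dict[int, int]:
        deg = {n: 0 for n in self.nodes}
        for b in self.branches:
            deg[b.node_a] += 1
            deg[b.node_b] += 1
        return deg

    def junction_ids(self) -> list[int]:
        return [n for n, d in self.degrees().items() if d >= 3]

    def endpoint_ids(self) -> list[int]:
        return [n for n, d in self.degrees().items() if d == 1]

    @property
    def n_junctions(self) -> int:
        return len(self.junction_ids())

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoint_ids())

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def n_cycles(self) -> int:
        """Cycle rank (number of independent cycles) of the branch multigraph."""
        g = self.to_networkx()
        n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
        return g.number_of_edges() - g.number_of_nodes() + n_comp

    def topology_counts(self) -> tuple[int, int, int, int]:
        """(junctions, endpoints, branches, independent cycles)."""
        return (self.n_junctions, self.n_endpoints, self.n_branches, self.n_cycles())

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n, pos in self.nodes.items():
            g.add_node(n, pos=np.asarray(pos, float))
        for b in self.branches:
            g.add_edge(b.node_a, b.node_b, key=b.id, branch=b)
        return g

    # -- editing -----------------------------------------------------------

    def copy(self) -> "VesselGraph":
        return VesselGraph(
            nodes={n: np.array(p, float) for n, p in self.nodes.items()},
            branches=[replace(b, points=b.points.copy()) for b in self.branches],
            domain_size_um=self.domain_size_um,
        )

    def remove_branches(self, branch_ids: set[int]) -> "VesselGraph":
        """Return a copy with the given branches deleted and the graph
        re-canonicalized (degree-2 nodes dissolved, orphan nodes dropped)."""
        g = self.copy()
        g.branches = [b for b in g.branches if b.id not in branch_ids]
        g._drop_orphans()
        g.dissolve_degree2()
        return g

    def _drop_orphans(self) -> None:
        deg = self.degrees()
        self.nodes = {n: p for n, p in self.nodes.items() if deg.get(n, 0) > 0}

    def dissolve_degree2(self) -> None:
        """Merge branch pairs meeting at degree-2 nodes into single branches.

        A node of degree 2 is not a junction; after branch deletion (or raw
        extraction) such nodes are dissolved and the incident centerlines
        concatenated, with the merged mean diameter arc-length weighted.
        Degree-2 nodes closing a pure loop (both ends of one branch) are kept
        as an anchor for the cycle.
        """
        changed = True
        while changed:
            changed = False
            deg = self.degrees()
            incident: dict[int, list[Branch]] = {}
            for b in self.branches:
                incident.setdefault(b.node_a, []).append(b)
                incident.setdefault(b.node_b, []).append(b)
            for n, d in deg.items():
                if d != 2:
                    continue
                bs = incident[n]
                if len(bs) != 2:  # self-loop at n counts twice: keep as anchor
                    continue
                b1, b2 = bs
                if b1.id == b2.id:
                    continue
                merged = _merge_branches(b1, b2, n)
                self.branches = [b for b in self.branches if b.id not in (b1.id, b2.id)]
                self.branches.append(merged)
                del self.nodes[n]
                changed = True
                break

    def merge_nodes(self, keep: int, drop: int) -> None:
        """Contract node ``drop`` into ``keep`` (position -> midpoint).

        Incident branch polylines are re-anchored onto the merged node
        position so arc lengths stay continuous across the contraction.
        """
        pos = 0.5 * (np.asarray(self.nodes[keep]) + np.asarray(self.nodes[drop]))
        self.nodes[keep] = pos
        for b in self.branches:
            if b.node_a == drop:
                b.node_a = keep
            if b.node_b == drop:
                b.node_b = keep
            if keep in (b.node_a, b.node_b) and b.node_a != b.node_b and len(b.points) >= 2:
                if np.linalg.norm(b.points[0] - pos) <= np.linalg.norm(b.points[-1] - pos):
                    b.points = np.vstack([pos, b.points])
                else:
                    b.points = np.vstack([b.points, pos])
        del self.nodes[drop]

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "domain_size_um": list(self.domain_size_um) if self.domain_size_um else None,
            "nodes": [
                {"id": int(n), "position_um": [float(v) for v in p]}
                for n, p in sorted(self.nodes.items())
            ],
            "branches": [
                {
                    "id": int(b.id),
                    "node_a": int(b.node_a),
                    "node_b": int(b.node_b),
                    "points_um": np.asarray(b.points).tolist(),
                    "arc_length_um": b.arc_length_um,
                    "chord_length_um": b.chord_length_um,
                    "mean_diameter_um": float(b.mean_diameter_um),
                    "perfused": b.perfused,
                    "sprout": bool(b.sprout),
                }
                for b in sorted(self.branches, key=lambda b: b.id)
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj))
        return obj

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "VesselGraph":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        g = cls(
            nodes={
                int(n["id"]): np.asarray(n["position_um"], float) for n in source["nodes"]
            },
            domain_size_um=tuple(source["domain_size_um"]) if source.get("domain_size_um") else None,
        )
        for b in source["branches"]:
            g.branches.append(
                Branch(
                    id=int(b["id"]),
                    node_a=int(b["node_a"]),
                    node_b=int(b["node_b"]),
                    points=np.asarray(b["points_um"], float),
                    mean_diameter_um=float(b["mean_diameter_um"]),
                    perfused=b["perfused"],
                    sprout=bool(b["sprout"]),
                )
            )
        return g

    def branch_table(self) -> pd.DataFrame:
        """Flat per-branch table (id, lengths, diameter, flags)."""
        rows = [
            {
                "branch_id": b.id,
                "arc_length_um": b.arc_length_um,
                "chord_length_um": b.chord_length_um,
                "mean_diameter_um": b.mean_diameter_um,
                "tortuosity": b.tortuosity,
                "perfused": b.perfused,
                "sprout": b.sprout,
            }
            for b in sorted(self.branches, key=lambda b: b.id)
        ]
        return pd.DataFrame(rows)


def _merge_branches(b1: Branch, b2: Branch, via: int) -> Branch:
    """Concatenate two branches sharing degree-2 node ``via``."""
    p1 = b1.points if b1.node_b == via else b1.points[::-1]
    a_node = b1.node_a if b1.node_b == via else b1.node_b
    p2 = b2.points if b2.node_a == via else b2.points[::-1]
    b_node = b2.node_b if b2.node_a == via else b2.node_a
    pts = np.vstack([p1, p2[1:]]) if np.allclose(p1[-1], p2[0]) else np.vstack([p1, p2])
    l1, l2 = b1.arc_length_um, b2.arc_length_um
    if l1 + l2 > 0 and np.isfinite(b1.mean_diameter_um) and np.isfinite(b2.mean_diameter_um):
        d = (b1.mean_diameter_um * l1 + b2.mean_diameter_um * l2) / (l1 + l2)
    else:
        d = b1.mean_diameter_um
    if b1.perfused == b2.perfused:
        perfused = b1.perfused
    else:
        # disagreeing flags: the longer segment dominates the merged branch
        perfused = (b1 if l1 >= l2 else b2).perfused
    return Branch(
        id=min(b1.id, b2.id),
        node_a=a_node,
        node_b=b_node,
        points=pts,
        mean_diameter_um=d,
        perfused=perfused,
        sprout=b1.sprout or b2.sprout,
    )
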