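"""Vascular network morphometry.

Computes the per-stack parameter suite used to follow tumour vascular
remodelling over time: branch tortuosity (arc/chord), directional
coherence of branch orientations, junction (node) density per mm^2 of
analyzed footprint, the fractions of short (< 80 um) and long (> 400
um) branches, mean branch length and diameter, the length-to-diameter
ratio, sprout count, and the length-weighted perfused fraction —
together with normalization of a longitudinal series to its baseline
day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .graphs import VesselGraph

log = logging.getLogger(__name__)

L_SHORT_UM = 80.0
L_LONG_UM = 400.0
#: long-branch threshold preset for the sparser melanoma-like networks
L_LONG_UM_B16F10 = 300.0


@dataclass
class NetworkMetrics:
    """One record of the vascular parameter suite for one stack."""

    tortuosity: float
    directional_coherence: float
    node_density_per_mm2: float
    frac_short: float
    frac_long: float
    mean_branch_length_um: float
    mean_diameter_um: float
    length_to_diameter: float
    length_to_diameter_mean_of_ratios: float
    sprout_count: int
    perfused_fraction: float
    analysis_area_mm2: float
    n_branches: int
    n_junctions: int

    def to_dict(self) -> dict:
        return asdict(self)


def branch_tortuosity(graph: VesselGraph, weighting: str = "length") -> float:
    """Network tortuosity: arc/chord per branch, aggregated either
    arc-length-weighted (default) or as a plain per-branch mean.
    Branches with zero chord (closed loops) are excluded and logged."""
    vals, weights = [], []
    for b in graph.branches:
        chord = b.chord_length_um
        if chord == 0:
            log.info("branch %d has zero chord (loop); excluded from tortuosity", b.id)
            continue
        vals.append(b.arc_length_um / chord)
        weights.append(b.arc_length_um)
    if not vals:
        raise ValueError("no branches with nonzero chord")
    if weighting == "length":
        return float(np.average(vals, weights=weights))
    if weighting == "branch":
        return float(np.mean(vals))
    raise ValueError(f"unknown weighting {weighting!r}")


def directional_coherence(graph: VesselGraph) -> float:
    """Coherence of branch chord directions in [0, 1].

    Builds the length-weighted second-moment orientation tensor of unit
    chord directions (sign-invariant) and maps its largest eigenvalue
    lmax from the isotropic value 1/3 to 0 and perfect alignment to 1:
    coherence = (3 lmax - 1) / 2.  Undefined (NaN) for < 2 branches.
    """
    dirs, weights = [], []
    for b in graph.branches:
        v = b.points[-1] - b.points[0]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        dirs.append(v / nv)
        weights.append(b.arc_length_um)
    if len(dirs) < 2:
        return float("nan")
    u = np.asarray(dirs)
    w = np.asarray(weights) / np.sum(weights)
    tensor = np.einsum("i,ij,ik->jk", w, u, u)
    lmax = float(np.linalg.eigvalsh(tensor)[-1])
    return (3.0 * lmax - 1.0) / 2.0


def node_density(graph: VesselGraph, analysis_area_mm2: float) -> float:
    """Junction nodes (degree >= 3) per mm^2 of projected footprint."""
    if analysis_area_mm2 <= 0:
        raise ValueError("analysis area must be positive")
    return graph.n_junctions / analysis_area_mm2


def branch_length_fractions(
    graph: VesselGraph,
    l_short_um: float = L_SHORT_UM,
    l_long_um: float = L_LONG_UM,
) -> tuple[float, float]:
    """Count-weighted fractions of branches with arc length < l_short
    and > l_long."""
    if not graph.branches:
        raise ValueError("empty graph")
    lengths = np.array([b.arc_length_um for b in graph.branches])
    return float(np.mean(lengths < l_short_um)), float(np.mean(lengths > l_long_um))


def length_to_diameter_ratio(graph: VesselGraph, mode: str = "ratio_of_means") -> float:
    """l/d ratio of the network.

    ``ratio_of_means`` (default) divides the mean branch length by the
    mean diameter; ``mean_of_ratios`` averages per-branch l/d.  The two
    differ on heterogeneous networks and are both reported.
    """
    if not graph.branches:
        raise ValueError("empty graph")
    lengths = np.array([b.arc_length_um for b in graph.branches])
    diams = np.array([b.mean_diameter_um for b in graph.branches])
    if np.any(~np.isfinite(diams)) or np.any(diams <= 0):
        raise ValueError("branch diameters unset or non-positive")
    if mode == "ratio_of_means":
        return float(lengths.mean() / diams.mean())
    if mode == "mean_of_ratios":
        return float(np.mean(lengths / diams))
    raise ValueError(f"unknown mode {mode!r}")


def perfused_fraction(graph: VesselGraph) -> float:
    """Arc-length-weighted fraction of branches flagged perfused."""
    if not graph.branches:
        raise ValueError("empty graph")
    if any(b.perfused is None for b in graph.branches):
        raise ValueError("perfusion flags unset")
    lengths = np.array([b.arc_length_um for b in graph.branches])
    flags = np.array([bool(b.perfused) for b in graph.branches])
    total = lengths.sum()
    if total == 0:
        raise ValueError("zero total length")
    return float(lengths[flags].sum() / total)


def sprout_count(graph: VesselGraph) -> int:
    return sum(bool(b.sprout) for b in graph.branches)


def summarize_network(
    graph: VesselGraph,
    analysis_area_mm2: float,
    l_short_um: float = L_SHORT_UM,
    l_long_um: float = L_LONG_UM,
    tortuosity_weighting: str = "length",
) -> NetworkMetrics:
    """Bundle the full parameter suite for one stack / timepoint."""
    if not graph.branches:
        raise ValueError("empty graph")
    lengths = np.array([b.arc_length_um for b in graph.branches])
    diams = np.array([b.mean_diameter_um for b in graph.branches])
    frac_short, frac_long = branch_length_fractions(graph, l_short_um, l_long_um)
    return NetworkMetrics(
        tortuosity=branch_tortuosity(graph, tortuosity_weighting),
        directional_coherence=directional_coherence(graph),
        node_density_per_mm2=node_density(graph, analysis_area_mm2),
        frac_short=frac_short,
        frac_long=frac_long,
        mean_branch_length_um=float(lengths.mean()),
        mean_diameter_um=float(diams.mean()),
        length_to_diameter=length_to_diameter_ratio(graph, "ratio_of_means"),
        length_to_diameter_mean_of_ratios=length_to_diameter_ratio(graph, "mean_of_ratios"),
        sprout_count=sprout_count(graph),
        perfused_fraction=(
            perfused_fraction(graph)
            if all(b.perfused is not None for b in graph.branches)
            else float("nan")
        ),
        analysis_area_mm2=analysis_area_mm2,
        n_branches=graph.n_branches,
        n_junctions=graph.n_junctions,
    )


def normalize_to_baseline(series: pd.DataFrame, baseline_day=None) -> pd.DataFrame:
    """Divide each numeric metric column by its value on the baseline
    day (first day by default); the baseline row maps to 1.0.

    Zero baselines yield NaN for that column (logged), never an error.
    """
    if "day" not in series.columns:
        raise ValueError("series needs a 'day' column")
    df = series.sort_values("day").reset_index(drop=True)
    if baseline_day is None:
        baseline_day = df["day"].iloc[0]
    base_rows = df[df["day"] == baseline_day]
    if base_rows.empty:
        raise ValueError(f"baseline day {baseline_day!r} not in series")
    base = base_rows.iloc[0]
    out = df.copy()
    for col in df.columns:
        if col == "day" or not pd.api.types.is_numeric_dtype(df[col]):
            continue
        b = base[col]
        if b == 0 or not np.isfinite(b):
            log.warning("baseline of %r is zero or invalid; normalized values set NaN", col)
            out[col] = np.nan
        else:
            out[col] = df[col] / b
    return out


def tumor_volume_mm3(length_mm: float, width_mm: float, depth_mm: float) -> float:
    """Caliper tumour volume: L x W x D x pi/6 (ellipsoid approximation)."""
    if length_mm <= 0 or width_mm <= 0 or depth_mm <= 0:
        raise ValueError("dimensions must be positive")
    return length_mm * width_mm * depth_mm * math.pi / 6.0
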