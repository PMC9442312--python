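"""Validation protocols tying the synthetic generators to the analysis
pipeline.

Each protocol fixes the study conditions (generator spec, render
geometry, extraction parameters) for one kind of end-to-end check:

* ``topology``   — small networks rendered noiselessly for exact
  graph-topology recovery;
* ``recovery``   — a 256 x 256 x 64 voxel stack (2 um isotropic, i.e. a
  0.5 mm field of view) for quantitative metric recovery at a given
  noise level;
* ``pruning``    — graph-level radiation-response emulation: deleting
  the small non-perfused branches from a dense (MC38-like) and a sparse
  (B16F10-like) network and comparing the signed metric changes.

Extraction lengths are tied to tube calibre: spur pruning must exceed
the end-erosion of thinning (about one tube radius) and junction
merging the diameter of the thickest junction blob, while remaining
below the shortest true branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .extract import (
    classify_branch_perfusion,
    estimate_diameters,
    extract_graph,
    flag_sprouts,
    skeletonize_mask,
)
from .graphs import Branch, VesselGraph
from .metrics import NetworkMetrics, summarize_network
from .segmentation import perfusion_mask, segment_vessels
from .stacks import ImageStack
from .synth.network import NetworkSpec, generate_network
from .synth.render import RenderSpec, render_stack

# -- topology protocol ------------------------------------------------------

TOPOLOGY_PRUNE_UM = 14.0
TOPOLOGY_MERGE_UM = 24.0


def topology_network_spec(seed: int) -> NetworkSpec:
    """Small (<= ~50 branch) networks with tube calibres well above the
    render resolution and true branch lengths well above the cleaning
    lengths, so recovered topology must match exactly."""
    return NetworkSpec(
        domain_size_um=(400.0, 400.0, 120.0),
        target_node_density_per_mm2=100.0,
        branch_length_dist=(math.log(110.0), 0.4),
        diameter_dist=(math.log(10.0), 0.25),
        diameter_range_um=(6.0, 16.0),
        tortuosity_amplitude=0.03,
        sprout_fraction=0.15,
        min_junction_separation_um=60.0,
        clearance_margin_um=10.0,
        sprout_length_range_um=(45.0, 90.0),
        repair_relax=False,
        seed=seed,
    )


def run_topology_trial(seed: int) -> tuple[tuple, tuple]:
    """Generate, render noiselessly, re-extract; return (truth, recovered)
    (junctions, endpoints, branches, cycles) tuples."""
    g = generate_network(topology_network_spec(seed))
    stack = render_stack(g, RenderSpec(voxel_size_um=(2.0, 2.0, 2.0)))
    mask = segment_vessels(stack, iso_um=2.0, smooth_um=0.0)
    skel = skeletonize_mask(mask)
    rec = extract_graph(skel, mask.voxel_size_um, prune_um=TOPOLOGY_PRUNE_UM,
                        merge_junction_um=TOPOLOGY_MERGE_UM)
    return g.topology_counts(), rec.topology_counts()


# -- metric-recovery protocol ----------------------------------------------

RECOVERY_PRUNE_UM = 14.0
# junction blobs of the thickest tubes (28 um) can thin into split
# junctions; the merge length must exceed that while staying below the
# shortest true branch (45 um)
RECOVERY_MERGE_UM = 35.0
#: the benchmark field of view is 0.5 mm, so the long-branch threshold is
#: scaled down from the 400 um used on mm-scale mosaics
RECOVERY_L_SHORT_UM = 80.0
RECOVERY_L_LONG_UM = 200.0


def recovery_network_spec(seed: int) -> NetworkSpec:
    """Network filling a 512 x 512 x 128 um volume rendered at 2 um
    isotropic (256 x 256 x 64 voxels)."""
    return NetworkSpec(
        domain_size_um=(512.0, 512.0, 128.0),
        target_node_density_per_mm2=160.0,
        branch_length_dist=(math.log(100.0), 0.4),
        diameter_dist=(math.log(14.0), 0.30),
        diameter_range_um=(8.0, 28.0),
        # the benchmark calibres are scaled down with the field of view,
        # so the non-perfusion midpoint scales down with them
        nonperfused_diameter_threshold_um=12.0,
        nonperfused_diameter_scale_um=3.0,
        tortuosity_amplitude=0.05,
        sprout_fraction=0.2,
        min_junction_separation_um=50.0,
        clearance_margin_um=8.0,
        sprout_length_range_um=(45.0, 90.0),
        repair_relax=False,
        seed=seed,
    )


def recovery_render_spec(seed: int, snr: float | None = None) -> RenderSpec:
    """Noiseless or Gaussian-noise render at SNR = signal / sigma."""
    signal = 100.0
    return RenderSpec(
        voxel_size_um=(2.0, 2.0, 2.0),
        psf_sigma_um=(1.0, 1.0, 1.0),
        signal_level=signal,
        noise_model="none" if snr is None else "gaussian",
        noise_sigma=0.0 if snr is None else signal / snr,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    truth: NetworkMetrics
    recovered: NetworkMetrics

    def relative_errors(self) -> dict[str, float]:
        out = {}
        for name in (
            "tortuosity",
            "node_density_per_mm2",
            "frac_short",
            "frac_long",
            "mean_branch_length_um",
            "mean_diameter_um",
            "length_to_diameter",
            "sprout_count",
            "perfused_fraction",
        ):
            t = float(getattr(self.truth, name))
            r = float(getattr(self.recovered, name))
            # a zero truth value (e.g. no long branches) compares absolutely
            out[name] = abs(r - t) / abs(t) if t != 0 else abs(r)
        return out


def analyze_rendered_stack(
    stack: ImageStack,
    iso_um: float = 2.0,
    smooth_um: float = 1.5,
    prune_um: float = RECOVERY_PRUNE_UM,
    merge_junction_um: float = RECOVERY_MERGE_UM,
    # skeleton end-erosion pulls boundary endpoints inward by up to one
    # tube radius (14 um here); the margin must exceed that
    boundary_margin_um: float = 20.0,
    coverage_threshold: float = 0.5,
    l_short_um: float = RECOVERY_L_SHORT_UM,
    l_long_um: float = RECOVERY_L_LONG_UM,
) -> tuple[VesselGraph, NetworkMetrics]:
    """Segment -> skeletonize -> graph -> measure, one stack."""
    mask = segment_vessels(stack, iso_um=iso_um, smooth_um=smooth_um)
    pmask, _ = perfusion_mask(stack, mask, smooth_um=smooth_um)
    skel = skeletonize_mask(mask)
    graph = extract_graph(skel, mask.voxel_size_um, prune_um=prune_um,
                          merge_junction_um=merge_junction_um, mask=mask)
    estimate_diameters(graph, mask)
    flag_sprouts(graph, boundary_margin_um=boundary_margin_um)
    classify_branch_perfusion(graph, pmask, coverage_threshold)
    metrics = summarize_network(graph, stack.projected_area_mm2,
                                l_short_um=l_short_um, l_long_um=l_long_um)
    return graph, metrics


def run_recovery_trial(seed: int, snr: float | None = None) -> RecoveryResult:
    """Ground-truth metrics vs metrics recovered through the full render
    -> segment -> graph pipeline."""
    g = generate_network(recovery_network_spec(seed))
    truth = summarize_network(
        g, recovery_network_spec(seed).projected_area_mm2,
        l_short_um=RECOVERY_L_SHORT_UM, l_long_um=RECOVERY_L_LONG_UM,
    )
    stack = render_stack(g, recovery_render_spec(seed, snr))
    _, rec = analyze_rendered_stack(stack)
    return RecoveryResult(truth=truth, recovered=rec)


def _union_graph(graphs) -> VesselGraph:
    out = VesselGraph()
    offset = 0
    bid = 0
    for g in graphs:
        for n, p in g.nodes.items():
            out.nodes[n + offset] = p
        for b in g.branches:
            nb = Branch(
                id=bid, node_a=b.node_a + offset, node_b=b.node_b + offset,
                points=b.points, mean_diameter_um=b.mean_diameter_um,
                perfused=b.perfused, sprout=b.sprout,
            )
            out.branches.append(nb)
            bid += 1
        offset += (max(g.nodes) + 1) if g.nodes else 0
    return out


def run_recovery_ensemble(seeds, snr: float | None = None) -> RecoveryResult:
    """Metric recovery over an ensemble of stacks, scored on the pooled
    branch population (tiles of a mosaic are pooled before computing
    count-sensitive metrics like the sprout count)."""
    truths, recs = [], []
    area = 0.0
    for seed in seeds:
        g = generate_network(recovery_network_spec(seed))
        stack = render_stack(g, recovery_render_spec(seed, snr))
        rec, _ = analyze_rendered_stack(stack)
        truths.append(g)
        recs.append(rec)
        area += recovery_network_spec(seed).projected_area_mm2
    truth = summarize_network(_union_graph(truths), area,
                              l_short_um=RECOVERY_L_SHORT_UM,
                              l_long_um=RECOVERY_L_LONG_UM)
    recovered = summarize_network(_union_graph(recs), area,
                                  l_short_um=RECOVERY_L_SHORT_UM,
                                  l_long_um=RECOVERY_L_LONG_UM)
    return RecoveryResult(truth=truth, recovered=recovered)


# -- radiation-pruning protocol --------------------------------------------


def prune_small_nonperfused(graph: VesselGraph, d_max_um: float = 25.0) -> VesselGraph:
    """Emulate the selective loss of small non-perfused vessels after
    irradiation: delete every non-perfused branch with mean diameter
    below ``d_max_um`` and re-canonicalize the graph."""
    doomed = {
        b.id
        for b in graph.branches
        if b.perfused is False and b.mean_diameter_um < d_max_um
    }
    return graph.remove_branches(doomed)


PRUNING_METRICS = (
    "node_density_per_mm2",
    "frac_short",
    "frac_long",
    "length_to_diameter",
    "perfused_fraction",
    "sprout_count",
)

#: signed direction of each metric's change when small non-perfused
#: vessels are lost (the irradiation response of a dense network)
PRUNING_DIRECTIONS = {
    "node_density_per_mm2": -1,
    "frac_short": -1,
    "frac_long": +1,
    "length_to_diameter": +1,
    "perfused_fraction": +1,
    "sprout_count": -1,
}


#: domain used for the pruning suite (smaller than the preset default so
#: a trial stays inexpensive while keeping hundreds of branches)
PRUNING_DOMAIN_UM = (700.0, 700.0, 150.0)


def pruning_response(spec: NetworkSpec, l_long_um: float | None = None) -> dict[str, float]:
    """Relative change of each metric after deleting non-perfused
    branches below 25 um from the given network.

    The long-branch threshold defaults to the 95th percentile of the
    baseline branch-length distribution, so the baseline fraction is
    nonzero and comparable between network presets of different scale.
    """
    g = generate_network(spec)
    if l_long_um is None:
        l_long_um = float(np.percentile([b.arc_length_um for b in g.branches], 95))
    area = spec.projected_area_mm2
    before = summarize_network(g, area, l_long_um=l_long_um)
    after = summarize_network(prune_small_nonperfused(g), area, l_long_um=l_long_um)
    out = {}
    for name in PRUNING_METRICS:
        b = float(getattr(before, name))
        a = float(getattr(after, name))
        out[name] = (a - b) / b if b != 0 else float("nan")
    return out


def mean_pruning_response(make_spec, seeds, l_long_um: float | None = None) -> dict[str, float]:
    """Average the relative changes over several generator seeds."""
    acc: dict[str, list[float]] = {}
    for s in seeds:
        resp = pruning_response(make_spec(seed=s), l_long_um=l_long_um)
        for k, v in resp.items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}
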