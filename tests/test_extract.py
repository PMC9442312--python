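import numpy as np
import pytest

from angioquant.extract import (
    classify_branch_perfusion,
    estimate_diameters,
    extract_graph,
    flag_sprouts,
    skeletonize_mask,
)
from angioquant.graphs import Branch, VesselGraph
from angioquant.stacks import VesselMask
from angioquant.synth.render import RenderSpec, rasterize_tubes, render_stack

from conftest import straight_tube_graph


def tube_mask(diameter=20.0, domain=(200.0, 100.0, 100.0), iso=2.0) -> VesselMask:
    g = straight_tube_graph(diameter_um=diameter, domain=domain)
    shape = tuple(int(round(d / iso)) for d in (domain[2], domain[1], domain[0]))
    return VesselMask(rasterize_tubes(g, shape, (iso,) * 3), (iso,) * 3)


def test_empty_mask_empty_skeleton_and_graph():
    mask = VesselMask(np.zeros((10, 10, 10), bool), (2, 2, 2))
    skel = skeletonize_mask(mask)
    assert not skel.any()
    g = extract_graph(skel, mask.voxel_size_um)
    assert g.topology_counts() == (0, 0, 0, 0)


def test_straight_tube_centerline_near_axis():
    mask = tube_mask()
    skel = skeletonize_mask(mask)
    zz, yy, xx = np.nonzero(skel)
    # physical distance of skeleton voxels from the true axis (y=z=50)
    d = np.hypot(zz * 2.0 - 50.0, yy * 2.0 - 50.0)
    assert d.max() <= 2.0 + 1e-9
    g = extract_graph(skel, mask.voxel_size_um, prune_um=12.0)
    assert g.topology_counts() == (0, 2, 1, 0)


def test_torus_skeleton_single_cycle():
    # solid torus around the z axis: R=30, r=8 um at 2 um voxels
    iso = 2.0
    n = 50
    ax = (np.arange(n) - n / 2) * iso
    X, Y, Z = np.meshgrid(ax, ax, (np.arange(16) - 8) * iso, indexing="ij")
    ring = (np.hypot(X, Y) - 30.0) ** 2 + Z**2 <= 8.0**2
    mask = VesselMask(np.transpose(ring, (2, 0, 1)), (iso,) * 3)
    skel = skeletonize_mask(mask)
    g = extract_graph(skel, mask.voxel_size_um, prune_um=10.0)
    assert g.n_cycles() == 1
    assert g.n_endpoints == 0


def test_y_junction_three_branches():
    g = VesselGraph(domain_size_um=(200.0, 200.0, 80.0))
    c = np.array([100.0, 100.0, 40.0])
    arms = [np.array([0.0, 100.0, 40.0]), np.array([200.0, 30.0, 40.0]),
            np.array([200.0, 170.0, 40.0])]
    g.nodes = {0: c, 1: arms[0], 2: arms[1], 3: arms[2]}
    for i, a in enumerate(arms):
        g.branches.append(Branch(i, 0, i + 1, np.vstack([c, a]), mean_diameter_um=14))
    stack = render_stack(g, RenderSpec(voxel_size_um=(2, 2, 2)))
    mask = VesselMask(stack.channel("endothelium") > 50, (2, 2, 2))
    skel = skeletonize_mask(mask)
    rec = extract_graph(skel, mask.voxel_size_um, prune_um=12.0, merge_junction_um=24.0)
    assert rec.topology_counts() == (1, 3, 3, 0)


def test_diameter_recovery_straight_tube():
    mask = tube_mask(diameter=20.0)
    skel = skeletonize_mask(mask)
    g = extract_graph(skel, mask.voxel_size_um, prune_um=12.0, mask=mask)
    estimate_diameters(g, mask)
    assert g.branches[0].mean_diameter_um == pytest.approx(20.0, abs=2.0)


def test_diameter_cone_mean_of_linear_radius():
    # cone from radius 5 to 15 um along x: mean diameter ~ 20 um
    iso = 1.0
    nx, ny, nz = 200, 50, 50
    x = np.arange(nx) * iso
    r = 5.0 + 10.0 * x / x.max()
    zz, yy = np.meshgrid(np.arange(nz) * iso, np.arange(ny) * iso, indexing="ij")
    vol = np.zeros((nz, ny, nx), bool)
    for i in range(nx):
        vol[:, :, i] = np.hypot(zz - 25.0, yy - 25.0) <= r[i]
    mask = VesselMask(vol, (iso,) * 3)
    skel = skeletonize_mask(mask)
    g = extract_graph(skel, mask.voxel_size_um, prune_um=18.0, mask=mask)
    estimate_diameters(g, mask)
    assert len(g.branches) == 1
    assert g.branches[0].mean_diameter_um == pytest.approx(20.0, rel=0.10)


def test_isolated_voxel_degenerate_diameter():
    vol = np.zeros((9, 9, 9), bool)
    vol[4, 4, 4] = True
    mask = VesselMask(vol, (2, 2, 2))
    g = VesselGraph(domain_size_um=(18, 18, 18))
    g.nodes = {0: np.array([8.0, 8.0, 8.0]), 1: np.array([8.0, 8.0, 8.0])}
    g.branches = [Branch(0, 0, 1, np.array([[8.0, 8.0, 8.0]]))]
    estimate_diameters(g, mask)
    # EDT of a single voxel gives one voxel size
    assert g.branches[0].mean_diameter_um == pytest.approx(4.0, abs=2.1)


def test_flag_sprouts_geometry():
    g = VesselGraph(domain_size_um=(200.0, 200.0, 100.0))
    c = np.array([100.0, 100.0, 50.0])
    g.nodes = {
        0: c,
        1: np.array([0.0, 100.0, 50.0]),     # on a face
        2: np.array([200.0, 100.0, 50.0]),   # on a face
        3: np.array([100.0, 150.0, 50.0]),   # interior blind end
    }
    for i, n in enumerate((1, 2, 3)):
        g.branches.append(Branch(i, 0, n, np.vstack([c, g.nodes[n]])))
    flag_sprouts(g, boundary_margin_um=10.0)
    assert [b.sprout for b in g.branches] == [False, False, True]


def test_classify_perfusion_thresholds():
    g = straight_tube_graph(diameter_um=10.0)
    g.branches[0].points = np.array([[x, 50.0, 50.0] for x in np.linspace(0, 200, 41)])
    full = VesselMask(np.ones((50, 50, 100), bool), (2, 2, 2))
    empty = VesselMask(np.zeros((50, 50, 100), bool), (2, 2, 2))
    classify_branch_perfusion(g, full)
    assert g.branches[0].perfused is True
    classify_branch_perfusion(g, empty)
    assert g.branches[0].perfused is False
    # half coverage straddles the default 0.5 threshold
    half = VesselMask(np.zeros((50, 50, 100), bool), (2, 2, 2))
    half.data[:, :, :50] = True
    classify_branch_perfusion(g, half, coverage_threshold=0.4)
    assert g.branches[0].perfused is True
    classify_branch_perfusion(g, half, coverage_threshold=0.7)
    assert g.branches[0].perfused is False
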