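import math

import numpy as np
import pandas as pd
import pytest

from angioquant.graphs import Branch, VesselGraph
from angioquant.metrics import (
    branch_length_fractions,
    branch_tortuosity,
    directional_coherence,
    length_to_diameter_ratio,
    node_density,
    normalize_to_baseline,
    perfused_fraction,
    summarize_network,
    tumor_volume_mm3,
)

from conftest import graph_from_lengths


def polyline_branch(pts, bid=0):
    return Branch(bid, 0, 1, np.asarray(pts, float))


def single_branch_graph(pts):
    g = VesselGraph()
    pts = np.asarray(pts, float)
    g.nodes = {0: pts[0], 1: pts[-1]}
    g.branches = [polyline_branch(pts)]
    return g


class TestTortuosity:
    def test_straight_branch_is_one(self):
        g = single_branch_graph([[0, 0, 0], [100, 0, 0]])
        assert branch_tortuosity(g) == pytest.approx(1.0)

    def test_semicircle_is_half_pi(self):
        t = np.linspace(0, np.pi, 250)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        g = single_branch_graph(pts)
        assert branch_tortuosity(g) == pytest.approx(np.pi / 2, rel=0.01)

    def test_helix_matches_closed_form(self):
        R, pitch = 10.0, 20.0
        t = np.linspace(0, 2 * np.pi, 400)
        pts = np.column_stack([R * np.cos(t), R * np.sin(t), pitch * t / (2 * np.pi)])
        g = single_branch_graph(pts)
        expected = math.sqrt((2 * math.pi * R) ** 2 + pitch**2) / pitch
        assert branch_tortuosity(g) == pytest.approx(expected, rel=0.01)

    def test_zero_chord_branch_excluded(self):
        t = np.linspace(0, 2 * np.pi, 100)
        loop = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        loop[-1] = loop[0]  # close the loop exactly
        g = single_branch_graph([[0, 0, 0], [100, 0, 0]])
        g.nodes[2] = loop[0]
        g.branches.append(Branch(1, 2, 2, loop))
        assert branch_tortuosity(g) == pytest.approx(1.0)


class TestCoherence:
    def test_parallel_is_one(self):
        g = VesselGraph()
        g.nodes = {i: np.zeros(3) for i in range(6)}
        for i in range(3):
            g.branches.append(
                polyline_branch([[0, i * 50, 0], [100, i * 50, 0]], bid=i))
        assert directional_coherence(g) == pytest.approx(1.0)

    def test_orthogonal_pairs_quarter(self):
        g = VesselGraph()
        g.nodes = {}
        g.branches = [
            polyline_branch([[0, 0, 0], [100, 0, 0]], 0),
            polyline_branch([[0, 0, 0], [0, 100, 0]], 1),
        ]
        assert directional_coherence(g) == pytest.approx(0.25)

    def test_isotropic_directions_near_zero(self, rng):
        g = VesselGraph()
        u = rng.normal(size=(10000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        g.branches = [
            polyline_branch(np.vstack([np.zeros(3), 100 * d]), i)
            for i, d in enumerate(u)
        ]
        assert abs(directional_coherence(g)) < 0.03

    def test_undefined_below_two_branches(self):
        g = single_branch_graph([[0, 0, 0], [100, 0, 0]])
        assert math.isnan(directional_coherence(g))


class TestDensityAndFractions:
    def test_node_density_arithmetic(self):
        g = graph_from_lengths(np.full(12, 100.0))  # 1 junction (degree 12)
        assert node_density(g, 0.25) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            node_density(g, 0.0)

    def test_fraction_examples(self):
        g = graph_from_lengths([50, 100, 500])
        assert branch_length_fractions(g, 80, 400) == pytest.approx((1 / 3, 1 / 3))
        g2 = graph_from_lengths([200, 200, 200])
        assert branch_length_fractions(g2, 80, 400) == (0.0, 0.0)
        with pytest.raises(ValueError):
            branch_length_fractions(VesselGraph())

    def test_fractions_match_lognormal_cdf(self, rng):
        from scipy.stats import lognorm

        mu, sigma = math.log(120.0), 0.5
        lengths = rng.lognormal(mu, sigma, 10000)
        g = graph_from_lengths(lengths)
        fs, fl = branch_length_fractions(g, 80.0, 400.0)
        dist = lognorm(s=sigma, scale=math.exp(mu))
        assert fs == pytest.approx(dist.cdf(80.0), abs=0.01)
        assert fl == pytest.approx(dist.sf(400.0), abs=0.01)


class TestLengthToDiameter:
    def test_equal_modes_on_homogeneous(self):
        g = graph_from_lengths([100, 100], diameters=[20, 20])
        assert length_to_diameter_ratio(g, "ratio_of_means") == pytest.approx(5.0)
        assert length_to_diameter_ratio(g, "mean_of_ratios") == pytest.approx(5.0)

    def test_modes_differ_on_heterogeneous(self):
        g = graph_from_lengths([100, 100], diameters=[10, 50])
        assert length_to_diameter_ratio(g, "ratio_of_means") == pytest.approx(100 / 30)
        assert length_to_diameter_ratio(g, "mean_of_ratios") == pytest.approx(6.0)


def test_perfused_fraction_length_weighted():
    g = graph_from_lengths([100, 300], perfused=[True, False])
    assert perfused_fraction(g) == pytest.approx(0.25)
    g2 = graph_from_lengths([50, 70], perfused=[True, True])
    assert perfused_fraction(g2) == 1.0
    g3 = graph_from_lengths([50, 70])
    with pytest.raises(ValueError):
        perfused_fraction(g3)


class TestSummarize:
    def hand_graph(self):
        g = graph_from_lengths(
            [50, 100, 150, 200, 500],
            diameters=[10, 10, 20, 20, 40],
            perfused=[True, False, True, True, False],
        )
        g.branches[1].sprout = True
        return g

    def test_hand_worked_values(self):
        m = summarize_network(self.hand_graph(), analysis_area_mm2=0.5)
        assert m.tortuosity == pytest.approx(1.0)
        assert m.node_density_per_mm2 == pytest.approx(2.0)  # 1 junction / 0.5
        assert m.frac_short == pytest.approx(1 / 5)
        assert m.frac_long == pytest.approx(1 / 5)
        assert m.mean_branch_length_um == pytest.approx(200.0)
        assert m.mean_diameter_um == pytest.approx(20.0)
        assert m.length_to_diameter == pytest.approx(10.0)
        assert m.sprout_count == 1
        assert m.perfused_fraction == pytest.approx(400 / 1000)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            summarize_network(VesselGraph(), 1.0)

    def test_rigid_rotation_invariance(self, rng):
        g = self.hand_graph()
        m0 = summarize_network(g, 0.5)
        # random rotation matrix via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        g2 = g.copy()
        g2.nodes = {n: q @ p for n, p in g2.nodes.items()}
        for b in g2.branches:
            b.points = b.points @ q.T
        m1 = summarize_network(g2, 0.5)
        for f in ("tortuosity", "directional_coherence", "frac_short", "frac_long",
                  "mean_branch_length_um", "mean_diameter_um", "length_to_diameter",
                  "perfused_fraction"):
            assert getattr(m1, f) == pytest.approx(getattr(m0, f), rel=1e-9)

    def test_scale_equivariance(self):
        g = self.hand_graph()
        k = 2.5
        m0 = summarize_network(g, 0.5)
        g2 = g.copy()
        g2.nodes = {n: k * p for n, p in g2.nodes.items()}
        for b in g2.branches:
            b.points = k * b.points
            b.mean_diameter_um = k * b.mean_diameter_um
        m1 = summarize_network(g2, 0.5 * k**2)
        assert m1.mean_branch_length_um == pytest.approx(k * m0.mean_branch_length_um)
        assert m1.mean_diameter_um == pytest.approx(k * m0.mean_diameter_um)
        assert m1.tortuosity == pytest.approx(m0.tortuosity)
        assert m1.length_to_diameter == pytest.approx(m0.length_to_diameter)
        assert m1.perfused_fraction == pytest.approx(m0.perfused_fraction)
        assert m1.node_density_per_mm2 == pytest.approx(m0.node_density_per_mm2 / k**2)


class TestNormalize:
    def test_series_divided_by_baseline(self):
        df = pd.DataFrame({"day": [1, 2, 3], "x": [2.0, 4.0, 6.0]})
        out = normalize_to_baseline(df)
        assert out["x"].tolist() == pytest.approx([1.0, 2.0, 3.0])

    def test_constant_series_all_one(self):
        df = pd.DataFrame({"day": [1, 2], "x": [5.0, 5.0]})
        assert normalize_to_baseline(df)["x"].tolist() == [1.0, 1.0]

    def test_zero_baseline_missing_not_crash(self):
        df = pd.DataFrame({"day": [1, 2], "x": [0.0, 3.0]})
        out = normalize_to_baseline(df)
        assert out["x"].isna().all()


def test_tumor_volume_formula():
    assert tumor_volume_mm3(1, 1, 1) == pytest.approx(math.pi / 6)
    assert tumor_volume_mm3(10, 8, 6) == pytest.approx(80 * math.pi)
    assert tumor_volume_mm3(2, 1, 1) == tumor_volume_mm3(1, 2, 1)
    with pytest.raises(ValueError):
        tumor_volume_mm3(0, 1, 1)
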