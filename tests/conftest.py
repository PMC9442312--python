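import numpy as np
import pytest

from angioquant.graphs import Branch, VesselGraph


def straight_tube_graph(diameter_um=20.0, domain=(200.0, 100.0, 100.0),
                        axis="x") -> VesselGraph:
    """One straight tube spanning the domain through its centre."""
    lx, ly, lz = domain
    if axis == "x":
        a, b = np.array([0.0, ly / 2, lz / 2]), np.array([lx, ly / 2, lz / 2])
    else:
        a, b = np.array([lx / 2, 0.0, lz / 2]), np.array([lx / 2, ly, lz / 2])
    g = VesselGraph(domain_size_um=domain)
    g.nodes = {0: a, 1: b}
    g.branches = [Branch(0, 0, 1, np.vstack([a, b]), mean_diameter_um=diameter_um)]
    return g


def graph_from_lengths(lengths, diameters=None, perfused=None) -> VesselGraph:
    """Star-shaped graph with straight branches of prescribed lengths."""
    lengths = np.asarray(lengths, float)
    n = len(lengths)
    if diameters is None:
        diameters = np.full(n, 10.0)
    g = VesselGraph()
    center = np.zeros(3)
    g.nodes = {0: center}
    for i, (l, d) in enumerate(zip(lengths, diameters)):
        ang = 2 * np.pi * i / max(n, 1)
        end = np.array([l * np.cos(ang), l * np.sin(ang), 0.0])
        g.nodes[i + 1] = end
        b = Branch(i, 0, i + 1, np.vstack([center, end]), mean_diameter_um=float(d))
        if perfused is not None:
            b.perfused = bool(perfused[i])
        g.branches.append(b)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(0)
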