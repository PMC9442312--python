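"""Synthetic 2D section cell tables.

Emulates stained tumour sections scored for vessel-size-stratified
endothelial apoptosis and proliferation: each vessel cross-section
carries a handful of endothelial cells (TECs), apoptosis (cleaved
caspase-3) is enriched on small vessels, proliferation (EdU) likewise,
and caspase-positive non-endothelial cells form a homogeneous Poisson
background over the section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..sections import CellTable


@dataclass
class CellPlacementSpec:
    """Parameters for one synthetic section.

    Rates are per-vessel (apoptosis: probability that a vessel contains
    at least one caspase-3+ TEC) or per-TEC (EdU) probabilities, split
    by the small/large class at ``area_threshold_um2``.
    """

    section_extent_um: tuple[float, float] = (2000.0, 2000.0)
    #: explicit (x, y, area_um2) vessel sections; None -> sampled below
    vessel_sections: np.ndarray | None = None
    n_vessels: int = 200
    #: lognormal (mu, sigma) of cross-section area, um^2
    area_dist: tuple[float, float] = (math.log(180.0), 1.0)
    area_threshold_um2: float = 250.0
    apoptosis_rate_small: float = 0.4
    apoptosis_rate_large: float = 0.05
    proliferation_rate_small: float = 0.15
    proliferation_rate_large: float = 0.04
    background_caspase_density_per_mm2: float = 50.0
    #: TECs per vessel ~ 1 + Poisson(mean - 1)
    mean_tecs_per_vessel: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "apoptosis_rate_small", "apoptosis_rate_large",
            "proliferation_rate_small", "proliferation_rate_large",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_caspase_density_per_mm2 < 0:
            raise ValueError("background density must be >= 0")
        if any(v <= 0 for v in self.section_extent_um):
            raise ValueError("section extent must be positive")

    @property
    def area_mm2(self) -> float:
        return self.section_extent_um[0] * self.section_extent_um[1] / 1e6


def generate_section_cells(spec: CellPlacementSpec) -> CellTable:
    """Generate a :class:`CellTable` for one section."""
    rng = np.random.default_rng(spec.seed)
    ex, ey = spec.section_extent_um

    if spec.vessel_sections is not None:
        vs = np.asarray(spec.vessel_sections, float)
        xy = vs[:, :2]
        areas = vs[:, 2]
    else:
        n = spec.n_vessels
        xy = rng.uniform([0, 0], [ex, ey], size=(n, 2))
        mu, sigma = spec.area_dist
        areas = rng.lognormal(mu, sigma, size=n)
    n = len(areas)
    small = areas < spec.area_threshold_um2

    vessels = pd.DataFrame(
        {"vessel_id": np.arange(n), "x_um": xy[:, 0], "y_um": xy[:, 1],
         "area_um2": areas}
    )

    cells = []
    cell_id = 0
    for i in range(n):
        n_tec = 1 + rng.poisson(max(0.0, spec.mean_tecs_per_vessel - 1.0))
        apo_rate = spec.apoptosis_rate_small if small[i] else spec.apoptosis_rate_large
        edu_rate = spec.proliferation_rate_small if small[i] else spec.proliferation_rate_large
        vessel_apoptotic = rng.random() < apo_rate
        # TEC positions scattered on the vessel perimeter
        r = math.sqrt(areas[i] / math.pi)
        ang = rng.uniform(0, 2 * math.pi, n_tec)
        tx = np.clip(xy[i, 0] + r * np.cos(ang), 0, ex)
        ty = np.clip(xy[i, 1] + r * np.sin(ang), 0, ey)
        casp = np.zeros(n_tec, bool)
        if vessel_apoptotic:
            casp[int(rng.integers(n_tec))] = True
        edu = rng.random(n_tec) < edu_rate
        for k in range(n_tec):
            cells.append(
                (cell_id, tx[k], ty[k], True, bool(casp[k]), bool(edu[k]), i)
            )
            cell_id += 1

    # homogeneous Poisson background of caspase+ non-TEC cells
    lam = spec.background_caspase_density_per_mm2 * spec.area_mm2
    n_bg = int(rng.poisson(lam))
    bx = rng.uniform(0, ex, n_bg)
    by = rng.uniform(0, ey, n_bg)
    for k in range(n_bg):
        cells.append((cell_id, bx[k], by[k], False, True, False, -1))
        cell_id += 1

    cell_df = pd.DataFrame(
        cells,
        columns=["cell_id", "x_um", "y_um", "is_tec", "caspase3_pos", "edu_pos", "vessel_id"],
    )
    return CellTable(cells=cell_df, vessels=vessels, section_extent_um=(ex, ey))
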