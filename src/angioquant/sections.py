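"""Scoring of 2D stained tumour sections.

Vessels observed in cross-section are stratified by area (the two-class
scheme splits at 250 um^2), endothelial apoptosis is scored as the
fraction of vessels per class containing at least one cleaved
caspase-3-positive endothelial cell, proliferation as the EdU-positive
fraction of endothelial cells per class, and the local density of
caspase-positive non-endothelial cells is estimated in a 100 um disc
around reference cells with analytic edge correction at the section
border.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, box

CELL_COLUMNS = ["cell_id", "x_um", "y_um", "is_tec", "caspase3_pos", "edu_pos", "vessel_id"]
VESSEL_COLUMNS = ["vessel_id", "x_um", "y_um", "area_um2"]


@dataclass
class CellTable:
    """Cells and vessel cross-sections of one 2D section.

    ``cells`` columns: cell_id, x_um, y_um, is_tec, caspase3_pos,
    edu_pos, vessel_id (-1 for cells not assigned to a vessel).
    ``vessels`` columns: vessel_id, x_um, y_um, area_um2.
    """

    cells: pd.DataFrame
    vessels: pd.DataFrame
    section_extent_um: tuple[float, float]

    def __post_init__(self) -> None:
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise ValueError(f"cells table missing column {col!r}")
        for col in VESSEL_COLUMNS:
            if col not in self.vessels.columns:
                raise ValueError(f"vessels table missing column {col!r}")

    def write_csv(self, cells_path, vessels_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.vessels.to_csv(vessels_path, index=False)

    @classmethod
    def read_csv(cls, cells_path, vessels_path, section_extent_um) -> "CellTable":
        return cls(pd.read_csv(cells_path), pd.read_csv(vessels_path),
                   tuple(section_extent_um))


@dataclass
class SizeClassScheme:
    """Vessel-size classes from strictly increasing area thresholds (um^2).

    Intervals are half-open ``[low, high)``: a vessel of exactly 250 um^2
    under the single-threshold scheme is "large".
    """

    boundaries_um2: tuple[float, ...] = (250.0,)

    def __post_init__(self) -> None:
        b = tuple(self.boundaries_um2)
        if not b or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing and non-empty")
        self.boundaries_um2 = b

    @property
    def labels(self) -> list[str]:
        n = len(self.boundaries_um2) + 1
        if n == 2:
            return ["small", "large"]
        if n == 3:
            return ["small", "medium", "large"]
        return [f"class_{i}" for i in range(n)]


def two_class_scheme(threshold_um2: float = 250.0) -> SizeClassScheme:
    return SizeClassScheme((threshold_um2,))


def three_class_scheme(lo: float = 250.0, hi: float = 1000.0) -> SizeClassScheme:
    return SizeClassScheme((lo, hi))


def partition_by_area(vessels: pd.DataFrame, scheme: SizeClassScheme) -> pd.Series:
    """Class label per vessel by half-open area intervals."""
    areas = vessels["area_um2"].to_numpy(float)
    idx = np.searchsorted(np.asarray(scheme.boundaries_um2), areas, side="right")
    labels = np.asarray(scheme.labels, dtype=object)
    return pd.Series(labels[idx], index=vessels.index, name="size_class")


def apoptotic_vessel_fraction(table: CellTable, scheme: SizeClassScheme) -> pd.Series:
    """Per size class, the fraction of vessels containing >= 1
    caspase-3-positive TEC.  Empty classes give NaN."""
    labels = partition_by_area(table.vessels, scheme)
    tec = table.cells[table.cells["is_tec"] & table.cells["caspase3_pos"]]
    apoptotic_vessels = set(tec["vessel_id"].to_numpy())
    has_apo = table.vessels["vessel_id"].isin(apoptotic_vessels)
    out = {}
    for cls in scheme.labels:
        in_cls = labels == cls
        out[cls] = float(has_apo[in_cls].mean()) if in_cls.any() else float("nan")
    return pd.Series(out, name="apoptotic_vessel_fraction")


def proliferating_tec_fraction(table: CellTable, scheme: SizeClassScheme) -> pd.Series:
    """Per size class, EdU-positive TEC count / total TEC count.
    Classes without TECs give NaN."""
    labels = partition_by_area(table.vessels, scheme)
    cls_by_vessel = dict(zip(table.vessels["vessel_id"], labels))
    tecs = table.cells[table.cells["is_tec"]].copy()
    tecs["size_class"] = tecs["vessel_id"].map(cls_by_vessel)
    out = {}
    for cls in scheme.labels:
        sub = tecs[tecs["size_class"] == cls]
        out[cls] = float(sub["edu_pos"].mean()) if len(sub) else float("nan")
    return pd.Series(out, name="proliferating_tec_fraction")


def _disc_section_area_mm2(x, y, radius, extent) -> float:
    """Area of the disc clipped to the section rectangle, mm^2."""
    disc = Point(x, y).buffer(radius, quad_segs=128)
    rect = box(0.0, 0.0, extent[0], extent[1])
    return disc.intersection(rect).area / 1e6


def local_caspase_density(
    table: CellTable,
    radius_um: float = 100.0,
    references: pd.DataFrame | None = None,
    use_negative_references: bool = False,
) -> pd.DataFrame:
    """Density (per mm^2) of caspase-3-positive non-TEC cells within
    ``radius_um`` of each reference cell.

    References default to caspase-positive TECs; a control run uses the
    caspase-negative TECs instead (``use_negative_references``).  The
    denominator is the disc area intersected with the section rectangle
    (edge correction).
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    cells = table.cells
    if references is None:
        is_tec = cells["is_tec"]
        if use_negative_references:
            references = cells[is_tec & ~cells["caspase3_pos"]]
        else:
            references = cells[is_tec & cells["caspase3_pos"]]
    if len(references) == 0:
        raise ValueError("reference set is empty")
    targets = cells[~cells["is_tec"] & cells["caspase3_pos"]]
    tpos = targets[["x_um", "y_um"]].to_numpy(float)
    rpos = references[["x_um", "y_um"]].to_numpy(float)
    if len(tpos):
        tree = cKDTree(tpos)
        counts = np.array(tree.query_ball_point(rpos, radius_um, return_length=True))
    else:
        counts = np.zeros(len(rpos), dtype=int)
    areas = np.array(
        [_disc_section_area_mm2(x, y, radius_um, table.section_extent_um) for x, y in rpos]
    )
    return pd.DataFrame(
        {
            "reference_cell_id": references["cell_id"].to_numpy(),
            "count": counts,
            "area_mm2": areas,
            "density_per_mm2": counts / areas,
        }
    )


def summarize_sections(table: CellTable, scheme: SizeClassScheme | None = None,
                       radius_um: float = 100.0) -> dict:
    """Bundle the per-class apoptosis / proliferation fractions and the
    local caspase-density summary for one section."""
    scheme = scheme or two_class_scheme()
    apo = apoptotic_vessel_fraction(table, scheme)
    prolif = proliferating_tec_fraction(table, scheme)
    out = {
        "apoptotic_vessel_fraction": apo.to_dict(),
        "proliferating_tec_fraction": prolif.to_dict(),
        "n_vessels": int(len(table.vessels)),
        "n_cells": int(len(table.cells)),
    }
    refs = table.cells[table.cells["is_tec"] & table.cells["caspase3_pos"]]
    if len(refs):
        dens = local_caspase_density(table, radius_um)
        out["local_caspase_density_mean_per_mm2"] = float(dens["density_per_mm2"].mean())
    else:
        out["local_caspase_density_mean_per_mm2"] = float("nan")
    return out
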