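import math

import numpy as np
import pandas as pd
import pytest

from angioquant.sections import (
    CellTable,
    SizeClassScheme,
    apoptotic_vessel_fraction,
    local_caspase_density,
    partition_by_area,
    proliferating_tec_fraction,
    three_class_scheme,
    two_class_scheme,
)
from angioquant.synth.cells import CellPlacementSpec, generate_section_cells


def make_table(cells_rows, vessels_rows, extent=(2000.0, 2000.0)):
    cells = pd.DataFrame(
        cells_rows,
        columns=["cell_id", "x_um", "y_um", "is_tec", "caspase3_pos", "edu_pos", "vessel_id"],
    )
    vessels = pd.DataFrame(vessels_rows, columns=["vessel_id", "x_um", "y_um", "area_um2"])
    return CellTable(cells=cells, vessels=vessels, section_extent_um=extent)


class TestPartition:
    def test_two_class_split(self):
        t = make_table([], [(0, 1, 1, 100.0), (1, 1, 1, 300.0)])
        labels = partition_by_area(t.vessels, two_class_scheme())
        assert labels.tolist() == ["small", "large"]

    def test_boundary_value_is_large(self):
        t = make_table([], [(0, 1, 1, 250.0)])
        assert partition_by_area(t.vessels, two_class_scheme()).tolist() == ["large"]

    def test_three_class(self):
        t = make_table([], [(0, 1, 1, 100.0), (1, 1, 1, 500.0), (2, 1, 1, 5000.0)])
        labels = partition_by_area(t.vessels, three_class_scheme(250, 1000))
        assert labels.tolist() == ["small", "medium", "large"]

    def test_partition_is_exhaustive(self):
        rngareas = np.random.default_rng(0).uniform(10, 5000, 200)
        t = make_table([], [(i, 0, 0, a) for i, a in enumerate(rngareas)])
        labels = partition_by_area(t.vessels, three_class_scheme())
        assert labels.value_counts().sum() == 200

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            SizeClassScheme((1000.0, 250.0))


class TestApoptosisFraction:
    def test_no_caspase_gives_zero(self):
        t = make_table(
            [(0, 1, 1, True, False, False, 0)],
            [(0, 1, 1, 100.0), (1, 1, 1, 500.0)],
        )
        out = apoptotic_vessel_fraction(t, two_class_scheme())
        assert out["small"] == 0.0 and out["large"] == 0.0

    def test_forced_fraction(self):
        vessels = [(i, 1, 1, 100.0) for i in range(10)]
        cells = [(i, 1, 1, True, i < 4, False, i) for i in range(10)]
        t = make_table(cells, vessels)
        out = apoptotic_vessel_fraction(t, two_class_scheme())
        assert out["small"] == pytest.approx(0.4)
        assert math.isnan(out["large"])  # empty class


class TestProliferation:
    def test_forced_fractions(self):
        vessels = [(0, 1, 1, 100.0), (1, 1, 1, 500.0)]
        cells = [(i, 1, 1, True, False, i < 3, 0) for i in range(10)]
        cells += [(100 + i, 1, 1, True, False, i < 1, 1) for i in range(20)]
        t = make_table(cells, vessels)
        out = proliferating_tec_fraction(t, two_class_scheme())
        assert out["small"] == pytest.approx(0.3)
        assert out["large"] == pytest.approx(0.05)


class TestLocalDensity:
    def test_interior_reference_arithmetic(self):
        # 3 cells within 100 um of an interior reference
        cells = [
            (0, 1000.0, 1000.0, True, True, False, 0),
            (1, 1050.0, 1000.0, False, True, False, -1),
            (2, 1000.0, 1080.0, False, True, False, -1),
            (3, 990.0, 995.0, False, True, False, -1),
            (4, 1500.0, 1500.0, False, True, False, -1),  # outside radius
        ]
        t = make_table(cells, [(0, 1000.0, 1000.0, 100.0)])
        out = local_caspase_density(t, radius_um=100.0)
        assert out["count"].iloc[0] == 3
        assert out["density_per_mm2"].iloc[0] == pytest.approx(3 / (math.pi * 0.01), rel=1e-3)

    def test_corner_reference_quarter_area(self):
        cells = [
            (0, 0.0, 0.0, True, True, False, 0),
            (1, 30.0, 40.0, False, True, False, -1),
        ]
        t = make_table(cells, [(0, 0.0, 0.0, 100.0)])
        out = local_caspase_density(t, radius_um=100.0)
        assert out["area_mm2"].iloc[0] == pytest.approx(math.pi * 0.01 / 4, rel=1e-3)
        assert out["density_per_mm2"].iloc[0] == pytest.approx(
            1 / (math.pi * 0.01 / 4), rel=1e-3)

    def test_invalid_radius(self):
        t = make_table([(0, 1, 1, True, True, False, 0)], [(0, 1, 1, 100.0)])
        with pytest.raises(ValueError):
            local_caspase_density(t, radius_um=0)

    def test_unbiased_on_homogeneous_poisson(self, rng):
        ext = (3000.0, 3000.0)
        n = rng.poisson(100.0 * 9.0)
        cells = pd.DataFrame({
            "cell_id": np.arange(n),
            "x_um": rng.uniform(0, ext[0], n),
            "y_um": rng.uniform(0, ext[1], n),
            "is_tec": False, "caspase3_pos": True, "edu_pos": False, "vessel_id": -1,
        })
        nref = 4000
        refs = pd.DataFrame({
            "cell_id": np.arange(10**6, 10**6 + nref),
            "x_um": rng.uniform(0, ext[0], nref),
            "y_um": rng.uniform(0, ext[1], nref),
        })
        vessels = pd.DataFrame({"vessel_id": [0], "x_um": [1.0], "y_um": [1.0],
                                "area_um2": [100.0]})
        t = CellTable(cells=cells, vessels=vessels, section_extent_um=ext)
        out = local_caspase_density(t, 100.0, references=refs)
        realized = n / 9.0
        rel_bias = abs(out["density_per_mm2"].mean() - realized) / realized
        assert rel_bias < 0.02


class TestGenerator:
    def test_zero_rates_give_no_caspase(self):
        spec = CellPlacementSpec(
            apoptosis_rate_small=0.0, apoptosis_rate_large=0.0,
            background_caspase_density_per_mm2=0.0, seed=1)
        t = generate_section_cells(spec)
        assert not t.cells["caspase3_pos"].any()

    def test_background_poisson_count(self):
        spec = CellPlacementSpec(
            n_vessels=0, vessel_sections=np.zeros((0, 3)),
            background_caspase_density_per_mm2=100.0, seed=2)
        t = generate_section_cells(spec)  # 2 x 2 mm -> expect 400
        n = len(t.cells)
        assert abs(n - 400) < 4 * math.sqrt(400)

    def test_small_vessels_more_apoptotic(self):
        """Enrichment of apoptosis on small vessels survives scoring."""
        rng = np.random.default_rng(3)
        areas = np.concatenate([rng.uniform(50, 240, 500), rng.uniform(260, 2000, 500)])
        vs = np.column_stack([rng.uniform(0, 2000, (1000, 2)), areas])
        spec = CellPlacementSpec(vessel_sections=vs, apoptosis_rate_small=0.4,
                                 apoptosis_rate_large=0.05, seed=3)
        t = generate_section_cells(spec)
        out = apoptotic_vessel_fraction(t, two_class_scheme())
        assert out["small"] > out["large"]

    def test_csv_roundtrip(self, tmp_path):
        spec = CellPlacementSpec(n_vessels=50, seed=4)
        t = generate_section_cells(spec)
        t.write_csv(tmp_path / "c.csv", tmp_path / "v.csv")
        t2 = CellTable.read_csv(tmp_path / "c.csv", tmp_path / "v.csv", t.section_extent_um)
        out1 = apoptotic_vessel_fraction(t, two_class_scheme())
        out2 = apoptotic_vessel_fraction(t2, two_class_scheme())
        pd.testing.assert_series_equal(out1, out2)
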