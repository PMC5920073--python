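import math

import numpy as np
import pandas as pd
import pytest

from ld3d.morphometrics import (cell_records, cell_spacing, droplet_records,
                                field_summary, field_volume_um3, size_distribution)
from ld3d.pipeline import quantify_field
from ld3d.segment_cells import CellAssignment
from ld3d.stack_io import Calibration, DEFAULT_CALIBRATION, LabelVolume
from ld3d.synthetic import voxelized_ball
from oracles import sphere_voxel_count


def _single_voxel_droplet(cal):
    lab = np.zeros((3, 3, 3), int)
    lab[1, 1, 1] = 1
    return LabelVolume(lab, cal, kind="droplet")


class TestDropletRecords:
    def test_single_voxel_volume_at_default_pitch(self):
        lv = _single_voxel_droplet(DEFAULT_CALIBRATION)
        rec = droplet_records(lv, CellAssignment({1: 2}, set()))
        assert rec.loc[0, "volume_um3"] == pytest.approx(9.607e-3, abs=1e-6)
        assert rec.loc[0, "cell_id"] == 2
        assert not rec.loc[0, "touches_border"]

    def test_equivalent_diameter_boundary_at_large_threshold(self):
        # one voxel of the exact 5-um-sphere volume (pi/6 * 125 = 65.45 um^3)
        # has eq. diameter 5.00 um: NOT "large" under the strict > threshold
        v5 = math.pi / 6 * 125 * (1 - 1e-9)
        lv = _single_voxel_droplet(Calibration(v5, 1.0, 1.0))
        rec = droplet_records(lv, CellAssignment({}, {1}))
        assert rec.loc[0, "volume_um3"] == pytest.approx(65.45, abs=1e-2)
        assert rec.loc[0, "eq_diameter_um"] == pytest.approx(5.000, abs=1e-3)
        assert not rec.loc[0, "is_large"]
        # just above the boundary the flag flips
        lv2 = _single_voxel_droplet(Calibration(v5 * 1.001, 1.0, 1.0))
        assert droplet_records(lv2, CellAssignment({}, {1})).loc[0, "is_large"]

    def test_small_class_boundary_is_strict(self):
        # exactly 100 um^3 -> eq. diameter (600/pi)^(1/3) = 5.759 um, not small-class
        lv = _single_voxel_droplet(Calibration(100.0, 1.0, 1.0))
        rec = droplet_records(lv, CellAssignment({}, {1}))
        assert rec.loc[0, "eq_diameter_um"] == pytest.approx(5.7588, abs=1e-3)
        assert not rec.loc[0, "is_small_class"]
        assert rec.loc[0, "is_large"]

    def test_digitized_sphere_diameter_converges(self, unit_cal):
        errors = []
        for r in (3, 5, 8, 11, 15):
            n = 2 * r + 5
            lab = np.zeros((n, n, n), int)
            lab[voxelized_ball((n, n, n), (n / 2,) * 3, float(r), unit_cal)] = 1
            rec = droplet_records(LabelVolume(lab, unit_cal), CellAssignment({}, {1}))
            errors.append(abs(rec.loc[0, "eq_diameter_um"] - 2 * r) / (2 * r))
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.01

    def test_sphere_voxel_count_matches_enumeration_oracle(self, unit_cal):
        shape = (15, 15, 15)
        idx = voxelized_ball(shape, (7.5, 7.5, 7.5), 5.0, unit_cal)
        oracle = sphere_voxel_count(5.0)
        assert len(idx[0]) == oracle
        assert len(idx[0]) == pytest.approx(4 / 3 * math.pi * 125, rel=0.05)


class TestCellRecords:
    def test_ratio_is_voxel_fraction(self, unit_cal):
        cells = np.zeros((10, 40, 40), int)
        cells[:, 5:30, :16] = 1  # 10*25*16 = 4000... use explicit count below
        cells = np.zeros((10, 100, 10), int)
        cells[:] = 1  # 10,000 voxels
        drops = np.zeros((10, 100, 10), int)
        drops.ravel()[:1500] = 1  # 1500 voxels inside cell 1
        records = droplet_records(LabelVolume(drops, unit_cal),
                                  CellAssignment({1: 1}, set()))
        out = cell_records(LabelVolume(cells, unit_cal, kind="cell"), records,
                           integrated=set())
        assert out.loc[0, "vld_vsc_ratio"] == pytest.approx(0.15)
        assert out.loc[0, "tnld"] == 1

    def test_cell_without_droplets(self, unit_cal):
        cells = np.ones((2, 2, 2), int)
        out = cell_records(LabelVolume(cells, unit_cal, kind="cell"),
                           pd.DataFrame(columns=["cell_id", "volume_um3", "is_large"]))
        assert out.loc[0, "vld_um3"] == 0.0
        assert out.loc[0, "vld_vsc_ratio"] == 0.0
        assert out.loc[0, "tnld"] == 0

    def test_unknown_cell_assignment_rejected(self, unit_cal):
        cells = np.ones((2, 2, 2), int)
        records = pd.DataFrame({"cell_id": [7], "volume_um3": [1.0], "is_large": [False]})
        with pytest.raises(ValueError, match="nonexistent"):
            cell_records(LabelVolume(cells, unit_cal, kind="cell"), records)

    def test_truth_recovery_on_clean_field(self, tiny_field_clean):
        fluor, _, truth = tiny_field_clean
        res = quantify_field(fluor, cells=truth.cell_labels)
        true_tnld = truth.droplet_truth.groupby("cell_id").size()
        for _, row in res.cells.iterrows():
            assert row["tnld"] == true_tnld.get(row["cell_id"], 0)
            true_vld = truth.droplet_truth.query("cell_id == @row.cell_id")["volume_um3"].sum()
            assert abs(row["vld_um3"] - true_vld) / row["vsc_um3"] < 0.01


class TestFieldSummary:
    def test_scanning_field_volume_at_acquisition_scale(self):
        # 800 x 800 x 70 voxels at the default pitch
        assert field_volume_um3((70, 800, 800), DEFAULT_CALIBRATION) == \
            pytest.approx(4.304e5, rel=1e-3)

    def test_empty_and_full_droplet_ratios(self, unit_cal):
        cells = LabelVolume(np.ones((3, 4, 4), int), unit_cal, kind="cell")
        empty = LabelVolume(np.zeros((3, 4, 4), int), unit_cal)
        full = LabelVolume(np.ones((3, 4, 4), int), unit_cal)
        assert field_summary(empty, cells, spacing=(float("nan"), pd.DataFrame()))[
            "vtld_vtsf_ratio"] == 0.0
        assert field_summary(full, cells, spacing=(float("nan"), pd.DataFrame()))[
            "vtld_vtsf_ratio"] == 1.0

    def test_vtld_conservation_and_ratio_bounds(self, tiny_field):
        fluor, _, truth = tiny_field
        res = quantify_field(fluor, cells=truth.cell_labels)
        assigned = res.droplets[res.droplets["cell_id"] > 0]["volume_um3"].sum()
        unassigned = res.droplets[res.droplets["cell_id"] == 0]["volume_um3"].sum()
        assert assigned + unassigned == pytest.approx(res.summary["vtld_um3"], rel=1e-12)
        assert res.cells["vld_um3"].sum() == pytest.approx(assigned, rel=1e-12)
        assert ((res.cells["vld_vsc_ratio"] >= 0) & (res.cells["vld_vsc_ratio"] <= 1)).all()

    def test_volumes_scale_linearly_in_dz(self, tiny_field_clean):
        fluor, _, truth = tiny_field_clean
        res = quantify_field(fluor, cells=truth.cell_labels)
        cal = fluor.calibration
        cal2 = Calibration(cal.dx_um, cal.dy_um, 2 * cal.dz_um)
        fluor2 = type(fluor)(fluor.voxels, cal2, fluor.channel)
        cells2 = LabelVolume(truth.cell_labels.labels, cal2, kind="cell")
        res2 = quantify_field(fluor2, cells=cells2)
        assert res2.summary["vtsf_um3"] == pytest.approx(2 * res.summary["vtsf_um3"])
        assert res2.summary["vtld_um3"] == pytest.approx(2 * res.summary["vtld_um3"])
        assert res2.summary["vtld_vtsf_ratio"] == pytest.approx(
            res.summary["vtld_vtsf_ratio"], rel=1e-12)
        np.testing.assert_allclose(res2.droplets["volume_um3"],
                                   2 * res.droplets["volume_um3"])


class TestCellSpacing:
    def test_two_slabs_with_five_voxel_gap(self, unit_cal):
        lab = np.zeros((3, 5, 20), int)
        lab[:, :, :5] = 1
        lab[:, :, 10:15] = 2
        mean, pairs = cell_spacing(LabelVolume(lab, unit_cal, kind="cell"))
        assert pairs.loc[0, "min_distance_um"] == pytest.approx(6.0)
        assert pairs.loc[0, "spacing_um"] == pytest.approx(5.0)
        assert mean == pytest.approx(5.0)

    def test_generator_wall_width_round_trip(self, tiny_field):
        _, _, truth = tiny_field
        mean, pairs = cell_spacing(truth.cell_labels)
        assert len(pairs) >= 1
        assert mean == pytest.approx(4.0, rel=0.20)  # wall_um of the generating spec

    def test_isolated_cell_contributes_no_pairs(self, unit_cal):
        lab = np.zeros((3, 5, 60), int)
        lab[:, :, :3] = 1
        lab[:, :, 5:8] = 2
        lab[:, :, 50:] = 3  # far beyond max_gap_um of the others
        _, pairs = cell_spacing(LabelVolume(lab, unit_cal, kind="cell"), max_gap_um=15.0)
        assert set(map(tuple, pairs[["cell_i", "cell_j"]].values)) == {(1, 2)}

    def test_fewer_than_two_cells_is_missing(self, unit_cal):
        lab = np.ones((2, 2, 2), int)
        with pytest.warns(UserWarning):
            mean, pairs = cell_spacing(LabelVolume(lab, unit_cal, kind="cell"))
        assert math.isnan(mean) and len(pairs) == 0


class TestSizeDistribution:
    def _records(self, volumes):
        return pd.DataFrame({
            "cell_id": [1] * len(volumes),
            "volume_um3": volumes,
            "is_large": [(6 * v / math.pi) ** (1 / 3) > 5.0 for v in volumes],
            "is_small_class": [v < 100.0 for v in volumes],
        })

    def test_counts_and_small_class_percentage(self):
        out = size_distribution(self._records([1.0, 2.0, 150.0]), [0, 100, 200])
        np.testing.assert_array_equal(out["counts"], [2, 1])
        assert out["small_class_pct"] == pytest.approx(100 * 2 / 3, abs=0.05)

    def test_all_small(self):
        out = size_distribution(self._records([1.0, 5.0]), [0, 100])
        assert out["small_class_pct"] == 100.0

    def test_empty_records_are_valid(self):
        out = size_distribution(pd.DataFrame(columns=["cell_id", "volume_um3",
                                                      "is_large", "is_small_class"]),
                                [0, 100])
        assert out["counts"].sum() == 0 and len(out["long"]) == 0

    def test_nonmonotone_edges_rejected(self):
        with pytest.raises(ValueError):
            size_distribution(self._records([1.0]), [10, 5])

    def test_large_count_recovered_from_truth(self, tiny_field_clean):
        fluor, _, truth = tiny_field_clean
        res = quantify_field(fluor, cells=truth.cell_labels)
        out = size_distribution(res.droplets, [0, 100, 1000])
        true_large = (truth.droplet_truth["eq_diameter_um"] > 5.0).sum()
        measured_large = res.droplets["is_large"].sum()
        assert abs(int(measured_large) - int(true_large)) <= 1
        assert out["long"].shape[0] == len(res.droplets)
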