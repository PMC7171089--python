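import numpy as np
import pandas as pd
import pytest

from devbrainmap import io, phantom, quantify


@pytest.fixture()
def toy_labels():
    """4x4x4 grid, spacing 20x20x50: region 7 occupies x<2, region 8 the rest of y<2."""
    arr = np.zeros((4, 4, 4), dtype=np.int32)
    arr[:2, :, :] = 7
    arr[2:, :2, :] = 8
    onto = io.Ontology.from_records(
        [
            {"id": 1, "acronym": "root", "name": "root", "parent_id": None},
            {"id": 7, "acronym": "A", "name": "left block", "parent_id": 1},
            {"id": 8, "acronym": "B", "name": "right block", "parent_id": 1},
        ]
    )
    return io.LabelVolume(io.Volume(arr, (20.0, 20.0, 50.0)), onto)


class TestAssignCells:
    def test_voxel_center_assignment(self, toy_labels):
        cells = io.make_cell_table([10.0], [10.0], [25.0], [0])  # center of voxel (0,0,0)
        out = quantify.assign_cells(cells, toy_labels)
        assert out["region_id"].tolist() == [7]

    def test_boundary_goes_to_higher_voxel(self, toy_labels):
        # x = 40 um is exactly the plane between voxel 1 (region 7) and voxel 2
        cells = io.make_cell_table([40.0], [10.0], [25.0], [0])
        out = quantify.assign_cells(cells, toy_labels)
        assert out["region_id"].tolist() == [8]

    def test_out_of_domain_flagged_and_kept(self, toy_labels):
        cells = io.make_cell_table([-5.0, 10.0], [10.0, 10.0], [25.0, 25.0], [0, 0])
        out = quantify.assign_cells(cells, toy_labels)
        assert out["out_of_domain"].tolist() == [True, False]
        assert len(out) == 2

    def test_background_flagged(self, toy_labels):
        cells = io.make_cell_table([70.0], [70.0], [25.0], [0])  # unlabeled corner
        out = quantify.assign_cells(cells, toy_labels)
        assert out["background"].tolist() == [True]

    def test_phantom_cells_recover_generating_region(self, stock_base):
        _, labels = stock_base
        spec = phantom.default_spec(seed=21)
        cells = phantom.simulate_cells(labels, spec, seed=22)
        out = quantify.assign_cells(cells, labels)
        idx = labels.volume.point_to_voxel(cells[["x_um", "y_um", "z_um"]].to_numpy())
        truth = labels.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert (out["region_id"].to_numpy() == truth).all()
        assert not out["out_of_domain"].any()


class TestRegionStats:
    def test_conversion_factor(self, toy_labels):
        rng = np.random.default_rng(0)
        n = 1000
        # all cells in region 7 (x < 40 um)
        cells = io.make_cell_table(
            rng.uniform(0, 39.99, n), rng.uniform(0, 79.99, n), rng.uniform(0, 199.9, n),
            np.zeros(n, dtype=int),
        )
        stats = quantify.region_stats(quantify.assign_cells(cells, toy_labels), toy_labels)
        row = stats.set_index("region_id").loc[7]
        assert row["n2d"] == 1000
        assert row["n3d"] == pytest.approx(1400.0)

    def test_voxel_volume_arithmetic(self):
        # 50,000 voxels at 20 x 20 x 50 um -> exactly 1 mm^3
        arr = np.ones((50, 50, 20), dtype=np.int32)
        lv = io.LabelVolume(io.Volume(arr, (20.0, 20.0, 50.0)))
        stats = quantify.region_stats(
            quantify.assign_cells(io.make_cell_table([], [], [], []), lv), lv
        )
        assert stats.set_index("region_id").loc[1, "volume_mm3"] == pytest.approx(1.0)

    def test_zero_count_region_has_zero_density(self, toy_labels):
        stats = quantify.region_stats(
            quantify.assign_cells(io.make_cell_table([], [], [], []), toy_labels), toy_labels
        )
        assert (stats["density_mm3"] == 0).all()
        assert set(stats["region_id"]) == {7, 8}

    def test_density_times_volume_is_n3d(self, stock_base):
        _, labels = stock_base
        spec = phantom.default_spec(seed=31)
        cells = phantom.simulate_cells(labels, spec, seed=32)
        stats = quantify.region_stats(quantify.assign_cells(cells, labels), labels)
        np.testing.assert_allclose(
            stats["density_mm3"] * stats["volume_mm3"], stats["n3d"], rtol=1e-12
        )

    def test_metadata_columns_attached(self, toy_labels):
        stats = quantify.region_stats(
            quantify.assign_cells(io.make_cell_table([], [], [], []), toy_labels),
            toy_labels, age="P14", sex="F",
        )
        assert (stats["age"] == "P14").all() and (stats["sex"] == "F").all()


class TestAggregate:
    def _stats(self, toy_labels, n7=10, n8=20):
        rng = np.random.default_rng(1)
        xs = np.concatenate([rng.uniform(0, 39.9, n7), rng.uniform(40, 79.9, n8)])
        ys = np.concatenate([rng.uniform(0, 79.9, n7), rng.uniform(0, 39.9, n8)])
        zs = rng.uniform(0, 199.9, n7 + n8)
        cells = io.make_cell_table(xs, ys, zs, np.zeros(n7 + n8, dtype=int))
        return quantify.region_stats(quantify.assign_cells(cells, toy_labels), toy_labels)

    def test_parent_density_from_summed_quantities(self):
        # hand oracle: children n3d 140 and 280, volumes 0.1 and 0.2 mm^3
        onto = io.Ontology.from_records(
            [
                {"id": 1, "acronym": "p", "name": "p", "parent_id": None},
                {"id": 2, "acronym": "c1", "name": "c1", "parent_id": 1},
                {"id": 3, "acronym": "c2", "name": "c2", "parent_id": 1},
            ]
        )
        stats = pd.DataFrame(
            {
                "region_id": [2, 3],
                "acronym": ["c1", "c2"],
                "name": ["c1", "c2"],
                "n2d": [100, 200],
                "n3d": [140.0, 280.0],
                "voxel_count": [5000, 10000],
                "volume_mm3": [0.1, 0.2],
                "density_mm3": [1400.0, 1400.0],
            }
        )
        agg = quantify.aggregate(stats, onto).set_index("region_id")
        assert agg.loc[1, "density_mm3"] == pytest.approx(420.0 / 0.3)
        assert agg.loc[1, "n3d"] == pytest.approx(420.0)

    def test_root_conserves_total_cells(self, toy_labels):
        stats = self._stats(toy_labels)
        agg = quantify.aggregate(stats, toy_labels.ontology).set_index("region_id")
        assert agg.loc[1, "n3d"] == pytest.approx(1.4 * 30)

    def test_idempotent(self, toy_labels):
        stats = self._stats(toy_labels)
        agg1 = quantify.aggregate(stats, toy_labels.ontology)
        agg2 = quantify.aggregate(agg1, toy_labels.ontology)
        pd.testing.assert_frame_equal(
            agg1.reset_index(drop=True), agg2.reset_index(drop=True)
        )

    def test_order_independent(self, toy_labels):
        stats = self._stats(toy_labels)
        shuffled = stats.sample(frac=1.0, random_state=3)
        agg1 = quantify.aggregate(stats, toy_labels.ontology)
        agg2 = quantify.aggregate(shuffled, toy_labels.ontology)
        pd.testing.assert_frame_equal(agg1, agg2)

    def test_unknown_region_rejected(self, toy_labels):
        stats = self._stats(toy_labels)
        stats.loc[0, "region_id"] = 4242
        with pytest.raises(KeyError, match="absent"):
            quantify.aggregate(stats, toy_labels.ontology)


class TestConservation:
    def test_every_cell_accounted_for(self, toy_labels):
        rng = np.random.default_rng(5)
        n = 200
        cells = io.make_cell_table(
            rng.uniform(-20, 100, n), rng.uniform(-20, 100, n), rng.uniform(-50, 250, n),
            np.zeros(n, dtype=int),
        )
        assigned = quantify.assign_cells(cells, toy_labels)
        report = quantify.conservation_report(assigned)
        stats = quantify.region_stats(assigned, toy_labels)
        assert (
            stats["n2d"].sum() + report["background"] + report["out_of_domain"]
            == report["total"]
            == n
        )
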