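import numpy as np
import pandas as pd
import pytest

from devbrainmap import flatmap, io, phantom, quantify
from devbrainmap import registration as reg


@pytest.fixture(scope="module")
def cortex_bins(stock_base):
    _, labels = stock_base
    return flatmap.shell_bins(labels, set(phantom.LAYER_IDS.values()), n_theta=6, n_phi=4)


@pytest.fixture(scope="module")
def uniform_cells(stock_base):
    """Cells at a uniform density in every cortical layer, 2D-thinned."""
    _, labels = stock_base
    dens = {rid: 4000.0 for rid in phantom.LAYER_IDS.values()}
    spec = phantom.default_spec(densities=dens, dispersion=np.inf, seed=17)
    cells3d = phantom.simulate_cells(labels, spec, seed=18)
    return phantom.thin_cells(cells3d, seed=19)


class TestLayerParsing:
    @pytest.mark.parametrize(
        "acronym,layer",
        [("ISO1", 1), ("ISO4", 4), ("SSp2/3", 2), ("VISp6a", 6), ("MOs6b", 6), ("PVH", None)],
    )
    def test_layer_of(self, acronym, layer):
        assert flatmap.layer_of(acronym) == layer


class TestLayerRestrict:
    def test_set_algebra(self, cortex_bins, stock_base):
        _, labels = stock_base
        full = cortex_bins.bin_volume.data
        sup = flatmap.layer_restrict(cortex_bins, labels, "superficial").bin_volume.data
        deep = flatmap.layer_restrict(cortex_bins, labels, "deep").bin_volume.data
        assert ((sup > 0) & (deep > 0)).sum() == 0  # disjoint
        assert (((sup > 0) | (deep > 0)) <= (full > 0)).all()  # subset of full
        # layer 4 voxels belong to neither restricted map
        l4 = labels.data == phantom.LAYER_IDS[4]
        assert (sup[l4] == 0).all() and (deep[l4] == 0).all()

    def test_counts_match_brute_force_mask(self, cortex_bins, stock_base):
        _, labels = stock_base
        sup = flatmap.layer_restrict(cortex_bins, labels, "superficial")
        sup_ids = [phantom.LAYER_IDS[k] for k in (1, 2, 3)]
        mask = np.isin(labels.data, sup_ids)
        brute = {
            b: int(((cortex_bins.bin_volume.data == b) & mask).sum())
            for b in range(1, cortex_bins.n_bins + 1)
        }
        got = sup.voxel_counts()
        assert {b: got.loc[b] for b in brute} == brute

    def test_missing_layers_give_empty_bins(self, cortex_bins, stock_base):
        _, labels = stock_base
        # erase the superficial layers from the label image
        data = labels.data.copy()
        for k in (1, 2, 3):
            data[data == phantom.LAYER_IDS[k]] = 0
        stripped = io.LabelVolume(labels.volume.with_data(data), labels.ontology)
        sup = flatmap.layer_restrict(cortex_bins, stripped, "superficial")
        assert (sup.bin_volume.data == 0).all()

    def test_unknown_which_rejected(self, cortex_bins, stock_base):
        _, labels = stock_base
        with pytest.raises(ValueError, match="superficial"):
            flatmap.layer_restrict(cortex_bins, labels, "middle")


class TestBinDensities:
    def test_identity_transform_keeps_reference_volumes(self, cortex_bins, uniform_cells):
        ident = reg.identity_transform(cortex_bins.bin_volume.volume)
        table = flatmap.bin_densities(uniform_cells, cortex_bins, ident)
        vox = cortex_bins.voxel_counts()
        vv = np.prod(cortex_bins.bin_volume.spacing) * 1e-9
        for _, row in table.iterrows():
            assert row["volume_mm3"] == pytest.approx(vox.loc[row["bin_id"]] * vv)

    def test_count_conservation(self, cortex_bins, uniform_cells):
        ident = reg.identity_transform(cortex_bins.bin_volume.volume)
        table = flatmap.bin_densities(uniform_cells, cortex_bins, ident)
        vol = cortex_bins.bin_volume
        idx = vol.volume.point_to_voxel(uniform_cells[["x_um", "y_um", "z_um"]].to_numpy())
        in_bin = vol.data[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
        assert table["n2d"].sum() == int(in_bin.sum())

    def test_uniform_field_is_flat(self, cortex_bins, uniform_cells):
        ident = reg.identity_transform(cortex_bins.bin_volume.volume)
        table = flatmap.bin_densities(uniform_cells, cortex_bins, ident)
        k3d = quantify.QuantConfig().k3d
        d = 4000.0
        for _, row in table.iterrows():
            if row["volume_mm3"] <= 0:
                continue
            lam2d = d * row["volume_mm3"] / k3d  # expected thinned count
            sd = np.sqrt(lam2d)
            assert abs(row["n2d"] - lam2d) < 5 * sd + 1

    def test_missing_transform_rejected(self, cortex_bins, uniform_cells):
        with pytest.raises(ValueError, match="age_transform"):
            flatmap.bin_densities(uniform_cells, cortex_bins, None)

    def test_layer_volume_additivity(self, cortex_bins, stock_base):
        _, labels = stock_base
        full = cortex_bins.voxel_counts()
        sup = flatmap.layer_restrict(cortex_bins, labels, "superficial").voxel_counts()
        deep = flatmap.layer_restrict(cortex_bins, labels, "deep").voxel_counts()
        unassigned_ids = [phantom.LAYER_IDS[4]]
        unassigned = np.isin(labels.data, unassigned_ids) & (cortex_bins.bin_volume.data > 0)
        assert full.sum() == sup.sum() + deep.sum() + int(unassigned.sum())


class TestRender:
    def test_constant_densities_give_constant_map(self, cortex_bins):
        table = cortex_bins.positions.copy()
        table["n2d"] = 10
        table["n3d"] = 14.0
        table["volume_mm3"] = 0.01
        table["density_mm3"] = 1400.0
        grid = flatmap.render_flatmap(table, cortex_bins)
        vals = grid[~np.isnan(grid)]
        assert len(np.unique(vals)) == 1

    def test_empty_bins_are_missing_not_zero(self, cortex_bins):
        table = cortex_bins.positions.copy()
        table["n2d"] = 0
        table["n3d"] = 0.0
        table["volume_mm3"] = 0.0
        table["density_mm3"] = np.nan
        grid = flatmap.render_flatmap(table, cortex_bins)
        assert np.isnan(grid[0, 0])

    def test_rendering_is_byte_deterministic(self, cortex_bins, uniform_cells, tmp_path):
        ident = reg.identity_transform(cortex_bins.bin_volume.volume)
        table = flatmap.bin_densities(uniform_cells, cortex_bins, ident)
        flatmap.render_flatmap(table, cortex_bins, path=tmp_path / "a.png")
        flatmap.render_flatmap(table, cortex_bins, path=tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()


class TestBinsContainer:
    def test_noncontiguous_ids_rejected(self, stock_base):
        _, labels = stock_base
        pos = pd.DataFrame({"bin_id": [1, 3], "grid_x": [0, 1], "grid_y": [0, 0]})
        bv = io.LabelVolume(labels.volume.with_data(np.zeros(labels.shape, dtype=np.int32)))
        with pytest.raises(ValueError, match="contiguous"):
            flatmap.FlatmapBins(bv, pos)

    def test_every_binned_voxel_is_cortical(self, cortex_bins, stock_base):
        _, labels = stock_base
        binned = cortex_bins.bin_volume.data > 0
        cortical = np.isin(labels.data, list(phantom.LAYER_IDS.values()))
        assert (binned <= cortical).all()
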