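import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condquant.droplets import (
    FieldQuant,
    MaskParams,
    concentration_sweep,
    droplet_stats,
    field_quant,
    field_quant_two_channel,
    make_droplet_mask,
    subtract_dark_frame,
)
from condquant.exceptions import CondquantError, DimensionError
from condquant.io import Image2D
from condquant.simulate import DropletFieldSpec, gen_droplet_field


class TestDarkSubtraction:
    def test_constant_offset(self):
        img = Image2D(np.full((8, 8), 100.0))
        dark = Image2D(np.full((8, 8), 10.0))
        out = subtract_dark_frame(img, dark)
        assert (out.pixels == 90.0).all()

    def test_scalar_mean_and_clamp(self):
        # dark mean 12.5 subtracted from {20, 10} clamps the 10 to 0
        img = Image2D(np.array([[20.0, 10.0]]))
        dark = Image2D(np.array([[12.0, 13.0]]))
        out = subtract_dark_frame(img, dark)
        np.testing.assert_array_equal(out.pixels, [[7.5, 0.0]])

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            subtract_dark_frame(Image2D(np.zeros((4, 4))), Image2D(np.zeros((5, 5))))


class TestMask:
    def test_constant_image_has_no_droplets(self):
        mask = make_droplet_mask(Image2D(np.full((32, 32), 7.0)))
        assert mask.n_droplets == 0
        assert (mask.labels == 0).all()

    def test_disk_area_matches_brute_force_rasterization(self, disk_field):
        image, disk = disk_field
        mask = make_droplet_mask(image)
        assert mask.n_droplets == 1
        found = set(zip(*np.nonzero(mask.labels)))
        assert found == disk

    def test_hot_pixel_removed_by_despeckle(self, disk_field):
        image, disk = disk_field
        pixels = image.pixels.copy()
        pixels[5, 5] = 100.0  # isolated speckle far from the droplet
        mask = make_droplet_mask(
            Image2D(pixels), MaskParams(min_area_px=1)
        )
        assert mask.n_droplets == 1
        assert mask.labels[5, 5] == 0

    def test_plain_mask_median_mode_also_removes_hot_pixel(self, disk_field):
        image, disk = disk_field
        pixels = image.pixels.copy()
        pixels[5, 5] = 100.0
        mask = make_droplet_mask(
            Image2D(pixels), MaskParams(min_area_px=1, median_mode="mask")
        )
        assert mask.labels[5, 5] == 0

    def test_min_area_drops_small_components(self):
        pixels = np.full((32, 32), 10.0)
        pixels[4:7, 4:7] = 100.0  # 9 px
        pixels[20, 20] = 100.0
        pixels[20, 21] = 100.0  # 2 px component
        mask = make_droplet_mask(
            Image2D(pixels), MaskParams(min_area_px=4, median_radius_px=0)
        )
        assert mask.n_droplets == 1
        assert mask.labels[20, 20] == 0

    def test_labels_in_raster_scan_order(self):
        pixels = np.full((32, 32), 10.0)
        pixels[2:6, 20:24] = 100.0  # first reached in raster order
        pixels[10:14, 2:6] = 100.0
        mask = make_droplet_mask(Image2D(pixels), MaskParams(median_radius_px=0))
        assert mask.labels[2, 20] == 1
        assert mask.labels[10, 2] == 2


class TestStatsAndFieldQuant:
    def test_single_droplet_pixel_loop_oracle(self):
        pixels = np.full((16, 16), 10.0)
        pixels[5:8, 5:8] = 100.0  # 9 px at 100
        img = Image2D(pixels)
        mask = make_droplet_mask(img, MaskParams(median_radius_px=0))
        stats = droplet_stats(img, mask)
        assert len(stats) == 1
        assert stats[0].area_px == 9
        assert stats[0].mean_intensity == 100.0
        assert stats[0].integrated_intensity == 900.0

    def test_two_droplets_independent_means(self):
        pixels = np.full((32, 32), 10.0)
        pixels[2:5, 2:5] = 80.0
        pixels[20:23, 20:23] = 120.0
        img = Image2D(pixels)
        mask = make_droplet_mask(img, MaskParams(median_radius_px=0))
        stats = droplet_stats(img, mask)
        assert sorted(s.mean_intensity for s in stats) == [80.0, 120.0]
        fq = field_quant(img, mask)
        assert fq.i_dp == 100.0
        assert fq.i_lp == 10.0
        assert fq.pc == 10.0

    def test_empty_mask_gives_rc_zero_and_undefined_pc(self):
        img = Image2D(np.full((16, 16), 5.0))
        mask = make_droplet_mask(img)
        fq = field_quant(img, mask)
        assert fq.rc == 0.0
        assert not fq.pc_defined
        assert np.isnan(fq.pc)

    def test_rc_pixel_sum_oracle(self, disk_field):
        image, disk = disk_field
        mask = make_droplet_mask(image)
        fq = field_quant(image, mask)
        n_in = len(disk)
        i_in = 100.0 * n_in
        i_out = 10.0 * (64 * 64 - n_in)
        assert fq.i_in == i_in
        assert fq.i_out == i_out
        assert fq.rc == i_in / (i_in + i_out)

    def test_i_in_plus_i_out_equals_total_sum(self, disk_field):
        image, _ = disk_field
        mask = make_droplet_mask(image)
        fq = field_quant(image, mask)
        assert fq.i_in + fq.i_out == image.pixels.sum()

    def test_relabeling_leaves_pc_rc_unchanged(self, disk_field):
        image, _ = disk_field
        pixels = image.pixels.copy()
        pixels[50:54, 50:54] = 100.0  # second droplet
        img = Image2D(pixels)
        mask = make_droplet_mask(img)
        fq = field_quant(img, mask)
        permuted = mask
        permuted.labels = np.where(
            mask.labels == 1, 2, np.where(mask.labels == 2, 1, 0)
        )
        fq2 = field_quant(img, permuted)
        assert fq2.pc == fq.pc
        assert fq2.rc == fq.rc


class TestTwoChannel:
    def test_uniform_rna_channel_has_pc_one(self):
        fld = gen_droplet_field(DropletFieldSpec(seed=2))
        rna = Image2D(np.full(fld.protein.shape, 20.0))
        _, fq2 = field_quant_two_channel(fld.protein, rna)
        assert fq2.pc == pytest.approx(1.0)

    def test_partitioned_rna_channel(self):
        fld = gen_droplet_field(
            DropletFieldSpec(seed=3, i_dense2=50.0, i_dilute2=5.0)
        )
        fq1, fq2 = field_quant_two_channel(fld.protein, fld.rna)
        assert fq2.pc == 10.0
        assert fq1.pc == 10.0

    def test_no_droplets_both_rc_zero(self):
        flat = Image2D(np.full((32, 32), 10.0))
        rna = Image2D(np.full((32, 32), 20.0))
        fq1, fq2 = field_quant_two_channel(flat, rna)
        assert fq1.rc == 0.0 and fq2.rc == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            field_quant_two_channel(
                Image2D(np.zeros((8, 8))), Image2D(np.zeros((9, 8)))
            )


class TestConcentrationSweep:
    @staticmethod
    def _fq(n, rc):
        return FieldQuant(
            channel_name="p", n_droplets=n, i_dp=100.0, i_lp=10.0,
            pc=10.0 if n else float("nan"), i_in=1.0, i_out=1.0, rc=rc,
            mean_area_px=20.0 if n else float("nan"), pc_defined=bool(n),
        )

    def test_onset_at_first_concentration_with_droplets(self):
        fields = [
            (1.0, self._fq(0, 0.0)),
            (3.0, self._fq(0, 0.0)),
            (5.0, self._fq(4, 0.1)),
            (10.0, self._fq(9, 0.3)),
        ]
        df = concentration_sweep(fields)
        assert df.attrs["onset"] == 5.0
        assert df.loc[df["is_onset"], "concentration_uM"].tolist() == [5.0]

    def test_all_empty_fields_has_no_onset(self):
        df = concentration_sweep([(1.0, self._fq(0, 0.0))])
        assert df.attrs["onset"] is None
        assert not df["is_onset"].any()

    def test_single_concentration_one_row(self):
        df = concentration_sweep([(5.0, self._fq(2, 0.1)), (5.0, self._fq(4, 0.2))])
        assert len(df) == 1
        assert df.loc[0, "mean_n_droplets"] == 3.0

    def test_empty_input_errors(self):
        with pytest.raises(CondquantError):
            concentration_sweep([])


class TestProperties:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_rc_in_unit_interval_and_sum_identity(self, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.uniform(0, 100, size=(48, 48))
        img = Image2D(pixels)
        mask = make_droplet_mask(img)
        fq = field_quant(img, mask)
        assert 0.0 <= fq.rc <= 1.0
        assert fq.i_in + fq.i_out == pytest.approx(pixels.sum(), rel=1e-12)
        assert (fq.rc == 0.0) == (mask.n_droplets == 0)

    @given(dense=st.sampled_from([50.0, 100.0, 200.0, 400.0]))
    @settings(max_examples=4, deadline=None)
    def test_pc_and_rc_monotone_in_dense_intensity(self, dense):
        base = gen_droplet_field(DropletFieldSpec(seed=11, i_dense=dense))
        higher = gen_droplet_field(DropletFieldSpec(seed=11, i_dense=dense * 2))
        mask_b = make_droplet_mask(base.protein)
        mask_h = make_droplet_mask(higher.protein)
        fq_b = field_quant(base.protein, mask_b)
        fq_h = field_quant(higher.protein, mask_h)
        assert fq_h.pc >= fq_b.pc
        assert fq_h.rc >= fq_b.rc
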