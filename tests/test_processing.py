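"""SPECT normalization/discretization and CT enhancement: hand-computed
oracles, distributional properties of histogram equalization, and the
mask-aware filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctpm.processing import (
    ProcessingConfig,
    discretize,
    enhance_ct,
    masked_median_filter,
    masked_uniform_filter,
    normalize_spect,
    process_sample,
)
from ctpm.volume import ImageVolume, LABEL

from conftest import make_volume


def vol_and_mask(values, mask=None):
    v = make_volume(np.asarray(values, dtype=float))
    m = np.ones(v.shape, dtype=int) if mask is None else np.asarray(mask)
    return v, make_volume(m, kind=LABEL)


class TestNormalizeSpect:
    def test_constant_maps_to_one(self):
        v, m = vol_and_mask(np.full((4, 4, 4), 37.0))
        out = normalize_spect(v, m)
        assert np.allclose(out.values, 1.0)

    def test_hand_percentile_oracle(self):
        """{10, 20, ..., 100}: the linear-interpolation 75th percentile is
        77.5, so a voxel at 77.5 maps to exactly 1.0."""
        vals = np.array([10.0, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        assert np.percentile(vals, 75) == 77.5  # frozen oracle
        grid = np.zeros((1, 2, 5))
        grid.flat[:10] = vals
        v, m = vol_and_mask(grid)
        out = normalize_spect(v, m)
        assert np.allclose(np.sort(out.values.ravel()), np.sort(vals / 77.5))

    def test_75_percent_of_voxels_at_most_one(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.linspace(1, 500, 10_000)).reshape(10, 40, 25)
        v, m = vol_and_mask(vals)
        out = normalize_spect(v, m)
        frac = (out.values <= 1.0).mean()
        assert abs(frac - 0.75) < 0.001

    def test_out_of_mask_zero(self):
        mask = np.zeros((4, 4, 4), dtype=int)
        mask[1:3, 1:3, 1:3] = 1
        v, m = vol_and_mask(np.full((4, 4, 4), 5.0), mask)
        out = normalize_spect(v, m)
        assert out.values[mask == 0].max() == 0.0

    def test_degenerate_perfusion_rejected(self):
        v, m = vol_and_mask(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            normalize_spect(v, m)


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.34, 0.3), (0.37, 0.4), (0.35, 0.4), (1.8, 1.0), (0.0, 0.0), (-0.2, 0.0)],
    )
    def test_nearest_level_with_ties_up(self, value, expected):
        v, m = vol_and_mask(np.full((2, 2, 2), value))
        out = discretize(v, m)
        assert np.allclose(out.values, expected, atol=1e-7)

    def test_dense_sweep_gives_exactly_11_levels(self):
        v, m = vol_and_mask(np.linspace(0, 1.5, 4096).reshape(16, 16, 16))
        out = discretize(v, m)
        assert len(np.unique(out.values)) == 11

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        v, m = vol_and_mask(rng.random((6, 6, 6)) * 1.4)
        once = discretize(v, m)
        twice = discretize(once, m)
        assert np.array_equal(once.values, twice.values)

    def test_level_set_exact(self):
        rng = np.random.default_rng(4)
        v, m = vol_and_mask(rng.random((8, 8, 8)))
        out = discretize(v, m)
        levels = np.arange(11) / 10
        for u in np.unique(out.values):
            assert np.abs(levels - u).min() < 1e-6


class TestEnhanceCT:
    def test_constant_volume_maps_to_one(self):
        v, m = vol_and_mask(np.full((8, 8, 8), -650.0))
        out = enhance_ct(v, m, ProcessingConfig(median_kernel_vox=4, uniform_kernel_vox=3))
        assert np.allclose(out.values, 1.0, atol=1e-6)

    def test_two_bin_histogram_oracle(self):
        """Half the voxels at -900, half at -500, filters off: the cumulative
        histogram gives 0.5 and 1.0."""
        vals = np.full((4, 4, 4), -900.0)
        vals[2:] = -500.0
        v, m = vol_and_mask(vals)
        cfg = ProcessingConfig(median_filter=False, uniform_filter=False)
        out = enhance_ct(v, m, cfg)
        assert np.allclose(out.values[:2], 0.5)
        assert np.allclose(out.values[2:], 1.0)

    def test_outliers_clipped_to_window(self):
        vals = np.full((4, 4, 4), -900.0)
        vals[0, 0, 0] = -1500.0  # below the window: treated as -1000
        vals[0, 0, 1] = 50.0     # above: treated as -300
        v, m = vol_and_mask(vals)
        cfg = ProcessingConfig(median_filter=False, uniform_filter=False)
        out = enhance_ct(v, m, cfg)
        # the -1500 voxel equals the lowest bin; the +50 voxel the highest
        assert out.values[0, 0, 0] == out.values.min()
        assert out.values[0, 0, 1] == 1.0

    def test_monotone_in_hu(self, subject):
        cfg = ProcessingConfig(median_filter=False, uniform_filter=False)
        out = enhance_ct(subject.ct, subject.mask, cfg)
        m = subject.mask.values > 0
        hu = subject.ct.values[m]
        eq = out.values[m]
        order = np.argsort(hu, kind="stable")
        assert np.all(np.diff(eq[order]) >= -1e-9)

    def test_range_in_unit_interval(self, subject):
        cfg = ProcessingConfig(median_filter=False, uniform_filter=False)
        out = enhance_ct(subject.ct, subject.mask, cfg)
        m = subject.mask.values > 0
        assert out.values[m].min() > 0.0
        assert out.values[m].max() <= 1.0

    def test_equalization_uniformizes(self):
        """Equalizing a dense distinct-valued input yields an empirical
        distribution within KS distance O(1/n) of uniform on (0, 1]."""
        rng = np.random.default_rng(5)
        vals = -1000 + 700 * rng.beta(2, 5, size=(16, 16, 16))
        v, m = vol_and_mask(vals)
        cfg = ProcessingConfig(median_filter=False, uniform_filter=False)
        eq = enhance_ct(v, m, cfg).values.ravel()
        grid = np.sort(eq)
        ks = np.abs(grid - (np.arange(1, grid.size + 1)) / grid.size).max()
        assert ks < 0.01

    def test_empty_mask_rejected(self):
        v, m = vol_and_mask(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), dtype=int))
        with pytest.raises(ValueError):
            enhance_ct(v, m)


class TestMaskAwareFilters:
    def test_filters_preserve_constants_and_bounds(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        vals = np.where(mask, 0.6, 0.0)
        for out in (
            masked_median_filter(vals, mask, 4),
            masked_uniform_filter(vals, mask, 3),
        ):
            assert np.allclose(out[mask], 0.6, atol=1e-9)
            assert np.all(out[~mask] == 0.0)

    def test_bounds_preserved_on_noise(self, rng):
        mask = np.ones((8, 8, 8), dtype=bool)
        vals = rng.random((8, 8, 8))
        for out in (
            masked_median_filter(vals, mask, 4),
            masked_uniform_filter(vals, mask, 3),
        ):
            assert out.min() >= vals.min() - 1e-9
            assert out.max() <= vals.max() + 1e-9

    def test_median_matches_bruteforce_oracle(self, rng):
        """Direct per-voxel nanmedian oracle, including the floor-centred
        even-kernel convention (offsets -2..+1 for kernel 4)."""
        mask = rng.random((6, 6, 6)) > 0.3
        vals = np.where(mask, rng.random((6, 6, 6)), 0.0)
        out = masked_median_filter(vals, mask, 4)
        for z, y, x in [(0, 0, 0), (2, 3, 4), (5, 5, 5), (3, 2, 1)]:
            if not mask[z, y, x]:
                assert out[z, y, x] == 0.0
                continue
            nb = []
            for dz in range(-2, 2):
                for dy in range(-2, 2):
                    for dx in range(-2, 2):
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if 0 <= zz < 6 and 0 <= yy < 6 and 0 <= xx < 6 and mask[zz, yy, xx]:
                            nb.append(vals[zz, yy, xx])
            assert out[z, y, x] == pytest.approx(np.median(nb))

    def test_uniform_matches_bruteforce_oracle(self, rng):
        mask = rng.random((6, 6, 6)) > 0.3
        vals = np.where(mask, rng.random((6, 6, 6)), 0.0)
        out = masked_uniform_filter(vals, mask, 3)
        z, y, x = 3, 3, 3
        nb = []
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if mask[z + dz, y + dy, x + dx]:
                        nb.append(vals[z + dz, y + dy, x + dx])
        if mask[z, y, x]:
            assert out[z, y, x] == pytest.approx(np.mean(nb), rel=1e-6)


class TestProcessSample:
    def test_defaults_give_discrete_label(self, raw_lung_samples):
        cfg = ProcessingConfig(median_kernel_vox=4, uniform_kernel_vox=3)
        s = process_sample(raw_lung_samples[0], cfg)
        m = s.roi_mask.values > 0
        assert len(np.unique(s.perfusion.values[m])) <= 11
        assert s.provenance["processing"]["n_levels"] == 11

    def test_all_toggles_off_is_passthrough(self, raw_lung_samples):
        cfg = ProcessingConfig(
            discretize=False, contrast_enhance=False,
            median_filter=False, uniform_filter=False,
        )
        s = process_sample(raw_lung_samples[0], cfg)
        m = s.roi_mask.values > 0
        # CT: clipped HU only (still negative HU values, not [0,1])
        raw_ct = np.clip(raw_lung_samples[0].ct.values[m], -1000, -300)
        assert np.allclose(s.ct.values[m], raw_ct, atol=1e-3)
        # label: normalized but continuous (far more than 11 distinct values)
        assert len(np.unique(s.perfusion.values[m])) > 11

    def test_median_toggle_changes_output(self, raw_lung_samples):
        on = process_sample(
            raw_lung_samples[0], ProcessingConfig(median_kernel_vox=4, uniform_kernel_vox=3)
        )
        off = process_sample(
            raw_lung_samples[0],
            ProcessingConfig(median_kernel_vox=4, uniform_kernel_vox=3, median_filter=False),
        )
        assert not np.allclose(on.ct.values, off.ct.values)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 2.0), min_size=8, max_size=8))
def test_discretize_idempotence_property(values):
    v = ImageVolume(np.array(values).reshape(2, 2, 2))
    m = ImageVolume(np.ones((2, 2, 2), dtype=np.int16), interpolation_class=LABEL)
    once = discretize(v, m)
    assert np.array_equal(discretize(once, m).values, once.values)
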