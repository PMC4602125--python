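"""k-space downsampling, Otsu, threshold segmentation, volume accounting."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

import infarctvt as iv
from infarctvt.imaging import VolumeReport
from infarctvt.volumes import IntensityVolume


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return IntensityVolume(data=np.asarray(data, float), spacing=spacing)


# ---------------------------------------------------------------------------
# fourier_downsample
# ---------------------------------------------------------------------------

class TestFourierDownsample:
    def test_native_target_is_exact_identity(self):
        rng = np.random.default_rng(0)
        img = _vol(rng.normal(100, 10, (16, 16, 16)), (0.39, 0.39, 0.39))
        out = iv.fourier_downsample(img, iv.DownsampleTarget((0.39, 0.39, 0.39)))
        assert np.array_equal(out.data, img.data)

    def test_constant_image_unchanged(self):
        img = _vol(np.full((12, 12, 12), 7.5))
        out = iv.fourier_downsample(img, iv.DownsampleTarget((3.0, 3.0, 3.0)))
        assert np.allclose(out.data, 7.5)

    def test_nyquist_sinusoid_attenuated_matches_dft_oracle(self):
        # 64-sample line along z, period = 2 * target spacing
        n = 64
        d, target = 1.0, 4.0
        z = np.arange(n)
        line = 100.0 + 10.0 * np.sin(2 * np.pi * z * d / (2 * target))
        img = _vol(np.broadcast_to(line, (4, 4, n)).copy(), (d, d, d))
        out = iv.fourier_downsample(img, iv.DownsampleTarget((d, d, target)))
        # brute-force DFT filter on the 1D line with the same mask rule
        k = int(round(n * d / (2 * target)))
        spec = np.fft.fft(line)
        freqs = np.rint(np.fft.fftfreq(n) * n).astype(int)
        spec[np.abs(freqs) > k] = 0.0
        oracle = np.fft.ifft(spec).real
        assert np.allclose(out.data[2, 2, :], oracle, atol=1e-9)
        # the sinusoid sits exactly on the mask edge bin; its pass/stop
        # status must match the oracle, and the mean must be preserved
        assert out.data.mean() == pytest.approx(100.0)

    def test_idempotent_projection(self):
        rng = np.random.default_rng(1)
        img = _vol(rng.normal(100, 10, (24, 24, 24)), (0.39, 0.39, 0.39))
        once = iv.fourier_downsample(img, iv.MED_RES)
        twice = iv.fourier_downsample(once, iv.MED_RES)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_upsampling_rejected(self):
        img = _vol(np.zeros((8, 8, 8)) + 1.0, (1.5, 1.5, 1.5))
        with pytest.raises(ValueError, match="upsampling"):
            iv.fourier_downsample(img, iv.DownsampleTarget((1.5, 1.5, 0.39)))


# ---------------------------------------------------------------------------
# Otsu myocardium
# ---------------------------------------------------------------------------

class TestOtsu:
    def test_two_valued_image_mask_equals_wall(self):
        data = np.full((10, 10, 10), 200.0)
        data[2:8, 2:8, 2:8] = 100.0
        img = _vol(data)
        mask = iv.otsu_myocardium(img, bath_brighter=True)
        assert np.array_equal(mask, data == 100.0)

    def test_toy_histogram_threshold_between_classes(self):
        img = _vol(np.array([100.0] * 4 + [200.0] * 4).reshape(2, 2, 2))
        thr = iv.otsu_threshold(img)
        assert 100.0 <= thr < 200.0

    def test_noisy_phantom_dice_above_099(self):
        spec = iv.PhantomSpec(matrix_size=(48, 48, 48), scar_radius=4.0,
                              gz_rim_width=1.5, infarct_center=(9.4, 9.4, 9.4))
        img, lab = iv.generate_phantom(spec)
        mask = iv.otsu_myocardium(img)
        gt = lab.labels != 0
        dice = 2.0 * np.sum(mask & gt) / (mask.sum() + gt.sum())
        assert dice > 0.99

    def test_constant_image_raises_degenerate_histogram(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            iv.otsu_myocardium(_vol(np.full((6, 6, 6), 42.0)))


# ---------------------------------------------------------------------------
# Thresholds and classification
# ---------------------------------------------------------------------------

class TestThresholds:
    def _hand_setup(self):
        # outside-ROI voxels {10,10,10,10}, ROI voxels {30,50}
        data = np.array([10.0, 10, 10, 10, 30, 50]).reshape(1, 1, 6)
        img = _vol(data)
        myo = np.ones_like(data, bool)
        roi = np.zeros_like(data, bool)
        roi[0, 0, 4:] = True
        return img, myo, roi

    def test_hand_arithmetic_example(self):
        img, myo, roi = self._hand_setup()
        thr = iv.compute_thresholds(img, myo, roi, k=4.0)
        assert thr.normal_max == 10.0
        assert thr.infarct_max == 50.0
        assert thr.infarct_range == 40.0
        assert thr.gz_upper == 30.0

    def test_boundary_conventions_of_classification(self):
        img, myo, roi = self._hand_setup()
        thr = iv.compute_thresholds(img, myo, roi, k=4.0)
        labels = iv.classify_tissue(img, myo, thr)
        flat = labels.labels[0, 0]
        assert list(flat[:4]) == [iv.LABEL_NORMAL] * 4  # == normal_max
        assert flat[4] == iv.LABEL_GZ                   # == gz_upper -> GZ
        assert flat[5] == iv.LABEL_SCAR                 # > gz_upper

    def test_degenerate_sd_zero_and_flat_roi(self):
        data = np.array([10.0, 10, 10, 10, 10, 10]).reshape(1, 1, 6)
        img = _vol(data)
        myo = np.ones_like(data, bool)
        roi = np.zeros_like(data, bool)
        roi[0, 0, 4:] = True
        thr = iv.compute_thresholds(img, myo, roi, k=4.0)
        assert thr.normal_max == 10.0
        assert thr.infarct_range == 0.0
        assert thr.gz_upper == thr.normal_max

    def test_gz_upper_monotone_in_k(self):
        rng = np.random.default_rng(2)
        data = rng.normal(100, 8, (6, 6, 6))
        data[0, 0, 0] = 300.0
        img = _vol(data)
        myo = np.ones_like(data, bool)
        roi = np.zeros_like(data, bool)
        roi[0, 0, 0] = True
        t3 = iv.compute_thresholds(img, myo, roi, k=3.0)
        t4 = iv.compute_thresholds(img, myo, roi, k=4.0)
        assert t3.gz_upper <= t4.gz_upper

    def test_empty_roi_and_roi_outside_myocardium_raise(self):
        img, myo, roi = self._hand_setup()
        with pytest.raises(ValueError, match="empty"):
            iv.compute_thresholds(img, myo, np.zeros_like(roi), k=4)
        bad = roi.copy()
        myo2 = myo.copy()
        myo2[0, 0, 5] = False
        with pytest.raises(ValueError, match="inside the myocardium"):
            iv.compute_thresholds(img, myo2, bad, k=4)

    def test_all_below_normal_max_yields_no_gz_or_scar(self):
        data = np.full((4, 4, 4), 50.0)
        img = _vol(data)
        myo = np.ones_like(data, bool)
        thr = iv.SegmentationThresholds(normal_max=60.0, infarct_max=60.0,
                                        sd_multiplier=4.0)
        labels = iv.classify_tissue(img, myo, thr)
        counts = labels.class_counts()
        assert counts["GZ"] == 0 and counts["scar"] == 0

    def test_classification_partitions_the_myocardium(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(0, 300, (8, 8, 8))
        img = _vol(data)
        myo = rng.random((8, 8, 8)) > 0.3
        thr = iv.SegmentationThresholds(normal_max=100.0, infarct_max=280.0,
                                        sd_multiplier=4.0)
        labels = iv.classify_tissue(img, myo, thr)
        assert np.all((labels.labels != 0) == myo)


def test_noisefree_phantom_segmentation_is_exact(noisefree_phantom):
    _, img, lab = noisefree_phantom
    roi = (lab.labels == iv.LABEL_GZ) | (lab.labels == iv.LABEL_SCAR)
    seg = iv.segment_lge(img, roi, k=4.0)
    assert np.array_equal(seg.labels, lab.labels)


# ---------------------------------------------------------------------------
# Volume accounting
# ---------------------------------------------------------------------------

class TestVolumeReport:
    def test_unit_conversion_1000_voxels_is_1_cm3(self):
        labels = np.ones((10, 10, 10), dtype=np.uint8)
        lab = iv.LabelVolume(data=labels, spacing=(1.0, 1.0, 1.0))
        vr = iv.volume_report(lab)
        assert vr.total_cm3 == pytest.approx(1.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, (12, 12, 12)).astype(np.uint8)
        lab = iv.LabelVolume(data=labels, spacing=(0.5, 0.5, 0.5))
        pct = iv.volume_report(lab).percentages
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_empty_myocardium_raises(self):
        lab = iv.LabelVolume(data=np.zeros((4, 4, 4), dtype=np.uint8),
                             spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="no myocardial"):
            iv.volume_report(lab)

    def test_table_layout(self):
        vr = VolumeReport(normal_cm3=90.0, gz_cm3=6.0, scar_cm3=4.0)
        df = vr.to_dataframe()
        assert list(df["class"]) == ["normal", "GZ", "scar", "total"]
        assert df["percent"].iloc[0] == pytest.approx(90.0)


class TestPairedT:
    def _reports(self, totals):
        return [VolumeReport(normal_cm3=t, gz_cm3=0.0, scar_cm3=0.0)
                for t in totals]

    def test_identical_lists_give_t0_p1(self):
        a = self._reports([140.0, 150.0, 155.0, 160.0])
        t, p = iv.compare_volume_sets(a, a)
        assert t == 0.0 and p == 1.0

    def test_constant_offset_degenerates_to_infinite_t_with_warning(self):
        a = self._reports([140.0, 150.0, 155.0])
        b = self._reports([141.0, 151.0, 156.0])
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            t, p = iv.compare_volume_sets(a, b)
        assert np.isinf(t) and p == 0.0
        assert any("zero variance" in str(x.message) for x in w)

    def test_matches_bruteforce_t_formula(self):
        rng = np.random.default_rng(5)
        xa = rng.normal(150, 8, 4)
        xb = xa + rng.normal(2, 3, 4)
        t, p = iv.compare_volume_sets(self._reports(xa), self._reports(xb))
        d = xa - xb
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_expect)

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            iv.compare_volume_sets(self._reports([1.0]), self._reports([2.0]))


def test_downsampling_grows_infarct_on_packaged_suite():
    """Lower resolution inflates GZ+scar via partial volume at the infarct
    rim, while total ventricular volume is unchanged (ground-truth wall)."""
    for spec in iv.phantom_suite(2):
        img, gt = iv.generate_phantom(spec)
        wall = gt.labels != 0
        infarct = (gt.labels == iv.LABEL_GZ) | (gt.labels == iv.LABEL_SCAR)
        roi = ndimage.binary_dilation(infarct, iterations=3) & wall
        thr = iv.compute_thresholds(img, wall, roi, k=4.0)
        native = iv.volume_report(iv.classify_tissue(img, wall, thr))
        for target in (iv.MED_RES, iv.LOW_RES):
            low = iv.fourier_downsample(img, target)
            thr_d = iv.downsampled_thresholds(low, wall, roi, target, k=3.0)
            down = iv.volume_report(iv.classify_tissue(low, wall, thr_d))
            assert (down.gz_cm3 + down.scar_cm3
                    >= native.gz_cm3 + native.scar_cm3)
            assert down.total_cm3 == pytest.approx(native.total_cm3)
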