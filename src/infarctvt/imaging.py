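"""Resolution degradation and LGE tissue segmentation.

Downsampling emulates low clinical MRI resolution without changing the
matrix: the image is taken to k-space, every component outside a centred
3D rectangular mask is zeroed, and an inverse FFT reconstructs the blurred
image on the original voxel grid.  The mask half-width per dimension is
K_i = round(N_i * d_i / (2 * D_i)) frequency bins for source spacing d and
target spacing D (the Nyquist-matching choice); the zero-frequency bin is
always retained.

Segmentation follows the standard gray-level thresholding of
contrast-enhanced scans: Otsu separates myocardium from the brighter
gadolinium bath; within the myocardium, normal_max = mean + k*SD of the
intensities outside the infarct region (k = 4 at native resolution, 3
after downsampling, reflecting the narrower intensity range of blurred
images); the infarct splits at 50% of infarct_range = infarct_max -
normal_max into gray zone (below) and scar (above).  Intensity exactly at
normal_max counts as normal and exactly at the GZ/scar boundary as GZ
(half-open on the left, closed on the right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .volumes import (
    IntensityVolume, LabelVolume,
    LABEL_BACKGROUND, LABEL_NORMAL, LABEL_GZ, LABEL_SCAR, _as_triple,
)

SD_MULTIPLIER_HIRES = 4.0
SD_MULTIPLIER_DOWNSAMPLED = 3.0


@dataclass(frozen=True)
class DownsampleTarget:
    """Target acquisition resolution in mm (e.g. 1.5 x 1.5 x 8)."""

    target_resolution: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_resolution",
                           _as_triple(self.target_resolution))
        if any(r <= 0 for r in self.target_resolution):
            raise ValueError("target resolution must be strictly positive")


MED_RES = DownsampleTarget((1.5, 1.5, 4.0))
LOW_RES = DownsampleTarget((1.5, 1.5, 8.0))


def kspace_mask_halfwidths(shape, source_spacing, target_resolution):
    """Frequency half-widths K_i = round(N_i d_i / (2 D_i)) per dimension."""
    ks = []
    for n, d, D in zip(shape, source_spacing, target_resolution):
        if D < d - 1e-12:
            raise ValueError(
                f"target resolution {D} mm finer than source {d} mm: "
                "upsampling is unsupported")
        ks.append(int(round(n * d / (2.0 * D))))
    return tuple(ks)


def fourier_downsample(image: IntensityVolume,
                       target: DownsampleTarget) -> IntensityVolume:
    """Low-pass the image through a centred rectangular k-space mask.

    The output keeps the source matrix and voxel size.  If the mask covers
    the full spectrum in every dimension (target equals source) the input
    data is returned unchanged.  Applying the same target twice equals
    applying it once (the mask is a projection), up to FFT round-off.
    """
    K = kspace_mask_halfwidths(image.shape, image.spacing,
                               target.target_resolution)
    if all(2 * k + 1 >= n for k, n in zip(K, image.shape)):
        return IntensityVolume(data=image.data.copy(),
                               spacing=image.spacing, origin=image.origin)
    spectrum = np.fft.fftn(np.asarray(image.data, dtype=float))
    for axis, (n, k) in enumerate(zip(image.shape, K)):
        freqs = np.rint(np.fft.fftfreq(n) * n).astype(int)
        keep = np.abs(freqs) <= k
        sl = [None, None, None]
        sl[axis] = slice(None)
        spectrum *= keep[tuple(sl)]
    data = np.fft.ifftn(spectrum).real
    return IntensityVolume(data=data, spacing=image.spacing, origin=image.origin)


def _clip_nonnegative(image: IntensityVolume) -> np.ndarray:
    """Gray levels are nonnegative; inverse-FFT ringing is clipped at zero."""
    return np.maximum(np.asarray(image.data, dtype=float), 0.0)


def otsu_threshold(image: IntensityVolume) -> float:
    """Between-class-variance-maximising gray level of the (clipped) image.

    Images with few distinct gray levels are thresholded on their exact
    value histogram, so the returned level is an attained intensity (the
    upper limit of the dark class); continuous images use the standard
    256-bin histogram.
    """
    data = _clip_nonnegative(image)
    if np.ptp(data) == 0:
        raise ValueError("degenerate histogram: the image is constant")
    vals, counts = np.unique(data, return_counts=True)
    if vals.size <= 1024:
        return float(threshold_otsu(hist=(counts, vals)))
    return float(threshold_otsu(data))


def otsu_myocardium(image: IntensityVolume, bath_brighter=True) -> np.ndarray:
    """Binary myocardium mask via Otsu's threshold against the bath.

    The myocardium is the class on the dark side of the threshold when the
    bath is brighter (gadolinium-filled bath, the default) and the bright
    side otherwise; only the largest face-connected component is kept.
    """
    data = _clip_nonnegative(image)
    thr = otsu_threshold(image)
    mask = data <= thr if bath_brighter else data > thr
    if not mask.any():
        raise ValueError("Otsu threshold produced an empty myocardium mask")
    comps = cc_label(mask, connectivity=1)
    counts = np.bincount(comps.ravel())
    counts[0] = 0
    return comps == int(np.argmax(counts))


@dataclass(frozen=True)
class SegmentationThresholds:
    """Gray-level limits of the three tissue classes.

    ``normal_max`` = mean + k*SD of myocardial intensity outside the
    infarct; ``infarct_max`` the maximum inside it; ``gz_upper`` =
    normal_max + 0.5 * infarct_range.
    """

    normal_max: float
    infarct_max: float
    sd_multiplier: float

    def __post_init__(self) -> None:
        if self.infarct_max < self.normal_max:
            raise ValueError("infarct_max must be >= normal_max")

    @property
    def infarct_range(self) -> float:
        return self.infarct_max - self.normal_max

    @property
    def gz_upper(self) -> float:
        return self.normal_max + 0.5 * self.infarct_range


def compute_thresholds(image: IntensityVolume, myocardium: np.ndarray,
                       infarct_roi: np.ndarray,
                       k: float = SD_MULTIPLIER_HIRES) -> SegmentationThresholds:
    """Threshold statistics from the myocardium and a supplied infarct ROI.

    The ROI plays the role of the manually drawn infarct region: statistics
    of the tissue outside it give normal_max = mean + k*SD, its interior
    gives infarct_max.  The ROI must lie within the myocardium and leave a
    non-empty remainder.
    """
    myocardium = np.asarray(myocardium, bool)
    infarct_roi = np.asarray(infarct_roi, bool)
    if not infarct_roi.any():
        raise ValueError("infarct ROI is empty")
    if np.any(infarct_roi & ~myocardium):
        raise ValueError("infarct ROI must lie inside the myocardium mask")
    outside = myocardium & ~infarct_roi
    if not outside.any():
        raise ValueError("no myocardium left outside the infarct ROI")
    data = _clip_nonnegative(image)
    vals = data[outside]
    normal_max = float(vals.mean() + k * vals.std(ddof=0))
    infarct_max = float(data[infarct_roi].max())
    infarct_max = max(infarct_max, normal_max)
    return SegmentationThresholds(normal_max=normal_max,
                                  infarct_max=infarct_max, sd_multiplier=k)


def classify_tissue(image: IntensityVolume, myocardium: np.ndarray,
                    thresholds: SegmentationThresholds) -> LabelVolume:
    """Partition the myocardium into normal / GZ / scar by gray level.

    intensity <= normal_max -> normal; normal_max < intensity <= gz_upper
    -> GZ; intensity > gz_upper -> scar; everything outside the mask is
    background.  Every myocardial voxel receives exactly one label.
    """
    data = _clip_nonnegative(image)
    myocardium = np.asarray(myocardium, bool)
    labels = np.full(image.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[myocardium] = LABEL_NORMAL
    gz = myocardium & (data > thresholds.normal_max) & (data <= thresholds.gz_upper)
    scar = myocardium & (data > thresholds.gz_upper)
    labels[gz] = LABEL_GZ
    labels[scar] = LABEL_SCAR
    return LabelVolume(data=labels, spacing=image.spacing, origin=image.origin)


def interior_mask(mask: np.ndarray, spacing_mm, margin_mm) -> np.ndarray:
    """Erode a mask by a physical margin (mm per axis, box structuring).

    Used to restrict threshold statistics of downsampled images to wall
    interior unaffected by bath partial-volume bleed — the stand-in for
    the conservative manually drawn boundaries of the clinical pipeline.
    """
    from scipy import ndimage

    rad = [int(np.ceil(float(m) / float(s)))
           for m, s in zip(margin_mm, spacing_mm)]
    struct = np.ones(tuple(2 * r + 1 for r in rad), bool)
    out = ndimage.binary_erosion(np.asarray(mask, bool), structure=struct)
    if not out.any():
        raise ValueError("interior mask is empty: margin exceeds wall thickness")
    return out


def downsampled_thresholds(image: IntensityVolume, myocardium: np.ndarray,
                           infarct_roi: np.ndarray, target: DownsampleTarget,
                           k: float = SD_MULTIPLIER_DOWNSAMPLED
                           ) -> SegmentationThresholds:
    """Threshold statistics for a downsampled image.

    Identical to :func:`compute_thresholds` except the normal-tissue
    statistics come from the myocardium eroded by the target resolution,
    keeping bath partial-volume voxels out of mean + k*SD; infarct_max is
    still the maximum over the full ROI.
    """
    stats_mask = interior_mask(myocardium, image.spacing,
                               target.target_resolution)
    stats_mask = stats_mask & ~np.asarray(infarct_roi, bool)
    if not stats_mask.any():
        raise ValueError("no interior myocardium outside the infarct ROI")
    data = _clip_nonnegative(image)
    vals = data[stats_mask]
    normal_max = float(vals.mean() + k * vals.std(ddof=0))
    infarct_max = float(data[np.asarray(infarct_roi, bool)].max())
    return SegmentationThresholds(normal_max=normal_max,
                                  infarct_max=max(infarct_max, normal_max),
                                  sd_multiplier=k)


def segment_lge(image: IntensityVolume, infarct_roi: np.ndarray,
                k: float = SD_MULTIPLIER_HIRES, bath_brighter=True) -> LabelVolume:
    """Full segmentation: Otsu myocardium, thresholds, classification."""
    myo = otsu_myocardium(image, bath_brighter=bath_brighter)
    roi = np.asarray(infarct_roi, bool) & myo
    thr = compute_thresholds(image, myo, roi, k=k)
    return classify_tissue(image, myo, thr)


# ---------------------------------------------------------------------------
# Volume accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeReport:
    """Per-class tissue volumes (cm³) and percentages of ventricular volume."""

    normal_cm3: float
    gz_cm3: float
    scar_cm3: float

    @property
    def total_cm3(self) -> float:
        return self.normal_cm3 + self.gz_cm3 + self.scar_cm3

    @property
    def percentages(self) -> dict[str, float]:
        tot = self.total_cm3
        if tot == 0:
            raise ValueError("empty myocardium: total volume is zero")
        return {"normal": 100.0 * self.normal_cm3 / tot,
                "GZ": 100.0 * self.gz_cm3 / tot,
                "scar": 100.0 * self.scar_cm3 / tot}

    def to_dataframe(self) -> pd.DataFrame:
        pct = self.percentages
        rows = [("normal", self.normal_cm3, pct["normal"]),
                ("GZ", self.gz_cm3, pct["GZ"]),
                ("scar", self.scar_cm3, pct["scar"]),
                ("total", self.total_cm3, 100.0)]
        return pd.DataFrame(rows, columns=["class", "volume_cm3", "percent"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def volume_report(labels: LabelVolume) -> VolumeReport:
    """Class volume = voxel count x voxel volume, in cm³ and % of total."""
    vox_cm3 = labels.voxel_volume_mm3 / 1000.0
    counts = labels.class_counts()
    if counts["normal"] + counts["GZ"] + counts["scar"] == 0:
        raise ValueError("label volume contains no myocardial voxels")
    return VolumeReport(normal_cm3=counts["normal"] * vox_cm3,
                        gz_cm3=counts["GZ"] * vox_cm3,
                        scar_cm3=counts["scar"] * vox_cm3)


def compare_volume_sets(a, b, attribute="total_cm3"):
    """Paired Student's t on matched volume reports (two-sided).

    Returns ``(t, p)``.  Identical lists give (0, 1); a constant non-zero
    offset with zero variance of the differences is degenerate and reported
    as signed infinity with p = 0 (and a warning).
    """
    xa = np.array([getattr(r, attribute) for r in a], dtype=float)
    xb = np.array([getattr(r, attribute) for r in b], dtype=float)
    if xa.size != xb.size:
        raise ValueError("paired lists must have equal length")
    if xa.size < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = xa - xb
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        import warnings

        warnings.warn("zero variance of paired differences: t is infinite",
                      RuntimeWarning, stacklevel=2)
        return float(np.sign(diff.mean()) * np.inf), 0.0
    res = stats.ttest_rel(xa, xb)
    return float(res.statistic), float(res.pvalue)
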