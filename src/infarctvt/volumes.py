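"""3D image containers shared by the phantom generator and image pipeline.

An :class:`IntensityVolume` is a scalar 3D array with voxel spacing and
origin in mm; a :class:`LabelVolume` is the matching per-voxel tissue-class
map.  Physical coordinates use the voxel-centre convention throughout the
package: centre of voxel (i, j, k) = origin + (index + 0.5) * spacing.

Label codes: 0 background, 1 normal myocardium, 2 gray zone, 3 scar
(identical to the simulation cell-type codes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

LABEL_BACKGROUND = 0
LABEL_NORMAL = 1
LABEL_GZ = 2
LABEL_SCAR = 3
LABEL_NAMES = {0: "background", 1: "normal", 2: "GZ", 3: "scar"}


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"expected a scalar or length-3 value, got {x!r}")
    return tuple(float(v) for v in arr)


@dataclass
class IntensityVolume:
    """3D scalar image (arbitrary units) with mm spacing and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self):
        """Meshgrid (x, y, z) of voxel-centre coordinates in mm."""
        axes = [self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
                for a in range(3)]
        return np.meshgrid(*axes, indexing="ij")

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))


@dataclass
class LabelVolume(IntensityVolume):
    """Per-voxel tissue class on the same grid as its intensity image."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        bad = set(np.unique(self.data)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def labels(self) -> np.ndarray:
        return self.data

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.data == code))
                for code, name in LABEL_NAMES.items()}


# ---------------------------------------------------------------------------
# NIfTI / MetaImage IO
# ---------------------------------------------------------------------------

def save_volume(vol: IntensityVolume, path) -> None:
    """Write a volume to .nii/.nii.gz (nibabel) or .mha/.mhd (SimpleITK)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.transpose(np.asarray(vol.data), (2, 1, 0))))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path, as_labels=False):
    """Read a volume written by :func:`save_volume`."""
    path = Path(path)
    name = path.name
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    else:
        raise ValueError(f"unsupported volume format: {name}")
    cls = LabelVolume if as_labels else IntensityVolume
    if as_labels:
        data = np.asarray(np.rint(data), dtype=np.uint8)
    return cls(data=data, spacing=spacing, origin=origin)
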