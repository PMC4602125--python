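"""Synthetic LGE-MRI phantoms and parametric tissue slabs.

The phantom generator stands in for contrast-enhanced ex-vivo scans of
infarcted ventricles: a myocardial wall (flat slab or half-ellipsoid shell
with a single bath-filled cavity) immersed in a brighter gadolinium bath,
containing a contiguous hyper-enhanced infarct with a dense scar core and
an intermediate-intensity gray-zone rim, optionally split by a surviving
isthmus channel.  Every voxel has an exact ground-truth label, so the
downstream segmentation, downsampling and simulation stages are testable
end to end.

Intensities are per-class Gaussians (normal tissue uses its own SD, all
classes share an additive acquisition noise SD) truncated at zero.
Partial-volume blur appears only after Fourier downsampling, never at
generation, so native-resolution ground truth stays exact.

The slab builder produces simulation-ready :class:`~infarctvt.monodomain.
TissueGrid` objects from labelled geometric primitives with a parametric
fiber rule (uniform angle, or linear transmural rotation between stated
endo- and epicardial angles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .monodomain import (
    ConductivityParams, TissueGrid, build_tissue_grid,
    CT_NORMAL, CT_GZ, CT_SCAR,
)
from .lrd import GZRemodeling
from .volumes import (
    IntensityVolume, LabelVolume,
    LABEL_BACKGROUND, LABEL_NORMAL, LABEL_GZ, LABEL_SCAR,
    save_volume, _as_triple,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity statistics and noise of one synthetic scan.

    All lengths are mm, intensities arbitrary units.  The intensity
    ordering normal < GZ < scar must hold; ``bath_intensity_mean`` is
    brighter than myocardium (gadolinium-filled bath).  The paper-style
    native acquisition is a 256³ matrix at 0.39 mm isotropic; the default
    here is a desk-scale 64³ at the same spacing.  Intensity statistics
    of the real scans are not published; the defaults below are the
    package's documented free parameters, not claims about any data set.
    """

    matrix_size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.39, 0.39, 0.39)
    wall_geometry: str = "slab"  # or "half-ellipsoid-shell"
    wall_thickness: float = 10.0
    bath_intensity_mean: float = 500.0
    normal_intensity_mean: float = 100.0
    normal_intensity_sd: float = 5.0
    scar_intensity_mean: float = 220.0
    gz_intensity_mean: float = 160.0
    infarct_center: tuple[float, float, float] | None = None
    scar_radius: float = 0.0
    gz_rim_width: float = 0.0
    isthmus: dict | None = None  # {"width": mm, "orientation": deg, "label": "GZ"}
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix_size",
                           tuple(int(n) for n in self.matrix_size))
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        if any(n <= 0 for n in self.matrix_size):
            raise ValueError("matrix_size entries must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.wall_geometry not in ("slab", "half-ellipsoid-shell"):
            raise ValueError(f"unknown wall geometry {self.wall_geometry!r}")
        if not (self.normal_intensity_mean < self.gz_intensity_mean
                < self.scar_intensity_mean):
            raise ValueError(
                "class means must satisfy normal < GZ < scar, got "
                f"{self.normal_intensity_mean}, {self.gz_intensity_mean}, "
                f"{self.scar_intensity_mean}")
        if self.scar_radius < 0 or self.gz_rim_width < 0:
            raise ValueError("scar_radius and gz_rim_width must be >= 0")
        if self.noise_sd < 0 or self.normal_intensity_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.matrix_size) * np.asarray(self.spacing)

    def center_mm(self) -> np.ndarray:
        return self.extent_mm / 2.0

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(path.read_text())
        else:
            d = json.loads(path.read_text())
        for key in ("matrix_size", "spacing", "infarct_center"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _check_inside(spec: PhantomSpec, center, radius, name):
    ext = spec.extent_mm
    c = np.asarray(center, float)
    if np.any(c - radius < 0) or np.any(c + radius > ext):
        raise ValueError(
            f"{name} (centre {tuple(np.round(c, 2))} mm, radius {radius} mm) "
            f"extends outside the image extent {tuple(np.round(ext, 2))} mm")


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume]:
    """Build the noisy intensity image and its exact ground-truth labels.

    Voxel labels are assigned by distance of the voxel centre to the
    geometry primitives; intensities are drawn per class from Gaussians
    truncated at zero, with the spec's seed (identical spec + seed gives
    bit-identical volumes).
    """
    nx, ny, nz = spec.matrix_size
    hx, hy, hz = spec.spacing
    x = (np.arange(nx) + 0.5) * hx
    y = (np.arange(ny) + 0.5) * hy
    z = (np.arange(nz) + 0.5) * hz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    ext = spec.extent_mm
    cx, cy, cz = spec.center_mm()

    if spec.wall_geometry == "slab":
        if spec.wall_thickness > ext[2]:
            raise ValueError(
                f"slab wall (thickness {spec.wall_thickness} mm) exceeds the "
                f"z extent {ext[2]:.2f} mm")
        wall = np.abs(Z - cz) <= spec.wall_thickness / 2.0
    else:  # half-ellipsoid-shell with a single bath-filled cavity
        semi = 0.42 * ext  # outer semi-axes, leaves a bath margin
        if spec.wall_thickness >= semi.min():
            raise ValueError(
                f"shell wall (thickness {spec.wall_thickness} mm) exceeds the "
                f"outer semi-axes {tuple(np.round(semi, 2))} mm")
        rho_out = np.sqrt(((X - cx) / semi[0]) ** 2 + ((Y - cy) / semi[1]) ** 2
                          + ((Z - cz) / semi[2]) ** 2)
        inner = semi - spec.wall_thickness
        rho_in = np.sqrt(((X - cx) / inner[0]) ** 2 + ((Y - cy) / inner[1]) ** 2
                         + ((Z - cz) / inner[2]) ** 2)
        wall = (rho_out <= 1.0) & (rho_in >= 1.0) & (Z <= cz)

    labels = np.full(spec.matrix_size, LABEL_BACKGROUND, dtype=np.uint8)
    labels[wall] = LABEL_NORMAL

    if spec.scar_radius > 0 or spec.gz_rim_width > 0:
        center = (spec.infarct_center if spec.infarct_center is not None
                  else spec.center_mm())
        _check_inside(spec, center,
                      spec.scar_radius + spec.gz_rim_width, "infarct sphere")
        r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2
                    + (Z - center[2]) ** 2)
        gz = wall & (r <= spec.scar_radius + spec.gz_rim_width)
        scar = wall & (r <= spec.scar_radius)
        labels[gz] = LABEL_GZ
        labels[scar] = LABEL_SCAR
        if spec.isthmus is not None and spec.scar_radius > 0:
            width = float(spec.isthmus["width"])
            theta = np.deg2rad(float(spec.isthmus.get("orientation", 0.0)))
            lab = spec.isthmus.get("label", "GZ")
            code = LABEL_GZ if str(lab).upper() == "GZ" else LABEL_NORMAL
            # channel: slab of given width through the infarct centre whose
            # normal lies in-plane at the given orientation
            nvec = np.array([-np.sin(theta), np.cos(theta), 0.0])
            dist = np.abs((X - center[0]) * nvec[0] + (Y - center[1]) * nvec[1]
                          + (Z - center[2]) * nvec[2])
            labels[scar & (dist <= width / 2.0)] = code

    rng = np.random.default_rng(spec.seed)
    means = np.array([spec.bath_intensity_mean, spec.normal_intensity_mean,
                      spec.gz_intensity_mean, spec.scar_intensity_mean])
    intensity = means[labels]
    if spec.normal_intensity_sd > 0:
        class_noise = rng.normal(0.0, spec.normal_intensity_sd, labels.shape)
        intensity = np.where(labels == LABEL_NORMAL,
                             intensity + class_noise, intensity)
    else:
        rng.normal(0.0, 1.0, labels.shape)  # keep the draw order fixed
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, labels.shape)
    intensity = np.maximum(intensity, 0.0)

    img = IntensityVolume(data=intensity, spacing=spec.spacing)
    lab = LabelVolume(data=labels, spacing=spec.spacing)
    return img, lab


def study_phantom_spec(seed: int = 0, scar_radius: float = 7.0,
                       gz_rim_width: float = 2.0) -> PhantomSpec:
    """Packaged resolution-study phantom: slab wall in a signal-free bath.

    The ex-vivo-style dark bath keeps the downsampled wall statistics free
    of bright partial-volume bleed; the infarct sphere is split by a
    surviving gray-zone isthmus.  The wall is thick enough (24 mm) that an
    interior statistics mask survives the low-resolution (8 mm) erosion
    margin.
    """
    return PhantomSpec(
        matrix_size=(64, 64, 96), spacing=(0.39, 0.39, 0.39),
        wall_geometry="slab", wall_thickness=24.0,
        bath_intensity_mean=5.0, normal_intensity_mean=100.0,
        normal_intensity_sd=5.0, gz_intensity_mean=160.0,
        scar_intensity_mean=220.0,
        infarct_center=(12.5, 12.5, 18.7),
        scar_radius=scar_radius, gz_rim_width=gz_rim_width,
        isthmus={"width": 2.4, "orientation": 0.0, "label": "GZ"},
        noise_sd=5.0, seed=seed)


def phantom_suite(n: int = 3) -> list[PhantomSpec]:
    """Small suite of study phantoms (varied infarct size and noise seed)."""
    radii = [7.0, 6.0, 8.0, 5.5, 7.5]
    rims = [2.0, 2.5, 1.6, 2.0, 2.4]
    return [study_phantom_spec(seed=i, scar_radius=radii[i % len(radii)],
                               gz_rim_width=rims[i % len(rims)])
            for i in range(n)]


def write_phantom(spec: PhantomSpec, out_dir, stem="phantom", fmt=".nii.gz"):
    """Generate and write the intensity/label pair plus the serialized spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img, lab = generate_phantom(spec)
    save_volume(img, out / f"{stem}_intensity{fmt}")
    save_volume(lab, out / f"{stem}_labels{fmt}")
    spec.save(out / f"{stem}_spec.yaml")
    return img, lab


# ---------------------------------------------------------------------------
# Parametric tissue slabs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned labelled box; later regions override earlier ones."""

    label: str  # "scar", "gz" or "normal"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    _CODES = {"scar": CT_SCAR, "gz": CT_GZ, "normal": CT_NORMAL}

    def code(self) -> int:
        try:
            return self._CODES[self.label.lower()]
        except KeyError:
            raise ValueError(f"unknown region label {self.label!r}") from None

    def contains(self, X, Y, Z) -> np.ndarray:
        c = _as_triple(self.center_mm)
        s = _as_triple(self.size_mm)
        return ((np.abs(X - c[0]) <= s[0] / 2.0)
                & (np.abs(Y - c[1]) <= s[1] / 2.0)
                & (np.abs(Z - c[2]) <= s[2] / 2.0))


@dataclass(frozen=True)
class SlabSpec:
    """Rectangular tissue slab with labelled primitives and a fiber rule.

    ``fiber_rule`` is ``("uniform-angle", angle_deg)`` or
    ``("linear-transmural-rotation", endo_deg, epi_deg)``; the rotation
    runs across the z (thickness) axis.
    """

    dimensions_mm: tuple[float, float, float]
    node_spacing_mm: float
    fiber_rule: tuple = ("uniform-angle", 0.0)
    regions: tuple[BoxRegion, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions_mm", _as_triple(self.dimensions_mm))
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.node_spacing_mm <= 0:
            raise ValueError("node_spacing must be strictly positive")
        n = np.asarray(self.dimensions_mm) / self.node_spacing_mm
        if np.any(np.abs(n - np.rint(n)) > 1e-6):
            raise ValueError(
                f"node_spacing {self.node_spacing_mm} mm does not divide the "
                f"slab dimensions {self.dimensions_mm} mm")
        dims = np.asarray(self.dimensions_mm)
        for reg in self.regions:
            c = np.asarray(_as_triple(reg.center_mm))
            s = np.asarray(_as_triple(reg.size_mm))
            if np.any(c - s / 2 < -1e-9) or np.any(c + s / 2 > dims + 1e-9):
                raise ValueError(
                    f"region {reg.label!r} at {tuple(c)} mm lies outside the slab")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        n = np.maximum(np.rint(np.asarray(self.dimensions_mm)
                               / self.node_spacing_mm).astype(int), 1)
        return tuple(int(v) for v in n)


def fiber_field(spec: SlabSpec) -> np.ndarray:
    """Per-node fiber angle (deg) for the slab's fiber rule."""
    shape = spec.grid_shape
    rule = spec.fiber_rule
    if rule[0] == "uniform-angle":
        return np.full(shape, float(rule[1]))
    if rule[0] == "linear-transmural-rotation":
        a0, a1 = float(rule[1]), float(rule[2])
        nk = shape[2]
        if nk == 1:
            prof = np.array([(a0 + a1) / 2.0])
        else:
            prof = a0 + (a1 - a0) * np.arange(nk) / (nk - 1)
        return np.broadcast_to(prof[None, None, :], shape).copy()
    raise ValueError(f"unknown fiber rule {rule[0]!r}")


def generate_slab(spec: SlabSpec,
                  cparams: ConductivityParams | None = None,
                  remodeling: GZRemodeling | None = None) -> TissueGrid:
    """Structured simulation grid from a slab spec.

    Nodes are voxel-centred; each node takes the label of the last region
    containing its centre (normal tissue elsewhere).
    """
    shape = spec.grid_shape
    h = spec.node_spacing_mm
    x = (np.arange(shape[0]) + 0.5) * h
    y = (np.arange(shape[1]) + 0.5) * h
    z = (np.arange(shape[2]) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    ct = np.full(shape, CT_NORMAL, dtype=np.uint8)
    for reg in spec.regions:
        ct[reg.contains(X, Y, Z)] = reg.code()
    return build_tissue_grid(ct, fiber_field(spec), (h, h, h),
                             cparams=cparams, remodeling=remodeling)


# ---------------------------------------------------------------------------
# Packaged reentry fixture
# ---------------------------------------------------------------------------

#: geometry of the packaged reentry fixture (mm); tuned and verified by
#: simulation during development and shipped as a regression target.
#:
#: "Theta" layout: every conducting path is a narrow wave-confined corridor
#: (fibers along x except inside the channel, where they run along y —
#: border-zone fiber disarray):
#:
#:     y=18 ┌────────────────────────┐
#:          │     top corridor       │
#:     y=16 │▒│ ██████ ░░ ██████ │▒│ │   ██ = passive scar blocks
#:          │▒│ scar  ░GZ░  scar │▒│ │   ░  = gray-zone isthmus (fibers ∥ y)
#:     y=2  │▒│ ██████ ░░ ██████ │▒│ │   ▒  = lateral corridors (transverse,
#:          │    bottom corridor     │        slow) closing the two loops
#:     y=0  └──────•─────────────────┘   • = PES site under the channel
#:
#: The premature beat blocks at the still-refractory gray-zone channel
#: mouth, travels out along the bottom corridor, slowly up both lateral
#: corridors (transverse conduction), across the top and back down the
#: channel into recovered tissue: two counter-rotating loops around the
#: two scars sharing the isthmus — figure-of-eight reentry.
ISTHMUS_FIXTURE = {
    "sheet_mm": (12.8, 18.0),
    "node_spacing_mm": 0.2,
    "corridor_mm": 2.0,
    "scar_width_mm": 3.2,
    "isthmus_width_mm": 2.4,
    "scar_y_mm": (2.0, 16.0),
    # normal-tissue plug (fibers still along the channel) at the channel's
    # top mouth: full sodium current there lets the returning corridor wave
    # ignite the channel, while the gray-zone mouth at the bottom keeps its
    # long refractory period for unidirectional block
    "plug_mm": 2.0,
    "pes_site_mm": (6.4, 1.0, 0.1),
}


def isthmus_fixture_grid(cparams: ConductivityParams | None = None,
                         remodeling: GZRemodeling | None = None) -> TissueGrid:
    """Build the packaged figure-of-eight reentry fixture (see module dict)."""
    p = ISTHMUS_FIXTURE
    h = p["node_spacing_mm"]
    nx = int(round(p["sheet_mm"][0] / h))
    ny = int(round(p["sheet_mm"][1] / h))
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")

    cor = p["corridor_mm"]
    sw = p["scar_width_mm"]
    iw = p["isthmus_width_mm"]
    y0, y1 = p["scar_y_mm"]
    x_l0, x_l1 = cor, cor + sw                     # left scar block
    x_c0, x_c1 = cor + sw, cor + sw + iw           # channel
    x_r0, x_r1 = cor + sw + iw, cor + 2 * sw + iw  # right scar block

    band = (Y >= y0) & (Y <= y1)
    ct = np.full((nx, ny), CT_NORMAL, dtype=np.uint8)
    ct[band & (X >= x_l0) & (X <= x_l1)] = CT_SCAR
    ct[band & (X >= x_r0) & (X <= x_r1)] = CT_SCAR
    channel = band & (X > x_c0) & (X < x_c1)
    ct[channel] = CT_GZ
    plug = channel & (Y > y1 - p["plug_mm"])
    ct[plug] = CT_NORMAL

    fibers = np.zeros((nx, ny))
    fibers[channel] = 90.0  # conduction along the channel axis

    return build_tissue_grid(ct[:, :, None], fibers[:, :, None], (h, h, h),
                             cparams=cparams, remodeling=remodeling)


def isthmus_fixture_anchor_centroids() -> list[np.ndarray]:
    """Designed centroids (mm) of the two anchoring scar blocks."""
    p = ISTHMUS_FIXTURE
    h = p["node_spacing_mm"]
    cor, sw, iw = p["corridor_mm"], p["scar_width_mm"], p["isthmus_width_mm"]
    y0, y1 = p["scar_y_mm"]
    cy = (y0 + y1) / 2.0
    return [np.array([cor + sw / 2.0, cy, h / 2.0]),
            np.array([cor + sw + iw + sw / 2.0, cy, h / 2.0])]
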