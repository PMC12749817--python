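"""Synthetic organotypic-model phantoms with programmed ground truth.

A phantom is built in two stages: :func:`build_label_volume` lays out a
semantic label volume (medium / cancer / stromal cell / collagen matrix)
containing a top cancer slab plus programmed invasion structures, recording
exact truth values by voxel enumeration; :func:`render_oct` turns the labels
into an OCT-like 16-bit intensity volume (per-class mean intensity,
exponential depth attenuation, multiplicative mean-one Gamma speckle,
anisotropic PSF blur, additive read noise).

Coordinate convention: axis order is ``(z, y, x)`` with ``z = 0`` at the
air-facing top surface; depth in micrometres of voxel index ``z`` spans
``[z * voxel_um, (z + 1) * voxel_um)``.  A voxel lies below a plane at depth
``d`` when its index satisfies ``z >= d / voxel_um``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from octinv.volume_io import LabelVolume, OCTVolume

# class codes
MEDIUM, CANCER, STROMAL_CELL, MATRIX = 0, 1, 2, 3

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# sub-stream tags so that e.g. adding islands never perturbs fibroblasts
_STREAM_COHESIVE, _STREAM_FINGER, _STREAM_ISLAND, _STREAM_FIBRO = 0, 1, 2, 3
_STREAM_SPECKLE, _STREAM_READNOISE = 10, 11

_PATTERNS = ("none", "cohesive", "finger", "island", "mixed")


class PhantomGeometryError(ValueError):
    """A programmed structure does not fit inside the volume."""


@dataclass
class PhantomSpec:
    """All generator parameters; defaults follow the imaging geometry of the
    target instrument (500x500 um ROI, 1 um isotropic voxels, 3 um lateral /
    0.86 um axial resolution, 16-bit dynamic range)."""

    lateral_size_um: tuple[float, float] = (500.0, 500.0)
    depth_um: float = 400.0
    voxel_um: float = 1.0
    cancer_thickness_um: float = 100.0
    stroma_thickness_um: float | None = None  # default: depth - cancer thickness
    invasion_pattern: str = "none"
    finger_count: int = 6
    finger_depth_um: float = 60.0
    finger_radius_um: float = 15.0
    island_count: int = 8
    island_radius_um: tuple[float, float] = (10.0, 0.0)  # (mean, sd)
    island_depth_range_um: tuple[float, float] = (130.0, 220.0)
    fibroblast_density: float = 2000.0  # count per mm^3 of stroma
    fibroblast_axis_um: tuple[float, float] = (12.0, 3.0)  # (long, short) semi-axes
    class_mean_intensity: dict[int, float] = field(
        default_factory=lambda: {MEDIUM: 600.0, CANCER: 28000.0, STROMAL_CELL: 16000.0, MATRIX: 5000.0}
    )
    speckle_shape: float | None = 3.0  # Gamma shape k >= 1; None disables speckle
    read_noise_sd: float = 300.0
    attenuation_per_um: float = 0.002
    psf_lateral_fwhm_um: float = 3.0
    psf_axial_fwhm_um: float = 0.86
    seed: int = 0

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        nz = int(round(self.depth_um / self.voxel_um))
        ny = int(round(self.lateral_size_um[1] / self.voxel_um))
        nx = int(round(self.lateral_size_um[0] / self.voxel_um))
        return nz, ny, nx

    def validate(self) -> None:
        if self.voxel_um <= 0:
            raise PhantomGeometryError("voxel_um must be positive")
        if self.invasion_pattern not in _PATTERNS:
            raise PhantomGeometryError(
                f"invasion_pattern must be one of {_PATTERNS}, got {self.invasion_pattern!r}"
            )
        if not (0 < self.cancer_thickness_um < self.depth_um):
            raise PhantomGeometryError("cancer_thickness_um must lie inside the depth range")
        for name, value in self.class_mean_intensity.items():
            if not (0.0 <= value <= 65535.0):
                raise PhantomGeometryError(f"class_mean_intensity[{name}]={value} outside [0, 65535]")
        if self.speckle_shape is not None and np.isfinite(self.speckle_shape) and self.speckle_shape < 1:
            raise PhantomGeometryError("speckle_shape must be >= 1 (or None to disable)")
        if self.attenuation_per_um < 0:
            raise PhantomGeometryError("attenuation_per_um must be >= 0")

        margin = 2.0 * self.voxel_um
        if self.invasion_pattern in ("cohesive", "finger", "mixed"):
            if self.finger_radius_um < 2.0 * self.voxel_um:
                raise PhantomGeometryError("finger_radius_um must be >= 2 voxels")
            reach = self.cancer_thickness_um + self.finger_depth_um + margin
            if reach > self.depth_um:
                raise PhantomGeometryError(
                    f"finger invasion reaches {reach:.1f} um but volume depth is {self.depth_um:.1f} um"
                )
        if self.invasion_pattern in ("island", "mixed"):
            mean_r, sd_r = self.island_radius_um
            if mean_r < 2.0 * self.voxel_um:
                raise PhantomGeometryError("island_radius_um mean must be >= 2 voxels")
            r_max = mean_r + 3.0 * sd_r
            lo, hi = self.island_depth_range_um
            if lo - r_max < self.cancer_thickness_um + 2.0 * self.voxel_um:
                raise PhantomGeometryError(
                    "island_depth_range_um starts too shallow: islands must clear the "
                    "cancer slab by >= 2 voxels"
                )
            if hi + r_max + margin > self.depth_um:
                raise PhantomGeometryError(
                    f"islands reach {hi + r_max + margin:.1f} um but volume depth is {self.depth_um:.1f} um"
                )

    def replace(self, **kwargs) -> "PhantomSpec":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_mean_intensity"] = {int(k): float(v) for k, v in self.class_mean_intensity.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "class_mean_intensity" in d:
            d["class_mean_intensity"] = {int(k): float(v) for k, v in d["class_mean_intensity"].items()}
        for key in ("lateral_size_um", "island_radius_um", "island_depth_range_um", "fibroblast_axis_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class ProgrammedTruth:
    """Exact truth for one phantom, computed by voxel enumeration at build time."""

    label_volume: LabelVolume
    true_baseline_z_um: float
    true_depth_of_invasion_um: float
    true_iccr_volume_um3: float
    true_invasion_fraction: float
    per_island_volumes_um3: list[float]


# ---------------------------------------------------------------------------
# label volume construction


def _rasterize_sphere(labels: np.ndarray, center: tuple[int, int, int], radius_vox: float,
                      value: int, clearance_mask: np.ndarray | None = None) -> int | None:
    """Set voxels whose centers lie within ``radius_vox`` of ``center`` (grid
    units) to ``value``.  If ``clearance_mask`` is given, first check that no
    voxel within ``radius_vox + 2`` is set in it; return None on conflict.
    Returns the number of voxels written."""
    nz, ny, nx = labels.shape
    cz, cy, cx = center
    r_chk = radius_vox + 2.0
    lo = [max(0, int(math.floor(c - r_chk))) for c in center]
    hi = [min(n, int(math.ceil(c + r_chk)) + 1) for c, n in zip(center, (nz, ny, nx))]
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    if clearance_mask is not None:
        if (clearance_mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] & (d2 <= r_chk ** 2)).any():
            return None
    inside = d2 <= radius_vox ** 2
    block = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    n_new = int((inside & (block != value)).sum())
    block[inside] = value
    return n_new


def _add_capsule(labels: np.ndarray, cx: int, cy: int, z_top: int, z_tip: int,
                 radius_vox: float) -> None:
    """Vertical capsule: cylinder from z_top to z_tip - radius, closed by a
    hemispherical cap with its apex at z_tip (exclusive lower bound)."""
    nz, ny, nx = labels.shape
    r = radius_vox
    x_lo, x_hi = max(0, int(cx - r) - 1), min(nx, int(cx + r) + 2)
    y_lo, y_hi = max(0, int(cy - r) - 1), min(ny, int(cy + r) + 2)
    z_hi = min(nz, z_tip)
    zz, yy, xx = np.ogrid[z_top:z_hi, y_lo:y_hi, x_lo:x_hi]
    lat2 = (yy - cy) ** 2 + (xx - cx) ** 2
    z_cap = z_tip - 1 - r  # sphere center of the cap
    in_cyl = (lat2 <= r ** 2) & (zz <= z_cap)
    in_cap = lat2 + (zz - z_cap) ** 2 <= r ** 2
    block = labels[z_top:z_hi, y_lo:y_hi, x_lo:x_hi]
    block[(in_cyl | in_cap) & (block == MATRIX)] = CANCER


def _add_cohesive_front(labels: np.ndarray, spec: PhantomSpec, seed: int) -> None:
    """Broad contiguous lobes: a smoothed random field selects ~30% of lateral
    columns whose cancer run is extended below the slab, up to finger_depth_um."""
    nz, ny, nx = labels.shape
    rng = np.random.default_rng([seed, _STREAM_COHESIVE])
    fld = rng.standard_normal((ny, nx))
    fld = gaussian_filter(fld, sigma=40.0 / spec.voxel_um, mode="wrap")
    fld = (fld - fld.mean()) / (fld.std() + 1e-12)
    thr = np.quantile(fld, 0.7)
    span = max(fld.max() - thr, 1e-12)
    dip_um = np.where(fld > thr, (fld - thr) / span * spec.finger_depth_um, 0.0)
    dip_vox = np.rint(dip_um / spec.voxel_um).astype(int)
    tc = int(round(spec.cancer_thickness_um / spec.voxel_um))
    zz = np.arange(nz)[:, None, None]
    ext = (zz >= tc) & (zz < tc + dip_vox[None, :, :])
    labels[ext & (labels == MATRIX)] = CANCER


def _add_fingers(labels: np.ndarray, spec: PhantomSpec, seed: int) -> None:
    nz, ny, nx = labels.shape
    tc = int(round(spec.cancer_thickness_um / spec.voxel_um))
    r = spec.finger_radius_um / spec.voxel_um
    margin = int(math.ceil(r)) + 2
    if nx <= 2 * margin or ny <= 2 * margin:
        raise PhantomGeometryError("lateral extent too small for the programmed finger radius")
    for i in range(spec.finger_count):
        rng = np.random.default_rng([seed, _STREAM_FINGER, i])
        cx = int(rng.integers(margin, nx - margin))
        cy = int(rng.integers(margin, ny - margin))
        z_tip = tc + int(round(spec.finger_depth_um / spec.voxel_um))
        # root the capsule a few voxels inside the slab: 26-connectivity is
        # then guaranteed by construction
        _add_capsule(labels, cx, cy, max(0, tc - 3), z_tip, r)


def _add_islands(labels: np.ndarray, spec: PhantomSpec, seed: int) -> list[int]:
    nz, ny, nx = labels.shape
    tc = int(round(spec.cancer_thickness_um / spec.voxel_um))
    mean_r, sd_r = spec.island_radius_um
    volumes: list[int] = []
    cancer = labels == CANCER
    for i in range(spec.island_count):
        rng = np.random.default_rng([seed, _STREAM_ISLAND, i])
        placed = False
        for _attempt in range(200):
            r_um = mean_r if sd_r == 0 else float(np.clip(rng.normal(mean_r, sd_r), 2.0 * spec.voxel_um, mean_r + 3 * sd_r))
            r = r_um / spec.voxel_um
            lo_z = max(int(math.ceil(spec.island_depth_range_um[0] / spec.voxel_um)), tc + 2 + int(math.ceil(r)))
            hi_z = int(math.floor(spec.island_depth_range_um[1] / spec.voxel_um))
            if hi_z < lo_z:
                raise PhantomGeometryError("island_depth_range_um admits no valid island center")
            marg = int(math.ceil(r)) + 1
            if nx <= 2 * marg or ny <= 2 * marg:
                raise PhantomGeometryError("lateral extent too small for the programmed island radius")
            cz = int(rng.integers(lo_z, hi_z + 1))
            cy = int(rng.integers(marg, ny - marg))
            cx = int(rng.integers(marg, nx - marg))
            n = _rasterize_sphere(labels, (cz, cy, cx), r, CANCER, clearance_mask=cancer)
            if n is not None:
                cancer = labels == CANCER
                volumes.append(n)
                placed = True
                break
        if not placed:
            raise PhantomGeometryError(
                f"could not place island {i} with >= 2-voxel clearance after 200 attempts"
            )
    return volumes


def _add_fibroblasts(labels: np.ndarray, spec: PhantomSpec, seed: int) -> None:
    nz, ny, nx = labels.shape
    rng = np.random.default_rng([seed, _STREAM_FIBRO])
    tc = int(round(spec.cancer_thickness_um / spec.voxel_um))
    stroma_mm3 = (
        spec.lateral_size_um[0] * spec.lateral_size_um[1] * (spec.depth_um - spec.cancer_thickness_um) * 1e-9
    )
    count = int(round(spec.fibroblast_density * stroma_mm3))
    a, b = (ax / spec.voxel_um for ax in spec.fibroblast_axis_um)
    pad = int(math.ceil(a)) + 1
    if count == 0 or nz - pad <= tc + pad:
        return
    for _ in range(count):
        cz = int(rng.integers(tc + pad, nz - pad))
        cy = int(rng.integers(0, ny))
        cx = int(rng.integers(0, nx))
        along_x = bool(rng.integers(0, 2))  # long axis along x or y
        ax_x, ax_y = (a, b) if along_x else (b, a)
        z_lo, z_hi = int(cz - b) - 1, int(cz + b) + 2
        y_lo, y_hi = max(0, int(cy - ax_y) - 1), min(ny, int(cy + ax_y) + 2)
        x_lo, x_hi = max(0, int(cx - ax_x) - 1), min(nx, int(cx + ax_x) + 2)
        zz, yy, xx = np.ogrid[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi]
        inside = ((zz - cz) / b) ** 2 + ((yy - cy) / ax_y) ** 2 + ((xx - cx) / ax_x) ** 2 <= 1.0
        block = labels[z_lo:z_hi, y_lo:y_hi, x_lo:x_hi]
        block[inside & (block == MATRIX)] = STROMAL_CELL


def build_label_volume(spec: PhantomSpec, seed: int | None = None) -> ProgrammedTruth:
    """Build the semantic label volume and its exact programmed truth.

    Deterministic given ``(spec, seed)``; ``seed`` defaults to ``spec.seed``.
    Raises :class:`PhantomGeometryError` when a programmed structure cannot
    fit — structures are never silently clipped.
    """
    spec.validate()
    seed = spec.seed if seed is None else int(seed)
    nz, ny, nx = spec.shape
    if min(nz, ny, nx) < 8:
        raise PhantomGeometryError("volume must be at least 8 voxels along every axis")

    labels = np.full((nz, ny, nx), MATRIX, dtype=np.uint8)
    tc = int(round(spec.cancer_thickness_um / spec.voxel_um))
    labels[:tc] = CANCER

    island_volumes: list[int] = []
    if spec.invasion_pattern == "cohesive":
        _add_cohesive_front(labels, spec, seed)
    elif spec.invasion_pattern == "finger":
        _add_fingers(labels, spec, seed)
    elif spec.invasion_pattern == "island":
        island_volumes = _add_islands(labels, spec, seed)
    elif spec.invasion_pattern == "mixed":
        _add_fingers(labels, spec, seed)
        island_volumes = _add_islands(labels, spec, seed)
    _add_fibroblasts(labels, spec, seed)

    # truth by direct voxel enumeration
    cancer = labels == CANCER
    zz = np.arange(nz)[:, None, None]
    n_total = int(cancer.sum())
    n_below = int((cancer & (zz >= tc)).sum())
    vox3 = spec.voxel_um ** 3
    if n_below:
        z_max = int(np.max(np.nonzero(cancer.any(axis=(1, 2)))[0]))
        doi = max(0.0, (z_max + 1) * spec.voxel_um - spec.cancer_thickness_um)
    else:
        doi = 0.0

    lv = LabelVolume(data=labels, voxel_um=spec.voxel_um,
                     provenance=f"phantom pattern={spec.invasion_pattern} seed={seed}")
    return ProgrammedTruth(
        label_volume=lv,
        true_baseline_z_um=spec.cancer_thickness_um,
        true_depth_of_invasion_um=doi,
        true_iccr_volume_um3=n_below * vox3,
        true_invasion_fraction=(n_below / n_total) if n_total else 0.0,
        per_island_volumes_um3=[v * vox3 for v in island_volumes],
    )


# ---------------------------------------------------------------------------
# OCT-style rendering


def render_oct(truth: ProgrammedTruth | LabelVolume, spec: PhantomSpec,
               seed: int | None = None) -> OCTVolume:
    """Render a label volume into a 16-bit OCT-like intensity volume.

    ``intensity = class_mean * exp(-attenuation * z_um) * speckle``, then
    anisotropic Gaussian blur at the PSF FWHMs, additive Gaussian read noise,
    clamping to [0, 65535] and integer quantization.  Deterministic given
    ``(spec, seed)``.
    """
    spec.validate()
    seed = spec.seed if seed is None else int(seed)
    labels = truth.label_volume.data if isinstance(truth, ProgrammedTruth) else truth.data
    nz = labels.shape[0]

    lut = np.zeros(max(spec.class_mean_intensity) + 1, dtype=np.float32)
    for code, mean in spec.class_mean_intensity.items():
        lut[code] = mean
    img = lut[labels]

    if spec.attenuation_per_um > 0:
        z_um = np.arange(nz, dtype=np.float32) * spec.voxel_um
        img *= np.exp(-spec.attenuation_per_um * z_um)[:, None, None]

    k = spec.speckle_shape
    if k is not None and np.isfinite(k):
        rng = np.random.default_rng([seed, _STREAM_SPECKLE])
        img *= rng.gamma(k, 1.0 / k, size=img.shape).astype(np.float32)

    sig_ax = spec.psf_axial_fwhm_um * _FWHM_TO_SIGMA / spec.voxel_um
    sig_lat = spec.psf_lateral_fwhm_um * _FWHM_TO_SIGMA / spec.voxel_um
    if sig_ax > 0 or sig_lat > 0:
        img = gaussian_filter(img, sigma=(sig_ax, sig_lat, sig_lat))

    if spec.read_noise_sd > 0:
        rng = np.random.default_rng([seed, _STREAM_READNOISE])
        img += rng.normal(0.0, spec.read_noise_sd, size=img.shape).astype(np.float32)

    data = np.rint(np.clip(img, 0.0, 65535.0)).astype(np.uint16)
    return OCTVolume(data=data, voxel_um=spec.voxel_um,
                     provenance=f"rendered phantom pattern={spec.invasion_pattern} seed={seed}")


def extract_slice(volume, axis: str, index: int) -> np.ndarray:
    """Extract a 2D plane: ``XY`` fixes z (en-face), ``XZ`` fixes y
    (cross-section, rows = depth). Values are returned unchanged."""
    data = getattr(volume, "data", volume)
    axis = axis.upper()
    if axis == "XY":
        n = data.shape[0]
    elif axis == "XZ":
        n = data.shape[1]
    else:
        raise ValueError(f"axis must be 'XY' or 'XZ', got {axis!r}")
    if not (0 <= index < n):
        raise IndexError(f"slice index {index} out of range [0, {n}) for axis {axis}")
    return data[index] if axis == "XY" else data[:, index, :]
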