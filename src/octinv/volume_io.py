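"""Volume, label and metric-table I/O with contract enforcement.

Intensity volumes are multi-page 16-bit grayscale TIFF (one page per z,
pages ordered z-ascending from the top surface — the depth convention is
load-bearing for every metric and is written into, and asserted from, the
TIFF metadata).  Label volumes are 8-bit TIFF with a JSON sidecar mapping
class codes.  Metric tables are UTF-8 CSV with '.' decimal.  All integer
I/O is lossless; nothing is ever rescaled silently.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

AXIS_ORDER = "zyx"
PAGE_ORDER = "z-ascending-from-top"
CLASS_CODES = {0: "medium", 1: "cancer", 2: "stromal cell", 3: "matrix"}

METRIC_COLUMNS = [
    "model_id", "cell_line", "stroma", "day", "replicate",
    "v_total_um3", "v_original_um3", "v_iccr_um3",
    "hif_area_um2", "mass_invasion_index", "depth_of_invasion_um",
]


class VolumeFormatError(ValueError):
    """The on-disk data violates the volume format contract."""


class VolumeReadError(IOError):
    """A page of a TIFF stack could not be decoded."""


def _check_grid(data: np.ndarray, kind: str) -> None:
    if data.ndim != 3:
        raise VolumeFormatError(f"{kind} must be 3-dimensional (z, y, x), got ndim={data.ndim}")
    if min(data.shape) < 8:
        raise VolumeFormatError(f"{kind} must be >= 8 voxels along every axis, got shape={data.shape}")


@dataclass
class OCTVolume:
    """A 3D intensity grid in 16-bit range with isotropic voxel size.

    ``data`` has axis order (z, y, x) with z = depth from the top surface.
    """

    data: np.ndarray
    voxel_um: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeFormatError(f"intensity volume must be integer-typed, got {self.data.dtype}")
        _check_grid(self.data, "intensity volume")
        if self.data.size and (int(self.data.min()) < 0 or int(self.data.max()) > 65535):
            raise VolumeFormatError("intensity values outside [0, 65535]")
        if self.voxel_um <= 0:
            raise VolumeFormatError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Per-voxel semantic class codes: 0 medium, 1 cancer, 2 stromal cell, 3 matrix."""

    data: np.ndarray
    voxel_um: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeFormatError(f"label volume must be integer-typed, got {self.data.dtype}")
        _check_grid(self.data, "label volume")
        present = set(np.unique(self.data).tolist())
        if not present <= set(CLASS_CODES):
            raise VolumeFormatError(f"undeclared class codes present: {sorted(present - set(CLASS_CODES))}")
        if self.voxel_um <= 0:
            raise VolumeFormatError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def cancer_mask(self) -> np.ndarray:
        return self.data == 1


# ---------------------------------------------------------------------------
# TIFF stacks


def _metadata_json(voxel_um: float, provenance: str) -> str:
    return json.dumps({"voxel_um": voxel_um, "axis_order": AXIS_ORDER,
                       "page_order": PAGE_ORDER, "provenance": provenance})


def write_volume(volume: OCTVolume, path: str | os.PathLike) -> None:
    """Write a 16-bit multi-page grayscale TIFF, one page per z."""
    data = volume.data.astype(np.uint16, casting="safe") if volume.data.dtype != np.uint16 else volume.data
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=_metadata_json(volume.voxel_um, volume.provenance))


def _read_stack(path: str | os.PathLike, expect_dtype: np.dtype, kind: str):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    with tifffile.TiffFile(path) as tif:
        first = tif.pages[0]
        dtype = first.dtype
        if dtype != expect_dtype:
            raise VolumeFormatError(
                f"{path}: expected {np.dtype(expect_dtype).name} samples for a {kind}, got {dtype.name}"
            )
        planes = []
        shapes = set()
        for i in range(len(tif.pages)):
            try:
                page = tif.pages[i]
                shapes.add(page.shape)
                planes.append(page.asarray())
            except (VolumeFormatError, VolumeReadError):
                raise
            except Exception as exc:  # corrupt/truncated page or IFD
                raise VolumeReadError(f"{path}: failed to decode page {i}: {exc}") from exc
        if len(shapes) != 1:
            raise VolumeFormatError(f"{path}: mixed page shapes {sorted(shapes)}")
        data = np.stack(planes, axis=0)
        meta = {}
        desc = first.description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if meta.get("page_order", PAGE_ORDER) != PAGE_ORDER:
        raise VolumeFormatError(f"{path}: unsupported page order {meta.get('page_order')!r}")
    return data, meta


def read_volume(path: str | os.PathLike) -> OCTVolume:
    """Read a 16-bit intensity stack written by :func:`write_volume`.

    Raises :class:`VolumeFormatError` on dtype or page-shape mismatches and
    :class:`VolumeReadError` (naming the page) on truncated pages.
    """
    data, meta = _read_stack(path, np.dtype(np.uint16), "intensity volume")
    return OCTVolume(data=data, voxel_um=float(meta.get("voxel_um", 1.0)),
                     provenance=str(meta.get("provenance", "")))


def write_labels(labels: LabelVolume, path: str | os.PathLike) -> None:
    """Write an 8-bit label stack plus a ``<path>.json`` class-code sidecar."""
    tifffile.imwrite(path, labels.data.astype(np.uint8), photometric="minisblack",
                     description=_metadata_json(labels.voxel_um, labels.provenance))
    with open(f"{path}.json", "w", encoding="utf-8") as fh:
        json.dump({"class_codes": {str(k): v for k, v in CLASS_CODES.items()},
                   "voxel_um": labels.voxel_um}, fh, indent=2)


def read_labels(path: str | os.PathLike) -> LabelVolume:
    data, meta = _read_stack(path, np.dtype(np.uint8), "label volume")
    return LabelVolume(data=data, voxel_um=float(meta.get("voxel_um", 1.0)),
                       provenance=str(meta.get("provenance", "")))


# ---------------------------------------------------------------------------
# metric tables


def write_metrics(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the invasion-metrics table as CSV; floats keep full precision.

    Requires the canonical columns (:data:`METRIC_COLUMNS`) and finite metric
    values in every row.
    """
    missing = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    numeric = ["v_total_um3", "v_original_um3", "v_iccr_um3",
               "hif_area_um2", "mass_invasion_index", "depth_of_invasion_um"]
    for col in numeric:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float)) if len(values) else np.array([], bool)
        if bad.any():
            raise ValueError(f"non-finite value in column {col!r} at rows {list(np.where(bad)[0])}")
    table[METRIC_COLUMNS].to_csv(path, index=False)


def read_metrics(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
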