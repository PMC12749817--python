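"""Partition of the cancer mask into the original region and the ICCR.

The baseline plane (the bottom of the original, seeded cancer layer) is
estimated as the robust mode of the per-column bottoms of the
contiguous-from-top cancer runs.  The original region is then defined
geometrically as cancer at depth <= baseline and the invasive cancer-cell
region (ICCR) as cancer below it, which keeps the volume conservation
``original + invasive = total`` exact by construction; a per-voxel
connectivity flag distinguishes invasive cancer that is 26-connected to the
original mass (fingers) from detached islands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


class NoOriginalRegionError(ValueError):
    """No cancer is present near the top surface; the baseline is undefined."""


@dataclass
class RegionPartition:
    """Cancer mask split at the baseline plane.

    ``original_mask | invasive_mask == cancer_mask`` exactly, with empty
    intersection; ``connected_to_original`` flags invasive voxels that have a
    26-connected path of cancer voxels to the original region.
    """

    cancer_mask: np.ndarray
    baseline_z_um: float
    original_mask: np.ndarray
    invasive_mask: np.ndarray
    connected_to_original: np.ndarray
    voxel_um: float


def estimate_baseline(cancer_mask: np.ndarray, voxel_um: float = 1.0,
                      top_fraction: float = 0.1, mode_support: float = 0.05) -> float:
    """Estimate the baseline depth (um) below which cancer counts as invasive.

    For every lateral column whose cancer surface starts within the top
    ``top_fraction`` of the depth range, the bottom of the contiguous-from-top
    cancer run is recorded; the baseline is the mode of those bottoms (ties
    resolved toward smaller depth), falling back to the median when the mode
    holds less than ``mode_support`` of the columns.
    """
    mask = np.asarray(cancer_mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("cancer_mask must be 3D (z, y, x)")
    nz = mask.shape[0]
    top = max(1, int(np.ceil(top_fraction * nz)))
    if not mask[:top].any():
        raise NoOriginalRegionError(
            f"no cancer voxels in the top {top_fraction:.0%} of the depth range; "
            "cannot locate the original cancer region"
        )
    has_cancer = mask.any(axis=0)
    z_first = np.argmax(mask, axis=0)  # first cancer voxel per column
    valid = has_cancer & (z_first < top)

    zz = np.arange(nz)[:, None, None]
    gap = (~mask) & (zz >= z_first[None])
    has_gap = gap.any(axis=0)
    bottoms = np.where(has_gap, np.argmax(gap, axis=0), nz)  # run ends at first gap
    bottoms = bottoms[valid]

    counts = np.bincount(bottoms, minlength=nz + 1)
    mode = int(np.argmax(counts))  # argmax returns the first (shallowest) tie
    if counts[mode] < mode_support * bottoms.size:
        mode = int(np.median(bottoms))
    return mode * voxel_um


def partition_cancer(cancer_mask: np.ndarray, baseline_z_um: float,
                     voxel_um: float = 1.0) -> RegionPartition:
    """Split cancer at the baseline plane and flag connectivity to the original.

    A single 26-connected component sweep through cancer voxels implements
    the flood fill from the original region.
    """
    mask = np.asarray(cancer_mask, dtype=bool)
    nz = mask.shape[0]
    b = int(round(baseline_z_um / voxel_um))
    if not (0 <= b <= nz):
        raise ValueError(f"baseline {baseline_z_um} um outside the volume depth")
    zz = np.arange(nz)[:, None, None]
    original = mask & (zz < b)
    invasive = mask & (zz >= b)

    connected = np.zeros_like(mask)
    if original.any() and invasive.any():
        lbl = _cc_label(mask, connectivity=3)
        orig_ids = np.unique(lbl[original])
        orig_ids = orig_ids[orig_ids > 0]
        connected = invasive & np.isin(lbl, orig_ids)
    return RegionPartition(cancer_mask=mask, baseline_z_um=b * voxel_um,
                           original_mask=original, invasive_mask=invasive,
                           connected_to_original=connected, voxel_um=voxel_um)


def label_components(mask: np.ndarray, connectivity: int = 26, voxel_um: float = 1.0,
                     reference_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Enumerate connected objects in a binary mask (3D object counter).

    Returns a table with one row per object: dense ``id`` from 1,
    ``voxel_count``, ``volume_um3``, bounding box, centroid (voxel indices),
    and ``touches_original`` — whether the object overlaps or is 26-adjacent
    to ``reference_mask`` (False everywhere when no reference is given).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("label_components expects a 3D mask")
    columns = ["id", "voxel_count", "volume_um3",
               "bbox_zmin", "bbox_ymin", "bbox_xmin", "bbox_zmax", "bbox_ymax", "bbox_xmax",
               "centroid_z", "centroid_y", "centroid_x", "touches_original"]
    if not mask.any():
        return pd.DataFrame(columns=columns)
    lbl = _cc_label(mask, connectivity=_CONNECTIVITY[connectivity])
    touching_ids: set[int] = set()
    if reference_mask is not None and reference_mask.any():
        ref = binary_dilation(np.asarray(reference_mask, dtype=bool),
                              structure=np.ones((3,) * mask.ndim, dtype=bool))
        touching_ids = set(np.unique(lbl[ref]).tolist()) - {0}
    rows = []
    for rp in regionprops(lbl):
        rows.append({
            "id": rp.label,
            "voxel_count": int(rp.area),
            "volume_um3": float(rp.area) * voxel_um ** 3,
            "bbox_zmin": rp.bbox[0], "bbox_ymin": rp.bbox[1], "bbox_xmin": rp.bbox[2],
            "bbox_zmax": rp.bbox[3], "bbox_ymax": rp.bbox[4], "bbox_xmax": rp.bbox[5],
            "centroid_z": rp.centroid[0], "centroid_y": rp.centroid[1], "centroid_x": rp.centroid[2],
            "touches_original": rp.label in touching_ids,
        })
    return pd.DataFrame(rows, columns=columns)


def partition_codes(partition: RegionPartition) -> np.ndarray:
    """8-bit code volume: 0 none, 1 original, 2 invasive-connected, 3 invasive-detached."""
    codes = np.zeros(partition.cancer_mask.shape, dtype=np.uint8)
    codes[partition.original_mask] = 1
    codes[partition.invasive_mask & partition.connected_to_original] = 2
    codes[partition.invasive_mask & ~partition.connected_to_original] = 3
    return codes
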