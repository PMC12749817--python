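"""Volumetric and planimetric invasion metrics.

3D: total/original/ICCR volumes by exact voxel counting, the invasion-front
height field and its triangulated surface area, the mass invasion index and
the depth of invasion.  2D: per-field depth of invasion and invasion index
on labeled sections, mirroring the histomorphometric protocol (five random
high-power fields per section).

Depth convention: the voxel at index z spans depths [z, z+1) voxel units, so
the lower face of the deepest cancer voxel — at ``(z + 1) * voxel_um`` — is
the front position used for the height field and the depth of invasion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from octinv.partition import RegionPartition, estimate_baseline

logger = logging.getLogger(__name__)

MASS_INDEX_FORMS = ("invasive_fraction", "printed")


@dataclass
class InvasionMetrics3D:
    v_total_um3: float
    v_original_um3: float
    v_iccr_um3: float
    hif_area_um2: float
    mass_invasion_index: float
    depth_of_invasion_um: float


@dataclass
class SectionMetrics2D:
    """Per-field 2D histomorphometric results for one section."""

    baseline_z_um: float
    field_origins_um: list[float]
    field_width_um: float
    depth_of_invasion_um: list[float] = field(default_factory=list)
    invasion_index: list[float] = field(default_factory=list)

    @property
    def n_fields(self) -> int:
        return len(self.field_origins_um)


# ---------------------------------------------------------------------------
# volumes


def iccr_volume(partition: RegionPartition) -> tuple[float, float, float]:
    """(v_iccr, v_total, v_original) in um^3, by exact voxel counts.

    ``v_iccr = v_total - v_original`` holds exactly: the partition masks are
    disjoint and cover the cancer mask by construction.
    """
    vox3 = partition.voxel_um ** 3
    v_total = float(partition.cancer_mask.sum()) * vox3
    v_original = float(partition.original_mask.sum()) * vox3
    v_iccr = float(partition.invasive_mask.sum()) * vox3
    return v_iccr, v_total, v_original


def mass_invasion_index(partition: RegionPartition, form: str = "invasive_fraction") -> float:
    """Volumetric invasion index in [0, 1].

    Default ``invasive_fraction`` returns ``v_iccr / v_total`` so that 0 means
    no infiltration and 1 complete infiltration, matching the 2D invasion
    index's anchor values; ``printed`` returns the complementary form
    ``1 - v_iccr / v_total``.
    """
    if form not in MASS_INDEX_FORMS:
        raise ValueError(f"form must be one of {MASS_INDEX_FORMS}")
    v_iccr, v_total, _ = iccr_volume(partition)
    if v_total == 0:
        raise ValueError("mass invasion index undefined: no cancer voxels (v_total = 0)")
    frac = v_iccr / v_total
    return frac if form == "invasive_fraction" else 1.0 - frac


def depth_of_invasion_3d(partition: RegionPartition) -> float:
    """Maximum vertical distance (um) from the baseline plane to the deepest
    cancer voxel's lower face, floored at 0."""
    mask = partition.cancer_mask
    if not mask.any():
        return 0.0
    z_max = int(np.max(np.nonzero(mask.any(axis=(1, 2)))[0]))
    return max(0.0, (z_max + 1) * partition.voxel_um - partition.baseline_z_um)


# ---------------------------------------------------------------------------
# invasion-front surface


def hif_height_map(partition: RegionPartition) -> np.ndarray:
    """Depth (um) of the invasion front per lateral column.

    The front is the lower envelope of the cancer mass contiguous with the
    original region: for each (y, x) column, the lower face of the deepest
    cancer voxel that is original or 26-connected to the original region.
    Detached islands are excluded by construction; columns without contiguous
    cancer fall back to the baseline depth.
    """
    if not partition.original_mask.any():
        raise ValueError("no original region: invasion front undefined")
    contiguous = partition.original_mask | partition.connected_to_original
    nz = contiguous.shape[0]
    any_col = contiguous.any(axis=0)
    z_deepest = nz - 1 - np.argmax(contiguous[::-1], axis=0)
    heights = np.where(any_col, (z_deepest + 1) * partition.voxel_um, partition.baseline_z_um)
    if not any_col.all():
        logger.info("hif_height_map: %d columns without contiguous cancer filled with the baseline",
                    int((~any_col).sum()))
    return heights.astype(np.float64)


def hif_surface_area(height_map: np.ndarray, voxel_um: float) -> float:
    """Surface area (um^2) of a height field by triangulation.

    Heights sit at column centers ``(i + 1/2) * voxel_um``; edge values are
    replicated onto the ROI boundary (half-voxel edge replication), so the
    planform of the triangulation is exactly the lateral ROI and a flat front
    over an Lx x Ly ROI has area exactly Lx * Ly.  Each lateral cell
    contributes two triangles.
    """
    hm = np.asarray(height_map, dtype=np.float64)
    if hm.ndim != 2:
        raise ValueError("height_map must be 2D (y, x)")
    ny, nx = hm.shape
    z = np.pad(hm, 1, mode="edge")
    xs = np.concatenate(([0.0], (np.arange(nx) + 0.5) * voxel_um, [nx * voxel_um]))
    ys = np.concatenate(([0.0], (np.arange(ny) + 0.5) * voxel_um, [ny * voxel_um]))
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    P = np.stack([X, Y, z], axis=-1)  # (ny+2, nx+2, 3)

    A = P[:-1, :-1]
    B = P[:-1, 1:]
    C = P[1:, :-1]
    D = P[1:, 1:]
    t1 = np.cross(B - A, D - A)
    t2 = np.cross(D - A, C - A)
    area = 0.5 * (np.linalg.norm(t1, axis=-1) + np.linalg.norm(t2, axis=-1))
    return float(area.sum())


# ---------------------------------------------------------------------------
# 2D section metrics


def invasion_index_2d(cancer_section: np.ndarray, baseline_z_um: float,
                      voxel_um: float = 1.0) -> float:
    """``1 - area(original) / area(total)`` on a 2D cancer mask (rows = depth).

    0 means the cancer layer sits entirely above the baseline (no
    infiltration); 1 means every cancer pixel lies below it (complete
    infiltration).
    """
    mask = np.asarray(cancer_section, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("cancer_section must be 2D (z, x)")
    total = int(mask.sum())
    if total == 0:
        raise ValueError("no cancer in section: invasion index undefined")
    b = int(round(baseline_z_um / voxel_um))
    original = int(mask[:b].sum())
    return 1.0 - original / total


def section_metrics(label_slice: np.ndarray, voxel_um: float = 1.0, n_fields: int = 5,
                    field_width_um: float = 100.0, seed: int = 0,
                    baseline_z_um: float | None = None,
                    cancer_code: int = 1) -> SectionMetrics2D:
    """Per-field depth of invasion and invasion index on an X-Z label section.

    Fields are lateral windows of ``field_width_um`` placed at seeded random
    non-overlapping origins; fields containing no cancer are skipped and
    logged.  The baseline is estimated from the section itself unless given.
    """
    lab = np.asarray(label_slice)
    if lab.ndim != 2:
        raise ValueError("label_slice must be 2D (z, x)")
    mask = lab == cancer_code
    if not mask.any():
        raise ValueError("no cancer in slice")
    if baseline_z_um is None:
        baseline_z_um = estimate_baseline(mask[:, :, None], voxel_um)  # treat as (z, y=x, x=1)
    nz, nx = mask.shape
    w = max(1, int(round(field_width_um / voxel_um)))
    n_slots = nx // w
    if n_slots == 0:
        raise ValueError(f"field width {field_width_um} um exceeds section width {nx * voxel_um} um")
    rng = np.random.default_rng(seed)
    slots = rng.choice(n_slots, size=min(n_fields, n_slots), replace=False)

    out = SectionMetrics2D(baseline_z_um=baseline_z_um, field_origins_um=[],
                           field_width_um=w * voxel_um)
    b = int(round(baseline_z_um / voxel_um))
    for s in sorted(int(s) for s in slots):
        fld = mask[:, s * w:(s + 1) * w]
        if not fld.any():
            logger.info("section_metrics: field at %g um contains no cancer; skipped", s * w * voxel_um)
            continue
        out.field_origins_um.append(s * w * voxel_um)
        out.invasion_index.append(invasion_index_2d(fld, baseline_z_um, voxel_um))
        rows = np.nonzero(fld.any(axis=1))[0]
        out.depth_of_invasion_um.append(max(0.0, (int(rows.max()) + 1 - b) * voxel_um))
    return out


def compute_metrics_3d(partition: RegionPartition,
                       mass_index_form: str = "invasive_fraction") -> InvasionMetrics3D:
    """All 3D metrics for one partition."""
    v_iccr, v_total, v_original = iccr_volume(partition)
    area = hif_surface_area(hif_height_map(partition), partition.voxel_um)
    return InvasionMetrics3D(
        v_total_um3=v_total,
        v_original_um3=v_original,
        v_iccr_um3=v_iccr,
        hif_area_um2=area,
        mass_invasion_index=mass_invasion_index(partition, mass_index_form),
        depth_of_invasion_um=depth_of_invasion_3d(partition),
    )
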