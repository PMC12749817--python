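"""Invasion metrics: volumes, front surface area, indexes, 2D sections."""

import numpy as np
import pytest

from octinv import (
    build_label_volume,
    depth_of_invasion_3d,
    extract_slice,
    hif_height_map,
    hif_surface_area,
    iccr_volume,
    invasion_index_2d,
    mass_invasion_index,
    partition_cancer,
    section_metrics,
)
from octinv.metrics import compute_metrics_3d
from octinv.phantom import CANCER

from conftest import small_spec

SPHERE_R10_VOXELS = 4169  # frozen discrete-sphere oracle (see test_phantom)


def _slab_mask(nz=60, ny=20, nx=20, thickness=30):
    mask = np.zeros((nz, ny, nx), dtype=bool)
    mask[:thickness] = True
    return mask


def quadrature_area(height_fn, lx, ly, step=0.1):
    """Independent oracle: fine-grid quadrature of the surface-area integral
    A = integral sqrt(1 + zx^2 + zy^2) dx dy via central differences."""
    xs = np.arange(0, lx + step / 2, step)
    ys = np.arange(0, ly + step / 2, step)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    Z = height_fn(X, Y)
    zx = np.gradient(Z, step, axis=1)
    zy = np.gradient(Z, step, axis=0)
    integrand = np.sqrt(1.0 + zx ** 2 + zy ** 2)
    return float(np.trapezoid(np.trapezoid(integrand, dx=step, axis=1), dx=step))


# ---------------------------------------------------------------------------
# volumes and indexes


def test_iccr_slab_only_zero():
    part = partition_cancer(_slab_mask(), 30.0)
    v_iccr, v_total, v_original = iccr_volume(part)
    assert v_iccr == 0.0
    assert v_total == v_original == 30 * 20 * 20


def test_iccr_detached_island_exact_count():
    spec = small_spec(invasion_pattern="island", island_count=1, island_radius_um=(10.0, 0.0))
    truth = build_label_volume(spec, seed=2)
    part = partition_cancer(truth.label_volume.cancer_mask(), truth.true_baseline_z_um)
    v_iccr, _, _ = iccr_volume(part)
    assert v_iccr == SPHERE_R10_VOXELS


def test_conservation_identity_every_pattern():
    for pattern in ("none", "cohesive", "finger", "island", "mixed"):
        truth = build_label_volume(small_spec(invasion_pattern=pattern), seed=4)
        part = partition_cancer(truth.label_volume.cancer_mask(), truth.true_baseline_z_um)
        v_iccr, v_total, v_original = iccr_volume(part)
        assert v_total - v_original - v_iccr == 0.0


def test_mass_invasion_index_forms():
    mask = _slab_mask()
    mask[40:50, 5:15, 5:15] = True  # 1000 invasive voxels
    part = partition_cancer(mask, 30.0)
    v_iccr, v_total, _ = iccr_volume(part)
    assert mass_invasion_index(part) == pytest.approx(v_iccr / v_total)
    assert mass_invasion_index(part, form="printed") == pytest.approx(1 - v_iccr / v_total)
    with pytest.raises(ValueError):
        mass_invasion_index(part, form="bogus")


def test_mass_invasion_index_arithmetic():
    """2000 invasive / 10000 total -> 0.2 exactly."""
    mask = np.zeros((40, 25, 20), dtype=bool)
    mask[:16, :25, :20] = True  # 8000 original
    mask[20:24, :25, :20] = True  # 10000 total needs 2000 more
    part = partition_cancer(mask, 16.0)
    assert iccr_volume(part)[1] == 10000.0
    assert mass_invasion_index(part) == pytest.approx(0.2)


def test_mass_invasion_index_limits():
    no_inv = partition_cancer(_slab_mask(), 30.0)
    assert mass_invasion_index(no_inv) == 0.0
    all_below = np.zeros((60, 20, 20), dtype=bool)
    all_below[35:45] = True
    part = partition_cancer(all_below, 30.0)
    assert mass_invasion_index(part) == 1.0
    empty = partition_cancer(np.zeros((10, 5, 5), dtype=bool), 3.0)
    with pytest.raises(ValueError):
        mass_invasion_index(empty)


def test_depth_of_invasion():
    assert depth_of_invasion_3d(partition_cancer(_slab_mask(), 30.0)) == 0.0
    mask = _slab_mask(nz=200, thickness=100)
    mask[100:150, 10, 10] = True  # tip lower face at 150 um
    part = partition_cancer(mask, 100.0)
    assert depth_of_invasion_3d(part) == 50.0


# ---------------------------------------------------------------------------
# invasion-front surface


def test_flat_front_area_exact():
    hm = np.full((500, 500), 120.0)
    assert hif_surface_area(hm, 1.0) == pytest.approx(250_000.0, abs=1e-6)
    hm_small = np.full((20, 30), 7.0)
    assert hif_surface_area(hm_small, 1.0) == pytest.approx(600.0, abs=1e-9)
    assert hif_surface_area(np.full((10, 10), 5.0), 2.0) == pytest.approx(400.0, abs=1e-9)


def test_sinusoid_front_matches_quadrature_oracle():
    lam, amp = 100.0, 20.0
    nx = ny = 200
    xs = (np.arange(nx) + 0.5)
    hm = 50.0 + amp * np.sin(2 * np.pi * xs / lam)[None, :].repeat(ny, axis=0)
    area = hif_surface_area(hm, 1.0)
    oracle = quadrature_area(lambda X, Y: 50.0 + amp * np.sin(2 * np.pi * X / lam), nx, ny)
    assert abs(area - oracle) / oracle < 0.01


def test_area_at_least_planform_and_monotone_in_amplitude():
    ny = nx = 64
    xs = np.arange(nx) + 0.5
    areas = []
    for amp in (0.0, 5.0, 10.0, 20.0):
        hm = 40.0 + amp * np.sin(2 * np.pi * xs / 32.0)[None, :].repeat(ny, axis=0)
        a = hif_surface_area(hm, 1.0)
        assert a >= nx * ny - 1e-9
        areas.append(a)
    assert areas == sorted(areas)
    assert areas[0] == pytest.approx(nx * ny)
    assert areas[-1] > areas[0]


def test_height_map_excludes_detached_islands():
    mask = _slab_mask()
    part_plain = partition_cancer(mask.copy(), 30.0)
    with_island = mask.copy()
    with_island[45:50, 8:12, 8:12] = True
    part_island = partition_cancer(with_island, 30.0)
    hm_plain = hif_height_map(part_plain)
    hm_island = hif_height_map(part_island)
    assert np.array_equal(hm_plain, hm_island)
    assert hif_surface_area(hm_plain, 1.0) == hif_surface_area(hm_island, 1.0)


def test_height_map_follows_connected_finger():
    mask = _slab_mask()
    mask[30:50, 10, 10] = True
    part = partition_cancer(mask, 30.0)
    hm = hif_height_map(part)
    assert hm[10, 10] == 50.0
    assert hm[0, 0] == 30.0


def test_height_map_requires_original():
    empty = partition_cancer(np.zeros((10, 5, 5), dtype=bool), 3.0)
    with pytest.raises(ValueError, match="no original region"):
        hif_height_map(empty)


# ---------------------------------------------------------------------------
# 2D section metrics


def test_invasion_index_2d_limits():
    sec = np.zeros((40, 30), dtype=bool)
    sec[:20] = True
    assert invasion_index_2d(sec, 20.0) == 0.0
    below = np.zeros((40, 30), dtype=bool)
    below[25:35] = True
    assert invasion_index_2d(below, 20.0) == 1.0
    with pytest.raises(ValueError):
        invasion_index_2d(np.zeros((10, 10), dtype=bool), 5.0)


def test_invasion_index_2d_equal_blocks():
    """One 50x50 original block and one 50x50 invasive block -> 0.5."""
    sec = np.zeros((200, 120), dtype=bool)
    sec[50:100, 10:60] = True   # above baseline 100
    sec[120:170, 10:60] = True  # below
    assert invasion_index_2d(sec, 100.0) == 0.5


def test_section_metrics_no_infiltration_phantom():
    truth = build_label_volume(small_spec(invasion_pattern="none"), seed=0)
    sec = extract_slice(truth.label_volume, "XZ", 10)
    sm = section_metrics(sec, n_fields=5, field_width_um=16.0, seed=1)
    assert sm.n_fields >= 1
    assert all(v == 0.0 for v in sm.invasion_index)
    assert all(v == 0.0 for v in sm.depth_of_invasion_um)


def test_section_metrics_complete_infiltration():
    sec = np.zeros((60, 64), dtype=np.uint8)
    sec[35:45] = CANCER  # original layer fully consumed
    sm = section_metrics(sec, n_fields=4, field_width_um=16.0, seed=1, baseline_z_um=30.0)
    assert all(v == 1.0 for v in sm.invasion_index)


def test_section_metrics_seeded_and_skips_empty_fields(caplog):
    sec = np.zeros((60, 64), dtype=np.uint8)
    sec[:30, :16] = CANCER  # cancer only in the first quarter
    with caplog.at_level("INFO", logger="octinv.metrics"):
        sm = section_metrics(sec, n_fields=4, field_width_um=16.0, seed=3)
    assert sm.n_fields < 4  # empty fields skipped
    sm2 = section_metrics(sec, n_fields=4, field_width_um=16.0, seed=3)
    assert sm.field_origins_um == sm2.field_origins_um
    with pytest.raises(ValueError, match="no cancer"):
        section_metrics(np.zeros((20, 20), dtype=np.uint8))


def test_mass_index_equals_2d_index_on_laterally_uniform_volume():
    """Tile one X-Z section along y: the 3D invasive fraction equals the 2D
    index computed on the section with the same baseline, exactly."""
    sec = np.zeros((80, 48), dtype=bool)
    sec[:30] = True
    sec[30:55, 10:20] = True  # connected tongue below the baseline
    vol = np.repeat(sec[:, None, :], 32, axis=1)
    part = partition_cancer(vol, 30.0)
    assert mass_invasion_index(part) == pytest.approx(invasion_index_2d(sec, 30.0), abs=1e-15)


def test_compute_metrics_3d_bundle():
    truth = build_label_volume(small_spec(invasion_pattern="finger"), seed=5)
    part = partition_cancer(truth.label_volume.cancer_mask(), truth.true_baseline_z_um)
    m = compute_metrics_3d(part)
    assert m.v_iccr_um3 == truth.true_iccr_volume_um3
    assert m.v_total_um3 - m.v_original_um3 - m.v_iccr_um3 == 0.0
    assert m.depth_of_invasion_um == truth.true_depth_of_invasion_um
    assert m.hif_area_um2 >= 64 * 64
    assert 0.0 <= m.mass_invasion_index <= 1.0
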