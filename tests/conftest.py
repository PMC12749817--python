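"""Shared fixtures: small phantoms and a classifier trained once per session."""

from __future__ import annotations

import numpy as np
import pytest

from octinv import PhantomSpec, build_label_volume, render_oct
from octinv.segmentation import train_classifier


def small_spec(**overrides) -> PhantomSpec:
    """A 64x64x160 phantom geometry that keeps unit tests fast."""
    base = dict(
        lateral_size_um=(64.0, 64.0),
        depth_um=160.0,
        cancer_thickness_um=50.0,
        invasion_pattern="none",
        finger_count=4,
        finger_depth_um=50.0,
        finger_radius_um=10.0,
        island_count=3,
        island_radius_um=(10.0, 0.0),
        island_depth_range_um=(75.0, 130.0),
        fibroblast_density=2000.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def noiseless(**overrides) -> PhantomSpec:
    """Speckle, blur, attenuation and read noise all disabled."""
    base = dict(
        speckle_shape=None,
        read_noise_sd=0.0,
        attenuation_per_um=0.0,
        psf_lateral_fwhm_um=0.0,
        psf_axial_fwhm_um=0.0,
    )
    base.update(overrides)
    return small_spec(**base)


def make_training_slices(spec: PhantomSpec, n_per_pattern: int = 8, seed0: int = 100,
                         patterns=("cohesive", "finger", "island")):
    """Rendered X-Z slice/label pairs from one phantom per pattern."""
    slices = []
    for i, pattern in enumerate(patterns):
        s = spec.replace(invasion_pattern=pattern)
        truth = build_label_volume(s, seed=seed0 + i)
        vol = render_oct(truth, s, seed=seed0 + i)
        ny = vol.shape[1]
        for y in np.linspace(0, ny - 1, n_per_pattern).astype(int):
            slices.append((vol.data[:, int(y), :], truth.label_volume.data[:, int(y), :]))
    return slices


@pytest.fixture(scope="session")
def small_classifier():
    """Classifier trained on default-noise slices of the small geometry."""
    return train_classifier(make_training_slices(small_spec()), seed=0)


@pytest.fixture(scope="session")
def finger_truth():
    return build_label_volume(small_spec(invasion_pattern="finger"), seed=7)


@pytest.fixture(scope="session")
def island_truth():
    return build_label_volume(small_spec(invasion_pattern="island"), seed=7)
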