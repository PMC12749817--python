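"""Voxel classification of OCT-like volumes.

The deep network of the original workflow is replaced by a desk-scale
pluggable voxel classifier: multinomial logistic regression over multi-scale
log-intensity, local texture and normalized depth features, trained from
labeled cross-sectional (X-Z) slices.  The depth feature is what lets the
classifier compensate the exponential attenuation that defeats a global
threshold — :func:`otsu_baseline` provides that threshold baseline for
paired comparisons.

Features are computed per X-Z plane both at training and at inference time,
so a classifier fitted on 2D slices applies unchanged to full volumes.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from sklearn.linear_model import LogisticRegression

from octinv.volume_io import LabelVolume, OCTVolume

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class FeatureSpec:
    """Feature bank: Gaussian-smoothed log-intensity at several scales, a
    local-variance texture channel, and (optionally) depth normalized to [0, 1]."""

    smoothing_scales_um: tuple[float, ...] = (1.0, 2.0, 4.0)
    texture_window_um: float = 5.0
    include_depth: bool = True

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.smoothing_scales_um)
        if any(s <= 0 for s in scales):
            raise ValueError("smoothing scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("smoothing scales must be strictly increasing")
        self.smoothing_scales_um = scales

    @property
    def n_features(self) -> int:
        return len(self.smoothing_scales_um) + 1 + int(self.include_depth)

    def to_dict(self) -> dict:
        return {"smoothing_scales_um": list(self.smoothing_scales_um),
                "texture_window_um": self.texture_window_um,
                "include_depth": self.include_depth}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(smoothing_scales_um=tuple(d["smoothing_scales_um"]),
                   texture_window_um=d["texture_window_um"],
                   include_depth=d["include_depth"])


def slice_features(image: np.ndarray, voxel_um: float, spec: FeatureSpec) -> np.ndarray:
    """Feature stack for one X-Z plane, shape ``(nz, nx, n_features)``.

    Log transform first: multiplicative speckle becomes additive, and the
    exponential depth decay becomes linear in the depth channel.
    """
    img = np.log1p(image.astype(np.float32))
    nz, nx = img.shape
    feats = np.empty((nz, nx, spec.n_features), dtype=np.float32)
    j = 0
    for s in spec.smoothing_scales_um:
        feats[..., j] = gaussian_filter(img, sigma=s / voxel_um)
        j += 1
    w = max(1, int(round(spec.texture_window_um / voxel_um)))
    m1 = uniform_filter(img, size=w)
    m2 = uniform_filter(img * img, size=w)
    feats[..., j] = np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))
    j += 1
    if spec.include_depth:
        depth = (np.arange(nz, dtype=np.float32) / max(nz - 1, 1))[:, None]
        feats[..., j] = np.broadcast_to(depth, (nz, nx))
    return feats


@dataclass
class VoxelClassifier:
    """Multinomial logistic voxel classifier (JSON-serializable)."""

    feature_spec: FeatureSpec
    voxel_um: float
    classes: np.ndarray  # class codes, ascending
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray
    training_summary: dict = field(default_factory=dict)

    def _scores(self, feats: np.ndarray) -> np.ndarray:
        X = (feats.reshape(-1, feats.shape[-1]) - self.scaler_mean) / self.scaler_scale
        return X @ self.coef.T + self.intercept

    def predict_slice(self, image: np.ndarray) -> np.ndarray:
        feats = slice_features(image, self.voxel_um, self.feature_spec)
        scores = self._scores(feats)
        if scores.shape[1] == 1:  # binary fit: one decision column for classes[1]
            idx = (scores[:, 0] > 0).astype(np.intp)
        else:
            idx = np.argmax(scores, axis=1)
        return self.classes[idx].reshape(image.shape).astype(np.uint8)

    def to_json(self) -> str:
        return json.dumps({
            "feature_spec": self.feature_spec.to_dict(),
            "voxel_um": self.voxel_um,
            "classes": self.classes.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "training_summary": self.training_summary,
        }, indent=2)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "VoxelClassifier":
        d = json.loads(text)
        return cls(feature_spec=FeatureSpec.from_dict(d["feature_spec"]),
                   voxel_um=float(d["voxel_um"]),
                   classes=np.asarray(d["classes"], dtype=np.int64),
                   scaler_mean=np.asarray(d["scaler_mean"], dtype=np.float64),
                   scaler_scale=np.asarray(d["scaler_scale"], dtype=np.float64),
                   coef=np.asarray(d["coef"], dtype=np.float64),
                   intercept=np.asarray(d["intercept"], dtype=np.float64),
                   training_summary=d.get("training_summary", {}))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "VoxelClassifier":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def crop_roi(volume: OCTVolume, origin_um: tuple[float, float, float],
             size_um: tuple[float, float, float]) -> OCTVolume:
    """Crop a region of interest given in micrometres, axis order (z, y, x).

    Used to discard culture-medium and dish signal around the model; values
    are copied unchanged.
    """
    v = volume.voxel_um
    origin = [int(round(o / v)) for o in origin_um]
    size = [int(round(s / v)) for s in size_um]
    if any(o < 0 for o in origin) or any(s <= 0 for s in size):
        raise ValueError(f"ROI origin {origin_um} / size {size_um} invalid (negative origin or empty size)")
    if any(o + s > n for o, s, n in zip(origin, size, volume.shape)):
        raise ValueError(f"ROI origin {origin_um} + size {size_um} exceeds volume extent "
                         f"{tuple(n * v for n in volume.shape)} um")
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return OCTVolume(data=volume.data[sl].copy(), voxel_um=v,
                     provenance=f"{volume.provenance} | crop origin={origin_um} size={size_um}")


def train_classifier(slices: list[tuple[np.ndarray, np.ndarray]],
                     feature_spec: FeatureSpec | None = None,
                     voxel_um: float = 1.0,
                     seed: int = 0,
                     max_voxels_per_slice: int = 4000) -> VoxelClassifier:
    """Fit the voxel classifier from labeled X-Z slices.

    ``slices`` is a list of ``(intensity_image, label_image)`` pairs of equal
    shape.  Voxels are subsampled per slice (seeded, hence deterministic) and
    classes are weighted inversely to frequency.  Raises ``ValueError`` when
    the pooled labels contain fewer than two classes.
    """
    if feature_spec is None:
        feature_spec = FeatureSpec()
    if not slices:
        raise ValueError("need at least one labeled slice")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for img, lab in slices:
        if img.shape != lab.shape:
            raise ValueError(f"slice/label shape mismatch: {img.shape} vs {lab.shape}")
        feats = slice_features(img, voxel_um, feature_spec).reshape(-1, feature_spec.n_features)
        lab_flat = np.asarray(lab).reshape(-1)
        if lab_flat.size > max_voxels_per_slice:
            idx = rng.choice(lab_flat.size, size=max_voxels_per_slice, replace=False)
            feats, lab_flat = feats[idx], lab_flat[idx]
        X_parts.append(feats)
        y_parts.append(lab_flat)
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts).astype(np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"training labels contain a single class ({classes.tolist()}); need >= 2")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    model = LogisticRegression(max_iter=500, class_weight="balanced", random_state=seed)
    model.fit(Xs, y)
    acc = float(model.score(Xs, y))
    clf = VoxelClassifier(
        feature_spec=feature_spec,
        voxel_um=voxel_um,
        classes=model.classes_.astype(np.int64),
        scaler_mean=mean.astype(np.float64),
        scaler_scale=scale.astype(np.float64),
        coef=model.coef_.astype(np.float64),
        intercept=model.intercept_.astype(np.float64),
        training_summary={
            "n_slices": len(slices),
            "n_voxels_per_class": {int(c): int(n) for c, n in zip(classes, counts)},
            "training_accuracy": acc,
            "seed": int(seed),
        },
    )
    logger.info("trained voxel classifier on %d slices, training accuracy %.4f", len(slices), acc)
    return clf


def segment_volume(volume: OCTVolume, classifier: VoxelClassifier) -> LabelVolume:
    """Classify every voxel, plane by plane along y (X-Z cross-sections)."""
    if not np.isclose(volume.voxel_um, classifier.voxel_um):
        raise ValueError(f"voxel size mismatch: volume {volume.voxel_um} um vs "
                         f"classifier trained at {classifier.voxel_um} um")
    out = np.empty(volume.shape, dtype=np.uint8)
    for y in range(volume.shape[1]):
        out[:, y, :] = classifier.predict_slice(volume.data[:, y, :])
    if np.unique(out).size == 1:
        logger.warning("segmentation produced a single-class volume (code %d)", int(out.flat[0]))
    return LabelVolume(data=out, voxel_um=volume.voxel_um,
                       provenance=f"{volume.provenance} | classifier")


def otsu_baseline(volume: OCTVolume) -> np.ndarray:
    """Global bimodal-threshold cancer mask (the conventional baseline).

    Known failure modes: depth attenuation pushes deep cancer below the
    global threshold, and inverted-contrast volumes select the background.
    """
    data = volume.data
    if data.min() == data.max():
        raise ValueError("cannot threshold a constant volume")
    thr = threshold_otsu(data)
    return data > thr


def clean_mask(mask: np.ndarray, min_object_um3: float = 27.0, voxel_um: float = 1.0) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_object_um3``.

    Default 27 um^3 (a 3 um cube, the lateral optical resolution): anything
    smaller is below resolution and treated as noise.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    min_vox = int(math.ceil(min_object_um3 / voxel_um ** 3))
    if min_vox <= 1:
        return mask.copy()
    lbl, n = _cc_label(mask, connectivity=mask.ndim, return_num=True)
    if n == 0:
        return mask.copy()
    counts = np.bincount(lbl.ravel())
    keep = counts >= min_vox
    keep[0] = False
    return keep[lbl]
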