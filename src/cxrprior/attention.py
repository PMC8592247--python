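"""Grad-CAM attention maps and their 3x3 zone quantification.

For a class c with prediction score y^c = ||nu_c||, the gradient of
y^c with respect to the final conv layer's feature maps A^k is
global-average-pooled into weights a_k^c = (1/Z) sum_ij dy^c/dA^k_ij,
and the map is ReLU(sum_k a_k^c A^k), bilinearly upsampled to the
input size.  Because the network has two streams, a map is computed at
each stream's last conv layer and the two upsampled maps are averaged
(either stream alone is available via ``stream=``).

Attention mass is quantified over the 3x3 zone grid Z11..Z33 (row
band, column band; Z11 = top-left shoulder, Z22 = central spine):
per correctly classified image the min-max-normalized map's mean
intensity per zone is normalized to sum 1, and the class profile is
the mean of those per-image zone vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from matplotlib import cm
from skimage.transform import resize

from cxrprior.model import DualStreamModel
from cxrprior.phantom import ImageRecord
from cxrprior.training import Task, encode_targets, image_matrix

ZONE_NAMES: tuple[str, ...] = (
    "Z11", "Z12", "Z13",
    "Z21", "Z22", "Z23",
    "Z31", "Z32", "Z33",
)


@dataclass(frozen=True)
class ZoneGrid:
    """Nine rectangular zones partitioning an image.

    ``bounds[name] = (r0, r1, c0, c1)`` half-open pixel ranges.
    Remainder rows/columns of a side not divisible by 3 go to the last
    band, so bands differ by at most 2 pixels.
    """

    height: int
    width: int
    bounds: dict[str, tuple[int, int, int, int]]

    def masks(self) -> dict[str, tuple[slice, slice]]:
        return {
            n: (slice(r0, r1), slice(c0, c1))
            for n, (r0, r1, c0, c1) in self.bounds.items()
        }


def zone_partition(image_size: int | tuple[int, int]) -> ZoneGrid:
    """The 3x3 equal partition of an image into zones Z11..Z33."""
    h, w = (image_size, image_size) if isinstance(image_size, int) else image_size
    if h < 3 or w < 3:
        raise ValueError(f"image must be at least 3x3 to carry 9 zones, got {h}x{w}")
    r_edges = [0, h // 3, 2 * (h // 3), h]
    c_edges = [0, w // 3, 2 * (w // 3), w]
    bounds = {}
    for r in range(3):
        for c in range(3):
            bounds[f"Z{r + 1}{c + 1}"] = (
                r_edges[r], r_edges[r + 1], c_edges[c], c_edges[c + 1]
            )
    return ZoneGrid(height=h, width=w, bounds=bounds)


@dataclass
class GradCamMap:
    """Raw (feature-map-sized) and upsampled Grad-CAM maps for one class."""

    raw: np.ndarray
    upsampled: np.ndarray
    class_index: int
    z: int                      # pixels per feature map (the 1/Z pool size)


def cam_from_activations(activations: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """ReLU(sum_k a_k A^k) with a_k the spatial mean of the gradients.

    ``activations`` and ``grads`` are (K, u, v).  Kept as a pure
    function so the map arithmetic is testable against hand
    computation.
    """
    a = grads.mean(axis=(1, 2))                      # (K,)  = (1/Z) sum_ij
    combined = np.tensordot(a, activations, axes=(0, 0))
    return np.maximum(combined, 0.0)


def grad_cam(
    model: DualStreamModel,
    image: np.ndarray,
    class_index: int,
    stream: Literal["both", "s1", "s2"] = "both",
) -> GradCamMap:
    """Grad-CAM map for one image and class.

    ``image`` is a single (H, W) array in [0, 1].  The differentiated
    scalar is the class score y^c = ||nu_c||.
    """
    if not (0 <= class_index < model.cfg.n_classes):
        raise ValueError(
            f"class_index {class_index} out of range for {model.cfg.n_classes} classes"
        )
    convs = {"s1": [model.last_conv_s1], "s2": [model.last_conv_s2],
             "both": [model.last_conv_s1, model.last_conv_s2]}[stream]
    emb, _ = model.forward(image, train=False, capture=convs)
    # Seed d y^c / d nu_c = nu_c / ||nu_c||, zero elsewhere.
    grad_vec = np.zeros_like(emb.vectors)
    norm = max(float(emb.scores[0, class_index]), 1e-12)
    grad_vec[0, class_index] = emb.vectors[0, class_index] / norm
    grads = model.backward(grad_vec, capture_grads=convs)

    size = model.cfg.input_size
    maps = []
    z = None
    for conv in convs:
        act = model.captured[conv][0]                # (K, u, v)
        g = grads[conv][0]
        raw = cam_from_activations(act.astype(np.float64), g.astype(np.float64))
        z = raw.shape[0] * raw.shape[1]
        maps.append(resize(raw, (size, size), order=1, mode="edge",
                           anti_aliasing=False))
    upsampled = np.mean(maps, axis=0)
    return GradCamMap(raw=raw, upsampled=upsampled, class_index=class_index, z=z)


@dataclass
class ZoneAttentionProfile:
    """Mean per-zone attention fractions for one class."""

    class_label: str
    fractions: dict[str, float]
    n_images: int

    @property
    def empty(self) -> bool:
        return self.n_images == 0

    def as_row(self) -> dict:
        return {"class": self.class_label, **self.fractions, "n_images": self.n_images}


def _zone_vector(map2d: np.ndarray, grid: ZoneGrid) -> np.ndarray:
    lo, hi = map2d.min(), map2d.max()
    norm = (map2d - lo) / (hi - lo) if hi > lo else np.zeros_like(map2d)
    means = np.array([norm[sl].mean() for sl in grid.masks().values()])
    total = means.sum()
    return means / total if total > 0 else np.full(9, 1.0 / 9.0)


def zone_profile(
    model: DualStreamModel,
    records: Sequence[ImageRecord],
    class_label: str,
    task: Task,
    classes: Sequence[str] | None = None,
    stream: Literal["both", "s1", "s2"] = "both",
) -> ZoneAttentionProfile:
    """Zone-attention profile of one class over correctly classified records.

    Only records that carry the class *and* are correctly classified
    for it contribute.  If none qualify the profile is returned empty
    (``n_images == 0``) rather than raising.
    """
    from cxrprior.training import task_classes

    classes = tuple(classes) if classes is not None else task_classes(task)
    k = classes.index(class_label)
    grid = zone_partition(model.cfg.input_size)
    if not records:
        return ZoneAttentionProfile(
            class_label=class_label,
            fractions={z: float("nan") for z in ZONE_NAMES},
            n_images=0,
        )
    x = image_matrix(records)
    targets = encode_targets(records, task, classes)
    vectors = []
    for i, rec in enumerate(records):
        if targets[i, k] != 1.0:
            continue
        emb, _ = model.forward(x[i], train=False)
        pred = model.predict(emb.scores)[0]
        correct = (pred == k) if model.cfg.task_kind == "single" else bool(pred[k])
        if not correct:
            continue
        cam = grad_cam(model, x[i], k, stream=stream)
        vectors.append(_zone_vector(cam.upsampled, grid))
    if not vectors:
        return ZoneAttentionProfile(
            class_label=class_label,
            fractions={z: float("nan") for z in ZONE_NAMES},
            n_images=0,
        )
    mean = np.mean(vectors, axis=0)
    mean = mean / mean.sum()
    return ZoneAttentionProfile(
        class_label=class_label,
        fractions=dict(zip(ZONE_NAMES, map(float, mean))),
        n_images=len(vectors),
    )


def profiles_frame(profiles: Sequence[ZoneAttentionProfile]) -> pd.DataFrame:
    return pd.DataFrame([p.as_row() for p in profiles])


def overlay(image: np.ndarray, map2d: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Heat-colormap blend of an attention map over a grayscale image.

    Blend weight scales with the map value, so a zero map returns the
    plain grayscale image as RGB and a saturated map blends at
    ``alpha`` everywhere.  Returns uint8 RGB.
    """
    img = np.asarray(image)
    if img.shape != map2d.shape:
        raise ValueError(f"image shape {img.shape} != map shape {map2d.shape}")
    gray = img.astype(np.float64)
    gray = gray / 255.0 if img.dtype == np.uint8 else gray
    m = np.clip(np.asarray(map2d, dtype=np.float64), 0.0, None)
    if m.max() > 1.0:
        m = m / m.max()
    heat = cm.jet(m)[..., :3]
    w = (alpha * m)[..., None]
    rgb = (1.0 - w) * gray[..., None] + w * heat
    return (rgb * 255.0).round().astype(np.uint8)
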