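"""Stage-I preprocessing: dataset versions Ver_ORG and Ver_NMF.

``Ver_ORG`` is the rotation-augmented original data; ``Ver_NMF`` passes
every image through rank-``kappa`` non-negative matrix factorization
(treating the whole 2-D image as the matrix) followed by CLAHE.  The
low-rank reconstruction suppresses small, localized detail — disease
blobs — while CLAHE amplifies the surviving structural edges, which is
what lets the anatomy tasks (gender, age) train on images where disease
information has been deliberately weakened.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage import exposure, transform

from cxrprior.phantom import ImageRecord

_EPS = 1e-12


class PreprocessConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NMF


@dataclass(frozen=True)
class NMFConfig:
    """Rank, iteration budget and objective of the per-image NMF.

    ``kappa`` must satisfy the compression bound kappa < n*m/(n+m) for
    the image it is applied to.  ``objective`` selects between the
    Frobenius criterion ||Lambda - Psi H||_F and the log-form
    (Poisson/KL) criterion; both use multiplicative updates.
    """

    kappa: int = 6
    max_iter: int = 200
    tol: float = 1e-4
    objective: Literal["frobenius", "log_form"] = "frobenius"
    seed: int = 0

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.kappa < 1:
            raise PreprocessConfigError(f"kappa must be >= 1, got {self.kappa}")
        m, n = shape
        bound = m * n / (m + n)
        if not self.kappa < bound:
            raise PreprocessConfigError(
                f"kappa={self.kappa} violates the compression bound "
                f"kappa < n*m/(n+m) = {m}*{n}/({m}+{n}) = {bound:g} "
                f"for a {m}x{n} image"
            )


def max_admissible_kappa(shape: tuple[int, int]) -> int:
    """Largest rank satisfying the strict bound kappa < n*m/(n+m)."""
    m, n = shape
    bound = m * n / (m + n)
    k = int(math.floor(bound))
    return k - 1 if k == bound else k


@dataclass
class NMFResult:
    """Factors Psi (m x kappa), H (kappa x n) and the 8-bit reconstruction."""

    W: np.ndarray
    H: np.ndarray
    objective_value: float
    reconstruction: np.ndarray
    objective_trace: np.ndarray = field(repr=False, default=None)


def _frobenius(V: np.ndarray, WH: np.ndarray) -> float:
    return float(np.linalg.norm(V - WH))


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    Vp = np.maximum(V, _EPS)
    return float(np.sum(V * np.log(Vp / WH) - V + WH))


def nmf_compress(image: np.ndarray, cfg: NMFConfig) -> NMFResult:
    """Factorize a non-negative image Lambda ~= Psi H by multiplicative updates.

    The Frobenius objective ||Lambda - Psi H||_F and the KL/log-form
    objective are both non-increasing along their update sequences;
    the recorded trace lets callers verify this.  The 8-bit clipped
    reconstruction Psi H is the "NMF-compressed" image.
    """
    V = np.asarray(image, dtype=np.float64)
    if V.ndim != 2:
        raise PreprocessConfigError(f"expected a 2-D image, got shape {V.shape}")
    if (V < 0).any():
        raise ValueError("NMF requires non-negative pixel values")
    cfg.validate_for(V.shape)
    m, n = V.shape
    k = cfg.kappa

    rng = np.random.default_rng(cfg.seed)
    scale = math.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(m, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale

    obj_fn = _frobenius if cfg.objective == "frobenius" else _kl_divergence
    trace = [obj_fn(V, W @ H)]
    for _ in range(cfg.max_iter):
        if cfg.objective == "frobenius":
            H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
            W *= (V @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
        else:
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        trace.append(obj_fn(V, W @ H))
        prev, cur = trace[-2], trace[-1]
        if prev > 0 and (prev - cur) / max(prev, _EPS) < cfg.tol:
            break

    recon = np.clip(W @ H, 0, 255).astype(np.uint8)
    return NMFResult(
        W=W,
        H=H,
        objective_value=trace[-1],
        reconstruction=recon,
        objective_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# CLAHE


@dataclass(frozen=True)
class CLAHEConfig:
    """Tile grid NT = [rows, cols] and relative clip limit CL (> 0)."""

    nt: tuple[int, int] = (8, 8)
    cl: float = 2.0

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.nt[0] < 1 or self.nt[1] < 1:
            raise PreprocessConfigError(f"tile grid entries must be >= 1, got {self.nt}")
        if self.cl <= 0:
            raise PreprocessConfigError(f"clip limit must be > 0, got {self.cl}")
        if self.nt[0] > shape[0] or self.nt[1] > shape[1]:
            raise PreprocessConfigError(
                f"tile grid {self.nt} exceeds image shape {shape}"
            )


def tile_shape(image_shape: tuple[int, int], cfg: CLAHEConfig) -> tuple[int, int]:
    """Pixel size of one tile after edge-replication padding."""
    th = math.ceil(image_shape[0] / cfg.nt[0])
    tw = math.ceil(image_shape[1] / cfg.nt[1])
    return th, tw


def n_tiles(image_shape: tuple[int, int], cfg: CLAHEConfig) -> int:
    """Number of non-overlapping tiles the image is split into."""
    cfg.validate_for(image_shape)
    return cfg.nt[0] * cfg.nt[1]


def clahe_enhance(image: np.ndarray, cfg: CLAHEConfig = CLAHEConfig()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    The image is split into an ``nt[0] x nt[1]`` grid of equal tiles
    (edge-replication padding to the next tile multiple, cropped back
    afterwards); per-tile histograms are clipped at the relative limit
    ``cl`` and equalized, with bilinear interpolation across tile
    borders.  The relative clip limit follows the common convention of
    a multiple of the uniform histogram height.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise PreprocessConfigError(f"expected an 8-bit image, got dtype {img.dtype}")
    cfg.validate_for(img.shape)
    if img.min() == img.max():
        # Degenerate histogram: equalization maps every pixel through
        # the same LUT entry, so the image stays flat.
        return img.copy()
    th, tw = tile_shape(img.shape, cfg)
    ph = th * cfg.nt[0] - img.shape[0]
    pw = tw * cfg.nt[1] - img.shape[1]
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    nbins = 256
    out = exposure.equalize_adapthist(
        padded, kernel_size=(th, tw), clip_limit=cfg.cl / nbins, nbins=nbins
    )
    out = (out[: img.shape[0], : img.shape[1]] * 255.0).round().astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Dataset versions


@dataclass
class DatasetVersion:
    """A manifest-backed image collection tagged Ver_ORG or Ver_NMF."""

    tag: Literal["Ver_ORG", "Ver_NMF"]
    records: list[ImageRecord]

    def subset(self, role: str) -> list[ImageRecord]:
        return [r for r in self.records if r.role == role]

    def ids(self) -> list[str]:
        return [r.image_id for r in self.records]


def make_version_org(records: Sequence[ImageRecord]) -> DatasetVersion:
    """Tag the (already augmented) originals as Ver_ORG."""
    return DatasetVersion(tag="Ver_ORG", records=list(records))


def make_version_nmf(
    records: Sequence[ImageRecord],
    nmf_cfg: NMFConfig = NMFConfig(),
    clahe_cfg: CLAHEConfig = CLAHEConfig(),
) -> DatasetVersion:
    """Build Ver_NMF: NMF compression then CLAHE, per image.

    Labels and roles are untouched; each image is processed
    independently (batch membership cannot change a record's output).
    """
    out: list[ImageRecord] = []
    for rec in records:
        try:
            compressed = nmf_compress(rec.pixels, nmf_cfg).reconstruction
            enhanced = clahe_enhance(compressed, clahe_cfg)
        except Exception as exc:
            raise type(exc)(f"while preprocessing {rec.image_id!r}: {exc}") from exc
        out.append(rec.replace(pixels=enhanced))
    return DatasetVersion(tag="Ver_NMF", records=out)


# ---------------------------------------------------------------------------
# Augmentation


def rotate_image(pixels: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate an 8-bit image, filling exposed corners with black."""
    rotated = transform.rotate(
        pixels, angle_deg, resize=False, mode="constant", cval=0.0,
        preserve_range=True,
    )
    return np.clip(rotated, 0, 255).round().astype(np.uint8)


def _class_counts(
    records: Sequence[ImageRecord], by: str
) -> dict[str, list[int]]:
    """Map class label -> indices of records carrying it."""
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        for label in record_labels(rec, by):
            groups.setdefault(label, []).append(i)
    return groups


def record_labels(rec: ImageRecord, by: str) -> tuple[str, ...]:
    """Labels of a record under a task view: gender, age or disease."""
    if by == "gender":
        return (rec.gender,)
    if by == "age":
        return (rec.age_bin,)
    if by == "disease":
        return tuple(sorted(rec.diseases)) or ("No Finding",)
    raise ValueError(f"unknown task {by!r}")


def augment_balance(
    records: Sequence[ImageRecord],
    max_angle_deg: float = 30.0,
    by: str = "disease",
    seed: int = 0,
    classes: Iterable[str] | None = None,
) -> list[ImageRecord]:
    """Balance class counts by adding rotated copies of minority-class images.

    Rotation angles are drawn uniformly from ``[-max_angle_deg,
    +max_angle_deg]`` degrees.  Originals are always retained; each
    copy gets a derived id (``<stem>_rotNNN.png``) and records its
    angle in ``meta['rotation_deg']``.  For multi-label views a copy
    counts toward every label it carries, so balancing is to *at
    least* the majority count per class (exact for single-label views).
    """
    records = list(records)
    groups = _class_counts(records, by)
    if classes is not None:
        missing = [c for c in classes if c not in groups]
        if missing:
            raise ValueError(f"classes with zero records: {missing}")
    if not groups:
        return records
    rng = np.random.default_rng(seed)
    target = max(len(ix) for ix in groups.values())
    counts = {c: len(ix) for c, ix in groups.items()}
    out = records.copy()
    serial = 0
    for label in sorted(groups, key=lambda c: (counts[c], c)):
        while counts[label] < target:
            src = records[groups[label][int(rng.integers(len(groups[label])))]]
            angle = float(rng.uniform(-max_angle_deg, max_angle_deg))
            serial += 1
            stem = src.image_id.rsplit(".", 1)[0]
            copy = src.replace(
                image_id=f"{stem}_rot{serial:04d}.png",
                pixels=rotate_image(src.pixels, angle),
                meta={**src.meta, "rotation_deg": angle, "rotated_from": src.image_id},
            )
            out.append(copy)
            for lab in record_labels(copy, by):
                if lab in counts:
                    counts[lab] += 1
    return out


# ---------------------------------------------------------------------------
# Train/val/test split


def split_dataset(
    records: Sequence[ImageRecord],
    fractions: tuple[float, float, float] = (0.80, 0.10, 0.10),
    seed: int = 0,
    by: str = "disease",
) -> list[ImageRecord]:
    """Assign train/val/test roles, stratified by class.

    Single-label views stratify on the class itself.  Multi-label
    records are grouped by their *rarest* label (the least frequent
    one they carry), a cheap proxy for iterative stratification that
    spreads each disease's scarce positives across the three roles.
    Within each stratum, seats are allocated by largest remainder;
    remainder ties break toward the globally most under-allocated
    role, train first.  Strata with fewer than 3 members go entirely
    to train (with a warning).  The same ``(records, fractions,
    seed)`` always yields the same assignment, which is made once and
    shared by Ver_ORG and Ver_NMF.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    roles = ("train", "val", "test")
    label_freq: dict[str, int] = {}
    for rec in records:
        for lab in record_labels(rec, by):
            label_freq[lab] = label_freq.get(lab, 0) + 1
    strata: dict[tuple[str, ...], list[int]] = {}
    for i, rec in enumerate(records):
        labels = record_labels(rec, by)
        key = (min(labels, key=lambda l: (label_freq[l], l)),)
        strata.setdefault(key, []).append(i)

    assignment: dict[int, str] = {}
    global_alloc = {r: 0.0 for r in roles}   # seats granted minus seats owed
    for key in sorted(strata):
        idx = strata[key]
        n = len(idx)
        if n < 3:
            warnings.warn(
                f"stratum {key} has only {n} record(s), too few to fill three "
                "roles; assigning all to train",
                stacklevel=2,
            )
            for i in idx:
                assignment[i] = "train"
            for role, f in zip(roles, fractions):
                global_alloc[role] += (n if role == "train" else 0) - n * f
            continue
        quotas = [n * f for f in fractions]
        base = [int(math.floor(q)) for q in quotas]
        rem = [q - b for q, b in zip(quotas, base)]
        seats = n - sum(base)
        # Ties: prefer the role with the largest global deficit
        # (quota owed minus seats granted so far), then role order.
        order = sorted(
            range(3),
            key=lambda j: (-rem[j], global_alloc[roles[j]], j),
        )
        for j in order[:seats]:
            base[j] += 1
        for j, role in enumerate(roles):
            global_alloc[role] += base[j] - quotas[j]
        perm = rng.permutation(n)
        cursor = 0
        for j, role in enumerate(roles):
            for p in perm[cursor : cursor + base[j]]:
                assignment[idx[p]] = role
            cursor += base[j]

    return [rec.replace(role=assignment[i]) for i, rec in enumerate(records)]
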