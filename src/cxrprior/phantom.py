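"""Synthetic chest-phantom generator.

Phantoms are deliberately minimal radiograph stand-ins: two lung-field
ellipses, a central spine column and two shoulder bands on a dark
background.  Gender and age modulate *geometry only* (shoulder-band
width and rib-cage aspect ratio respectively), while each disease label
adds one localized bright blob inside a lung field.  Anatomy-driven and
disease-driven signal are therefore spatially separable by construction,
which is exactly the structure the sequential gender -> age -> disease
training protocol assumes of real chest radiographs.

All geometry is expressed in fractions of the image side so phantoms at
32 px and 128 px share the same anatomy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 14 thorax-disease labels of the ChestX-ray14 corpus, in the
#: spelling its label file uses ("Pleural_Thickening", not a space).
DISEASE_CLASSES: tuple[str, ...] = (
    "Atelectasis",
    "Cardiomegaly",
    "Consolidation",
    "Edema",
    "Effusion",
    "Emphysema",
    "Fibrosis",
    "Hernia",
    "Infiltration",
    "Mass",
    "Nodule",
    "Pleural_Thickening",
    "Pneumonia",
    "Pneumothorax",
)

#: Age bins used for the age-detection task.  Boundaries are closed
#: below, open above: [0, 11), [11, 21), [21, 31), [31, 121).
AGE_BINS: tuple[str, ...] = ("Age_1-10", "Age_11-20", "Age_21-30", "Age_31-120")
_AGE_EDGES = (11, 21, 31, 121)

GENDERS: tuple[str, str] = ("Male", "Female")

# Base anatomy, as fractions of the image side.
_SHOULDER_TOP = 0.06
_SHOULDER_BASE_WIDTH = 0.09       # band thickness before gender modulation
_SHOULDER_COLS = ((0.03, 0.36), (0.64, 0.97))
_SPINE_HALF_WIDTH = 0.05
_SPINE_ROWS = (0.04, 0.96)
_LUNG_CENTERS = ((0.56, 0.30), (0.56, 0.70))   # (row, col) fractions
_LUNG_SEMI_V = 0.26               # vertical semi-axis before age modulation
_LUNG_SEMI_H = 0.15               # horizontal semi-axis

_BG_LEVEL = 10.0
_LUNG_LEVEL = 60.0
_SPINE_LEVEL = 110.0
_SHOULDER_LEVEL = 150.0

# One blob placement per disease class: (lung index, angle in turns,
# radial fraction of the ellipse, radius scale, tilt in turns).  The
# placement angles avoid the top of the ellipse so blobs stay clear of
# the shoulder bands.  Blobs are anisotropic (2.5:1) and tilted, so a
# blob is not a separable (rank-1) pattern and genuinely costs the NMF
# compression rank it needs to survive.
_BLOB_ASPECT = 2.5
_BLOB_PARAMS: dict[str, tuple[int, float, float, float, float]] = {
    name: (
        i % 2,
        0.10 + 0.80 * ((i // 2) / 7.0),
        0.30 + 0.25 * ((i * 3) % 5) / 4.0,
        0.8 + 0.4 * ((i * 5) % 3) / 2.0,
        0.08 + 0.34 * ((i * 7) % 11) / 10.0,   # tilt away from the axes
    )
    for i, name in enumerate(DISEASE_CLASSES)
}


def age_to_bin(age_years: int) -> str:
    """Map an age in years onto one of the four reporting bins."""
    for name, hi in zip(AGE_BINS, _AGE_EDGES):
        if age_years < hi:
            return name
    return AGE_BINS[-1]


class PhantomConfigError(ValueError):
    """A phantom configuration that cannot be rendered."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom population.

    Parameters
    ----------
    image_size:
        Side length in pixels of the square images (>= 32).
    n_subjects:
        Number of subjects (one image each).
    gender_geometry_effect:
        Relative shoulder-band width difference between Male and
        Female: Male bands are ``1 + effect/2`` times the base width,
        Female bands ``1 - effect/2`` times.
    age_geometry_effect:
        Per-bin deltas added to the rib-cage (lung ellipse) vertical
        aspect ratio, one per age bin, monotone by default.
    disease_blob_intensity:
        Peak additive gray level of a disease blob, as a fraction of
        the 8-bit range.
    disease_blob_radius:
        Blob radius in pixels.
    disease_prevalence:
        Independent per-class probability that a subject carries each
        disease label; subjects with no label are "No Finding".
    noise_sd:
        SD of additive Gaussian pixel noise, in gray levels.
    seed:
        Seed of the single generator that drives all randomness.
    """

    image_size: int = 128
    n_subjects: int = 100
    gender_geometry_effect: float = 0.3
    age_geometry_effect: Sequence[float] = (-0.24, -0.08, 0.08, 0.24)
    disease_blob_intensity: float = 0.4
    disease_blob_radius: float = 8.0
    disease_prevalence: float = 0.08
    disease_classes: Sequence[str] = DISEASE_CLASSES
    noise_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise PhantomConfigError(
                f"image_size={self.image_size} is below the minimum of 32"
            )
        if len(self.age_geometry_effect) != len(AGE_BINS):
            raise PhantomConfigError(
                "age_geometry_effect needs one delta per age bin "
                f"({len(AGE_BINS)}), got {len(self.age_geometry_effect)}"
            )
        for name, value in (
            ("gender_geometry_effect", self.gender_geometry_effect),
            ("disease_blob_intensity", self.disease_blob_intensity),
            ("noise_sd", self.noise_sd),
        ):
            if not np.isfinite(value):
                raise PhantomConfigError(f"{name} must be finite, got {value}")
        if not all(np.isfinite(self.age_geometry_effect)):
            raise PhantomConfigError("age_geometry_effect entries must be finite")
        if self.noise_sd < 0:
            raise PhantomConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        unknown = set(self.disease_classes) - set(DISEASE_CLASSES)
        if unknown:
            raise PhantomConfigError(f"unknown disease classes: {sorted(unknown)}")
        # The smallest lung semi-axis must accommodate the largest blob,
        # otherwise blobs leak out of the lung fields.
        min_aspect = 1.0 + min(self.age_geometry_effect)
        semi_h = _LUNG_SEMI_H * self.image_size
        semi_v = _LUNG_SEMI_V * min_aspect * self.image_size
        max_scale = max(
            (_BLOB_PARAMS[d][3] for d in self.disease_classes), default=0.0
        )
        if self.disease_classes and self.disease_blob_radius * max_scale > 0.5 * min(
            semi_h, semi_v
        ) + 1e-9:
            raise PhantomConfigError(
                "image_size too small to place disease blobs: radius "
                f"{self.disease_blob_radius:.1f} px does not fit inside a lung "
                f"semi-axis of {min(semi_h, semi_v):.1f} px; increase image_size "
                "or decrease disease_blob_radius"
            )


@dataclass
class ImageRecord:
    """One grayscale image together with its manifest row."""

    image_id: str
    pixels: np.ndarray            # square uint8 array
    gender: str                   # "Male" | "Female"
    age_years: int
    diseases: frozenset[str] = frozenset()
    role: str | None = None       # train | val | test, set by split_dataset
    meta: dict = field(default_factory=dict)

    @property
    def age_bin(self) -> str:
        return age_to_bin(self.age_years)

    def replace(self, **kw) -> "ImageRecord":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class _SubjectLatents:
    """Per-subject draw of everything the renderer needs."""

    gender: str
    age_years: int
    diseases: frozenset[str]
    band_jitter: float      # multiplicative, ~N(1, 0.05)
    aspect_jitter: float


def _draw_subject(cfg: PhantomConfig, rng: np.random.Generator) -> _SubjectLatents:
    gender = GENDERS[int(rng.integers(2))]
    bin_idx = int(rng.integers(len(AGE_BINS)))
    lo = 1 if bin_idx == 0 else _AGE_EDGES[bin_idx - 1]
    age = int(rng.integers(lo, _AGE_EDGES[bin_idx]))
    present = rng.random(len(cfg.disease_classes)) < cfg.disease_prevalence
    diseases = frozenset(
        d for d, p in zip(cfg.disease_classes, present) if p
    )
    return _SubjectLatents(
        gender=gender,
        age_years=age,
        diseases=diseases,
        band_jitter=float(1.0 + 0.05 * rng.standard_normal()),
        aspect_jitter=float(0.03 * rng.standard_normal()),
    )


def render_subject(
    cfg: PhantomConfig,
    latents: _SubjectLatents,
    rng: np.random.Generator,
    *,
    diseases: Iterable[str] | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one phantom image from subject latents.

    ``diseases`` overrides the latents' label set, which lets tests
    render disease-present / disease-free twins of the same subject.
    Returns the uint8 image and a metadata dict of realized geometry.
    """
    s = cfg.image_size
    img = np.full((s, s), _BG_LEVEL, dtype=np.float64)
    rows = np.arange(s)[:, None]
    cols = np.arange(s)[None, :]

    bin_idx = AGE_BINS.index(age_to_bin(latents.age_years))
    aspect = 1.0 + cfg.age_geometry_effect[bin_idx] + latents.aspect_jitter
    semi_v = _LUNG_SEMI_V * aspect * s
    semi_h = _LUNG_SEMI_H * s

    # Lung-field ellipses.
    for rc, cc in _LUNG_CENTERS:
        mask = ((rows - rc * s) / semi_v) ** 2 + ((cols - cc * s) / semi_h) ** 2 <= 1.0
        img[mask] = np.maximum(img[mask], _LUNG_LEVEL)

    # Spine column.
    c0 = 0.5 * s - _SPINE_HALF_WIDTH * s
    c1 = 0.5 * s + _SPINE_HALF_WIDTH * s
    spine = (cols >= c0) & (cols < c1) & (rows >= _SPINE_ROWS[0] * s) & (
        rows < _SPINE_ROWS[1] * s
    )
    img[spine] = np.maximum(img[spine], _SPINE_LEVEL)

    # Shoulder bands; width carries the gender signal.
    gfac = (
        1.0 + cfg.gender_geometry_effect / 2.0
        if latents.gender == "Male"
        else 1.0 - cfg.gender_geometry_effect / 2.0
    )
    band_w = max(1.0, _SHOULDER_BASE_WIDTH * s * gfac * latents.band_jitter)
    r0 = _SHOULDER_TOP * s
    band = (rows >= r0) & (rows < r0 + band_w)
    for cl, cr in _SHOULDER_COLS:
        m = band & (cols >= cl * s) & (cols < cr * s)
        img[m] = np.maximum(img[m], _SHOULDER_LEVEL)

    # Disease blobs: one Gaussian bump per label, inside a lung field.
    labels = latents.diseases if diseases is None else frozenset(diseases)
    blob_centers = {}
    for d in sorted(labels):
        lung, turns, rfrac, rscale, tilt = _BLOB_PARAMS[d]
        rc, cc = _LUNG_CENTERS[lung]
        ang = 2.0 * np.pi * turns
        br = rc * s + rfrac * semi_v * np.sin(ang)
        bc = cc * s + rfrac * semi_h * np.cos(ang)
        radius = cfg.disease_blob_radius * rscale
        ct, st = np.cos(2.0 * np.pi * tilt), np.sin(2.0 * np.pi * tilt)
        u = (rows - br) * ct + (cols - bc) * st
        v = -(rows - br) * st + (cols - bc) * ct
        s_major = (radius / 2.0) * np.sqrt(_BLOB_ASPECT)
        s_minor = (radius / 2.0) / np.sqrt(_BLOB_ASPECT)
        bump = cfg.disease_blob_intensity * 255.0 * np.exp(
            -0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2)
        )
        img += bump
        blob_centers[d] = (float(br), float(bc), float(radius))

    if cfg.noise_sd > 0:
        img += cfg.noise_sd * rng.standard_normal((s, s))

    meta = {
        "band_width_px": float(band_w),
        "rib_aspect": float(aspect),
        "blob_centers": blob_centers,
    }
    return np.clip(img, 0, 255).astype(np.uint8), meta


def generate_phantom(cfg: PhantomConfig) -> list[ImageRecord]:
    """Generate ``cfg.n_subjects`` phantom records.

    Identical ``(config, seed)`` pairs produce byte-identical images:
    all randomness flows from one ``default_rng(cfg.seed)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[ImageRecord] = []
    for i in range(cfg.n_subjects):
        latents = _draw_subject(cfg, rng)
        pixels, meta = render_subject(cfg, latents, rng)
        records.append(
            ImageRecord(
                image_id=f"{i:08d}_000.png",
                pixels=pixels,
                gender=latents.gender,
                age_years=latents.age_years,
                diseases=latents.diseases,
                meta=meta,
            )
        )
    return records
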