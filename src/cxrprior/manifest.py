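"""Label-manifest I/O in the ChestX-ray14 ``Data_Entry_2017.csv`` dialect.

The manifest is a CSV with one row per image: ``Image Index``,
``Finding Labels`` (pipe-separated disease names, or the literal token
``No Finding``), ``Patient Age`` (years) and ``Patient Gender``
(``M``/``F``).  Round-trips through :func:`write_manifest` /
:func:`read_manifest` are lossless for the fields the pipeline uses.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from cxrprior.phantom import DISEASE_CLASSES, ImageRecord

NO_FINDING = "No Finding"
REQUIRED_COLUMNS = ("Image Index", "Finding Labels", "Patient Age", "Patient Gender")

_GENDER_TO_CODE = {"Male": "M", "Female": "F"}
_CODE_TO_GENDER = {"M": "Male", "F": "Female"}


class ManifestError(ValueError):
    pass


def serialize_labels(diseases: Iterable[str]) -> str:
    """Pipe-join a disease set (sorted); empty set -> ``No Finding``."""
    labels = sorted(diseases)
    return "|".join(labels) if labels else NO_FINDING


def parse_labels(text: str) -> frozenset[str]:
    """Inverse of :func:`serialize_labels`; validates disease names."""
    text = text.strip()
    if not text or text == NO_FINDING:
        return frozenset()
    labels = frozenset(t.strip() for t in text.split("|"))
    unknown = labels - set(DISEASE_CLASSES)
    if unknown:
        raise ManifestError(
            f"unknown disease labels {sorted(unknown)}; "
            f"known labels: {list(DISEASE_CLASSES)}"
        )
    return labels


def manifest_frame(records: Sequence[ImageRecord]) -> pd.DataFrame:
    ids = [r.image_id for r in records]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate image ids in manifest: {sorted(set(dup))}")
    return pd.DataFrame(
        {
            "Image Index": ids,
            "Finding Labels": [serialize_labels(r.diseases) for r in records],
            "Patient Age": [r.age_years for r in records],
            "Patient Gender": [_GENDER_TO_CODE[r.gender] for r in records],
        }
    )


def write_manifest(records: Sequence[ImageRecord], path: str | Path) -> Path:
    """Write the records' metadata as a manifest CSV."""
    if not records:
        raise ManifestError("cannot write an empty manifest")
    path = Path(path)
    manifest_frame(records).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV into a normalized frame.

    Returns columns ``image_id``, ``gender`` (Male/Female),
    ``age_years``, ``age_bin`` and ``diseases`` (frozenset).
    """
    from cxrprior.phantom import age_to_bin

    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest is missing required column(s): {missing}")
    out = pd.DataFrame(
        {
            "image_id": df["Image Index"].astype(str),
            "gender": df["Patient Gender"].map(_CODE_TO_GENDER),
            "age_years": df["Patient Age"].astype(int),
            "diseases": df["Finding Labels"].astype(str).map(parse_labels),
        }
    )
    if out["gender"].isna().any():
        bad = sorted(df.loc[out["gender"].isna(), "Patient Gender"].unique())
        raise ManifestError(f"unknown gender code(s): {bad}")
    out["age_bin"] = out["age_years"].map(age_to_bin)
    return out
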