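"""Reading ROI samples (image + mask + labels) and writing feature tables.

Supported image inputs are single-frame grayscale DICOM (requires the
optional ``pydicom`` dependency), 8/16-bit grayscale PNG, and plain-text
numeric grids.  Masks may be PNG or text grids; any nonzero pixel is
treated as inside the ROI.  DICOM pixel data are used raw (no rescale
windowing): every matrix descriptor is computed after in-ROI
quantization, which removes affine intensity scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateROIError, FormatError, ValidationError
from .feature_names import ALL_FEATURES, METADATA_COLUMNS

GROUPS = ("BME", "INJ", "OST")
SEQUENCES = ("PDFSE", "STIR")

#: Smallest mask at which the second-order matrices are nondegenerate.
MIN_ROI_PIXELS = 16


@dataclass(frozen=True)
class ROISample:
    """One subject's masked 2D intensity image for one MRI sequence."""

    subject_id: str
    group: str
    sequence: str
    image: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sequence not in SEQUENCES:
            raise ValidationError(
                f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}"
            )
        image = np.asarray(self.image, dtype=np.float64)
        mask = np.asarray(self.mask) != 0
        if image.ndim != 2:
            raise FormatError(f"image must be 2D, got shape {image.shape}")
        if image.shape != mask.shape:
            raise FormatError(
                f"image shape {image.shape} does not match mask shape {mask.shape}"
            )
        if not np.all(np.isfinite(image)):
            raise FormatError("image contains non-finite intensities")
        n_in = int(mask.sum())
        if n_in < MIN_ROI_PIXELS:
            raise DegenerateROIError(
                f"mask has {n_in} pixels; at least {MIN_ROI_PIXELS} required"
            )
        object.__setattr__(self, "image", image)
        object.__setattr__(self, "mask", mask)

    @property
    def masked_values(self) -> np.ndarray:
        """Intensities inside the ROI, as a flat float array."""
        return self.image[self.mask]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise FormatError(
            f"cannot read {path}: DICOM support requires the optional "
            "'pydicom' dependency (pip install marrowtex[dicom])"
        ) from exc
    ds = pydicom.dcmread(os.fspath(path))
    arr = np.asarray(ds.pixel_array, dtype=np.float64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: only single-frame grayscale DICOM is supported")
    return arr


def _read_png(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "F", "1"):
            im = im.convert("I")
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel grayscale image")
    return arr


def _read_grid(path: Path) -> np.ndarray:
    arr = np.loadtxt(os.fspath(path), dtype=np.float64, ndmin=2)
    return arr


def read_image_file(path: str | os.PathLike) -> np.ndarray:
    """Read an intensity or mask grid from DICOM, PNG or a text grid."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    if suffix == ".png":
        return _read_png(path)
    if suffix in (".txt", ".csv", ".dat"):
        return _read_grid(path)
    raise FormatError(f"{path}: unsupported file type {suffix!r}")


def load_roi_sample(
    image_path: str | os.PathLike,
    mask_path: str | os.PathLike,
    subject_id: str,
    group: str,
    sequence: str,
) -> ROISample:
    """Load and validate one ROI sample from an image file and a mask file."""
    image = read_image_file(image_path)
    mask = read_image_file(mask_path)
    return ROISample(
        subject_id=str(subject_id),
        group=group,
        sequence=sequence,
        image=image,
        mask=mask != 0,
    )


MANIFEST_COLUMNS = ["subject_id", "group", "sequence", "image_path", "mask_path"]


def load_cohort_manifest(manifest_path: str | os.PathLike) -> list[ROISample]:
    """Load every ROI listed in a manifest CSV, preserving row order.

    The manifest must have columns subject_id, group, sequence,
    image_path, mask_path; relative paths are resolved against the
    manifest's directory.  Duplicate (subject, sequence) rows are
    rejected; a missing file raises an error naming the offending row.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no such manifest: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest is missing columns {missing}")
    keys = list(zip(df["subject_id"], df["sequence"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (subject, sequence) entries: {dupes}")
    base = manifest_path.parent
    samples: list[ROISample] = []
    for idx, row in df.iterrows():
        image_path = base / row["image_path"] if not os.path.isabs(row["image_path"]) else Path(row["image_path"])
        mask_path = base / row["mask_path"] if not os.path.isabs(row["mask_path"]) else Path(row["mask_path"])
        try:
            samples.append(
                load_roi_sample(
                    image_path, mask_path, row["subject_id"], row["group"], row["sequence"]
                )
            )
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"manifest row {idx}: {exc}") from exc
    return samples


#: Fixed column order of a written cohort feature table.
TABLE_COLUMNS = METADATA_COLUMNS + ALL_FEATURES


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract and return the table in canonical column order."""
    if len(table) == 0:
        raise ValidationError("feature table is empty")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table is missing columns {missing[:5]}...")
    table = table[TABLE_COLUMNS]
    if table[ALL_FEATURES].isna().any().any():
        raise ValidationError("feature table contains missing descriptor values")
    counts = table.groupby("subject_id")["sequence"].nunique()
    dup = table.duplicated(subset=["subject_id", "sequence"])
    if dup.any():
        raise ValidationError("duplicate (subject, sequence) rows in feature table")
    if (counts > 2).any():
        raise ValidationError("a subject contributes more than two rows")
    return table


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cohort feature table as CSV, 12 significant digits, canonical order."""
    table = validate_feature_table(table)
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={c: str for c in METADATA_COLUMNS})
    return validate_feature_table(df)
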