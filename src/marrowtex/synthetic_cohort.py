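"""Synthetic three-group, two-channel ROI cohorts with controllable texture.

Each ROI is built as

    image = subject_offset + noise_sd * S

where S is a unit-variance structured field: white noise smoothed with
a Gaussian kernel of width ``correlation_length``, discretized into
four equal-mass piecewise-constant plateau levels, mixed with fresh
white noise at ratio ``plateau_contrast``, stamped with
``blob_density`` * area bright micro-blob plateaus spread across the
gray range, and with one fixed bright anchor plateau pinning the top
of the range.  Because S is normalized, ``noise_sd`` is a pure
intensity scale: it moves MAD/std linearly and leaves every quantized
matrix descriptor untouched.  ``plateau_contrast`` sets the
structure-to-noise ratio (joint maximum / ASM), ``correlation_length``
sets plateau extent (run lengths / RLV), and ``blob_density`` seeds
isolated zones at distant gray levels (gray-level zone variance).  The
large random per-subject offset washes out pure location descriptors,
and a lognormal per-subject gain jitters the intensity scale, so group
contrasts live in dispersion and texture, not raw intensity position.

The default parameter table is calibrated so that, on the default seed
family, the PD-FSE channel orders joint maximum, long-run low-gray
emphasis and run-length variance as BME > INJ > OST, and the STIR
channel orders MAD and gray-level zone variance as BME < OST < INJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError, ValidationError
from .roi_io import GROUPS, SEQUENCES, ROISample

_PLATEAU_LEVELS = 4
_ANCHOR_AMPLITUDE = 4.0
_ANCHOR_RADIUS = 1.4
_MICRO_BLOB_RADIUS = 0.9
_MICRO_BLOB_AMPS = (0.5, 4.0)


@dataclass(frozen=True)
class CellParams:
    """Texture parameters of one (group, sequence) cell."""

    correlation_length: float  # pixels; drives run lengths / coarseness
    blob_density: float  # bright micro-blobs per pixel; drives GLZV
    noise_sd: float  # overall intensity scale; drives MAD / std
    plateau_contrast: float  # structure-to-noise ratio; drives joint maximum

    def __post_init__(self) -> None:
        if min(self.blob_density, self.noise_sd, self.plateau_contrast) < 0 or (
            self.correlation_length < 0
        ):
            raise ParameterError("cell parameters must be nonnegative")


# Calibrated default table (see class docstring for the target orderings).
DEFAULT_PARAMS: dict[tuple[str, str], CellParams] = {
    ("BME", "PDFSE"): CellParams(2.5, 0.004, 10.0, 20.4),
    ("INJ", "PDFSE"): CellParams(2.3, 0.004, 10.0, 18.0),
    ("OST", "PDFSE"): CellParams(2.1, 0.004, 10.0, 15.8),
    ("BME", "STIR"): CellParams(2.3, 0.004, 9.2, 9.0),
    ("INJ", "STIR"): CellParams(2.3, 0.013, 10.8, 9.0),
    ("OST", "STIR"): CellParams(2.3, 0.0085, 10.0, 9.0),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Configuration of a synthetic cohort."""

    n_per_group: tuple[int, int, int] = (41, 37, 43)
    size: int = 48
    mask_shape: str = "ellipse"  # full | ellipse | blob
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    seed: int = 0
    base_offset: float = 2048.0
    offset_sd: float = 60.0
    #: lognormal sd of the per-subject intensity gain (scanner gain variation);
    #: spreads subject-level dispersion so no single scale descriptor becomes
    #: an implausibly noise-free group probe
    gain_jitter: float = 0.08

    def __post_init__(self) -> None:
        if self.mask_shape not in ("full", "ellipse", "blob"):
            raise ParameterError(f"unknown mask shape {self.mask_shape!r}")
        if any(n <= 0 for n in self.n_per_group):
            raise ParameterError("group sizes must be positive")
        for g in GROUPS:
            for s in SEQUENCES:
                if (g, s) not in self.params:
                    raise ValidationError(f"params table missing cell ({g}, {s})")

    def cell(self, group: str, sequence: str) -> CellParams:
        return self.params[(group, sequence)]


def null_spec(seed: int = 0) -> SyntheticCohortSpec:
    """A spec whose six cells are identical: no group signal in either channel."""
    cell = CellParams(2.3, 0.0075, 10.0, 12.0)
    return SyntheticCohortSpec(
        params={(g, s): cell for g in GROUPS for s in SEQUENCES}, seed=seed
    )


def _make_mask(shape: str, size: int, rng: np.random.Generator) -> np.ndarray:
    if shape == "full":
        return np.ones((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    a = 0.42 * size
    ellipse = ((yy - c) / a) ** 2 + ((xx - c) / a) ** 2 <= 1.0
    if shape == "ellipse":
        return ellipse
    # blob: smooth random field thresholded inside the ellipse, largest component
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=6.0)
    mask = ellipse & (f > np.quantile(f[ellipse], 0.35))
    labeled, n = ndimage.label(mask)
    if n == 0:
        return ellipse
    sizes = np.bincount(labeled.ravel())[1:]
    blob = labeled == (np.argmax(sizes) + 1)
    return blob if blob.sum() >= 64 else ellipse


def _structured_field(
    size: int, cell: CellParams, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance structured field: smoothed noise discretized into
    equal-mass plateau levels, mixed with white noise at the cell's
    contrast, stamped with one fixed bright anchor plateau pinning the
    top of the intensity range (stable level allocation under min-max
    quantization; the dark levels stay populated by bulk plateaus) and
    with ``blob_density`` * area bright micro-blobs whose amplitudes
    are spread uniformly across the range (isolated zones at distant
    gray levels with negligible pixel mass)."""
    g = rng.standard_normal((size, size))
    if cell.correlation_length > 0:
        g = ndimage.gaussian_filter(g, sigma=cell.correlation_length, mode="reflect")
        sd = g.std()
        if sd > 0:
            g = g / sd
    edges = np.quantile(g, np.linspace(0, 1, _PLATEAU_LEVELS + 1)[1:-1])
    values = np.linspace(-1.5, 1.5, _PLATEAU_LEVELS)
    plateaus = values[np.digitize(g, edges)]
    c = cell.plateau_contrast
    var_plat = float(np.var(values))  # equal-mass occupancy
    combined = (c * plateaus + rng.standard_normal((size, size))) / np.sqrt(
        c * c * var_plat + 1.0
    )
    # expected variance added by micro-blob replacement, normalized out so
    # that blob density does not leak into the intensity scale
    lo_a, hi_a = _MICRO_BLOB_AMPS
    e_amp2 = (hi_a**3 - lo_a**3) / (3.0 * (hi_a - lo_a))
    blob_fraction = min(1.0, cell.blob_density * np.pi * _MICRO_BLOB_RADIUS**2)
    combined = combined / np.sqrt(1.0 + blob_fraction * (e_amp2 - 1.0))
    n_micro = rng.poisson(cell.blob_density * size * size)
    if n_micro or cell.plateau_contrast > 0:
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_micro):
            cy, cx = rng.uniform(0, size, size=2)
            amp = rng.uniform(*_MICRO_BLOB_AMPS)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= _MICRO_BLOB_RADIUS**2
            combined = np.where(disc, amp, combined)
        if cell.plateau_contrast > 0:
            cy, cx = rng.uniform(0.15 * size, 0.85 * size, size=2)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= _ANCHOR_RADIUS**2
            combined = np.where(disc, _ANCHOR_AMPLITUDE, combined)
    return combined


def generate_roi(
    spec: SyntheticCohortSpec,
    group: str,
    sequence: str,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> ROISample:
    """One synthetic ROI for the given cell; deterministic given ``rng`` state."""
    cell = spec.cell(group, sequence)
    s = _structured_field(spec.size, cell, rng)
    offset = spec.base_offset + rng.normal(0.0, spec.offset_sd)
    gain = float(np.exp(rng.normal(0.0, spec.gain_jitter)))
    image = offset + cell.noise_sd * gain * s
    mask = _make_mask(spec.mask_shape, spec.size, rng)
    return ROISample(
        subject_id=subject_id, group=group, sequence=sequence, image=image, mask=mask
    )


def _subject_rng(spec: SyntheticCohortSpec, subject_index: int, sequence: str):
    return np.random.default_rng([spec.seed, subject_index, SEQUENCES.index(sequence)])


def generate_cohort(spec: SyntheticCohortSpec) -> list[ROISample]:
    """All subjects of the cohort, two ROIs each (one per sequence channel).

    Per-subject reseeding makes every ROI reproducible independently of
    generation order.
    """
    samples: list[ROISample] = []
    subject_index = 0
    for group, n in zip(GROUPS, spec.n_per_group):
        for _ in range(n):
            subject_id = f"S{subject_index:03d}"
            for sequence in SEQUENCES:
                rng = _subject_rng(spec, subject_index, sequence)
                samples.append(
                    generate_roi(spec, group, sequence, rng, subject_id=subject_id)
                )
            subject_index += 1
    return samples


def write_cohort(spec: SyntheticCohortSpec, outdir) -> str:
    """Write the cohort as 16-bit PNGs + mask PNGs + a manifest CSV.

    Intensities are rounded to integers on a fixed global scale (no
    per-image rescaling), so group contrasts in intensity dispersion
    survive the round trip.  Returns the manifest path.
    """
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in generate_cohort(spec):
        stem = f"{sample.subject_id}_{sample.sequence}"
        img = np.clip(np.round(sample.image), 0, 65535).astype(np.uint16)
        Image.fromarray(img).save(outdir / f"{stem}.png")
        Image.fromarray(
            (sample.mask * 255).astype(np.uint8)
        ).save(outdir / f"{stem}_mask.png")
        rows.append(
            {
                "subject_id": sample.subject_id,
                "group": sample.group,
                "sequence": sample.sequence,
                "image_path": f"{stem}.png",
                "mask_path": f"{stem}_mask.png",
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return str(manifest)


#: Names of the five planted discriminative descriptors, by sequence channel.
PLANTED_FEATURES = (
    ("PDFSE", "glcm_joint_max"),
    ("PDFSE", "glrlm_lrlge"),
    ("PDFSE", "glrlm_rlv"),
    ("STIR", "fo_mad"),
    ("STIR", "glszm_glzv"),
)
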