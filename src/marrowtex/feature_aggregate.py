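"""Assemble the 81-entry feature vector per ROI; batch extraction over a cohort."""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from .errors import DegenerateROIError, ValidationError
from .feature_names import ALL_FEATURES, METADATA_COLUMNS
from .features_firstorder import first_order_features
from .features_matrix import glcm_features, glrlm_features, glszm_features
from .features_tamura_lbp import lbp_features, tamura_features
from .quantize import DEFAULT_NG, quantize_roi
from .roi_io import ROISample

logger = logging.getLogger(__name__)


def extract_all(sample: ROISample, Ng: int = DEFAULT_NG) -> dict[str, float]:
    """Compute all 81 descriptors of one ROI (17 FO + 22 GLCM + 16 GLRLM
    + 16 GLSZM + 6 Tamura + 4 LBP), in canonical column order.

    First-order descriptors are computed on the raw masked intensities;
    the matrix families share one quantization at ``Ng`` levels.
    """
    out: dict[str, float] = {}
    families = [("first-order", lambda: first_order_features(sample))]
    q = quantize_roi(sample, Ng)
    families += [
        ("GLCM", lambda: glcm_features(q)),
        ("GLRLM", lambda: glrlm_features(q)),
        ("GLSZM", lambda: glszm_features(q)),
        ("Tamura", lambda: tamura_features(sample)),
        ("LBP", lambda: lbp_features(sample)),
    ]
    for family, fn in families:
        try:
            out.update(fn())
        except DegenerateROIError as exc:
            raise DegenerateROIError(f"{family} family failed: {exc}") from exc
    assert list(out) == ALL_FEATURES
    values = np.array(list(out.values()))
    if not np.all(np.isfinite(values)):
        bad = [k for k, v in out.items() if not np.isfinite(v)]
        raise ValidationError(f"non-finite descriptor values: {bad}")
    return out


def extract_cohort(
    samples: list[ROISample],
    Ng: int = DEFAULT_NG,
    max_failure_fraction: float = 0.10,
) -> pd.DataFrame:
    """Extract features for every sample; one row per (subject, sequence).

    Individual failures are logged and the row skipped; if more than
    ``max_failure_fraction`` of samples fail, the whole extraction is
    aborted.
    """
    if not samples:
        raise ValidationError("no samples to extract")
    rows = []
    failures = []
    for sample in samples:
        t0 = time.perf_counter()
        try:
            features = extract_all(sample, Ng)
        except (DegenerateROIError, ValidationError) as exc:
            logger.warning(
                "skipping %s/%s: %s", sample.subject_id, sample.sequence, exc
            )
            failures.append((sample.subject_id, sample.sequence, str(exc)))
            continue
        logger.debug(
            "extracted %s/%s in %.1f ms",
            sample.subject_id,
            sample.sequence,
            1e3 * (time.perf_counter() - t0),
        )
        rows.append(
            {
                "subject_id": sample.subject_id,
                "group": sample.group,
                "sequence": sample.sequence,
                **features,
            }
        )
    if len(failures) > max_failure_fraction * len(samples):
        raise ValidationError(
            f"{len(failures)}/{len(samples)} samples failed extraction: "
            f"{failures[:3]}..."
        )
    if not rows:
        raise ValidationError("every sample failed extraction")
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + ALL_FEATURES)
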