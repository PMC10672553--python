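"""First-order (histogram / intensity) descriptors of a masked ROI.

Seventeen descriptors computed on the raw masked intensities: mean, std
(population), variance, skewness, kurtosis (Pearson; normal -> 3),
median, p10/p25/p75/p90, min, max, range, IQR, MAD (mean absolute
deviation from the mean), plus histogram energy and entropy over 32
equal-width bins of the masked range.  Degenerate conventions for a
constant ROI: skewness = kurtosis = 0, entropy = 0, energy = 1.
"""

from __future__ import annotations

import numpy as np

from .feature_names import FIRST_ORDER
from .roi_io import ROISample

HIST_BINS = 32


def _histogram_frequencies(values: np.ndarray, bins: int = HIST_BINS) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.array([1.0])
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    return counts / counts.sum()


def first_order_features(sample: ROISample) -> dict[str, float]:
    """Return the 17 first-order descriptors over the masked intensities."""
    x = sample.masked_values
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population, divisor n
    std = float(np.sqrt(var))
    centered = x - mean
    if std > 0:
        skew = float(np.mean(centered**3) / std**3)
        kurt = float(np.mean(centered**4) / std**4)
    else:
        skew = 0.0
        kurt = 0.0
    p10, p25, median, p75, p90 = (
        float(v) for v in np.percentile(x, [10, 25, 50, 75, 90])
    )
    mn, mx = float(x.min()), float(x.max())
    f = _histogram_frequencies(x)
    nz = f[f > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    energy = float(np.sum(f**2))
    out = {
        "fo_energy": energy,
        "fo_entropy": entropy,
        "fo_iqr": p75 - p25,
        "fo_kurtosis": kurt,
        "fo_mad": float(np.mean(np.abs(centered))),
        "fo_max": mx,
        "fo_mean": mean,
        "fo_median": median,
        "fo_min": mn,
        "fo_p10": p10,
        "fo_p25": p25,
        "fo_p75": p75,
        "fo_p90": p90,
        "fo_range": mx - mn,
        "fo_skewness": skew,
        "fo_std": std,
        "fo_variance": var,
    }
    assert list(out) == FIRST_ORDER
    return out
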