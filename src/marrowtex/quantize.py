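"""In-ROI gray-level discretization.

All matrix descriptors operate on levels 1..Ng obtained by equal-width
binning of the masked intensity range.  Because the bin edges are
calibrated per ROI (min-max inside the mask), the levels — and hence
every downstream matrix descriptor — are invariant under positive
affine rescaling of the source intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .roi_io import ROISample

DEFAULT_NG = 32


@dataclass(frozen=True)
class QuantizedROI:
    """Integer gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    Ng: int
    lo: float
    hi: float

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def quantize_roi(sample: ROISample, Ng: int = DEFAULT_NG) -> QuantizedROI:
    """Equal-width binning of the masked intensity range into ``Ng`` levels.

    A pixel with intensity x maps to floor((x - lo) / (hi - lo) * Ng) + 1,
    clipped to [1, Ng]; the top edge therefore falls in bin Ng.  A constant
    ROI (hi == lo) maps every masked pixel to level 1.
    """
    if Ng < 2:
        raise ParameterError(f"Ng must be >= 2, got {Ng}")
    values = sample.masked_values
    lo = float(values.min())
    hi = float(values.max())
    levels = np.zeros(sample.image.shape, dtype=np.int64)
    if hi == lo:
        levels[sample.mask] = 1
    else:
        scaled = (sample.image[sample.mask] - lo) / (hi - lo) * Ng
        levels[sample.mask] = np.clip(np.floor(scaled).astype(np.int64) + 1, 1, Ng)
    return QuantizedROI(levels=levels, mask=sample.mask, Ng=int(Ng), lo=lo, hi=hi)
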