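"""Single-level stationary (undecimated) 3D coiflet-1 wavelet decomposition.

Only the all-low-pass (LLL) and all-high-pass (HHH) subbands are produced,
via separable convolution with the coif1 decomposition filters and symmetric
boundary extension.  The transform is undecimated, so subbands share the
input grid and spacing, and the operator is linear.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .image import ImageVolume

_WAVELET = pywt.Wavelet("coif1")
_DEC_LO = np.asarray(_WAVELET.dec_lo, dtype=np.float64)
_DEC_HI = np.asarray(_WAVELET.dec_hi, dtype=np.float64)


def _separable(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = data
    for axis in range(data.ndim):
        # correlate1d with 'reflect' = symmetric (half-sample) extension
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="reflect")
    return out


def swt3_coif1(volume: ImageVolume) -> dict[str, ImageVolume]:
    """Return the LLL and HHH subbands of a single-level stationary transform."""
    if min(volume.shape) < len(_DEC_LO) // 2:
        raise ValueError(
            f"volume shape {volume.shape} too small for the coif1 filter "
            f"(length {len(_DEC_LO)})")
    return {
        "LLL": volume.copy_with(_separable(volume.data, _DEC_LO)),
        "HHH": volume.copy_with(_separable(volume.data, _DEC_HI)),
    }


def lowpass_gain() -> float:
    """DC gain of the LLL branch: (sum of coif1 low-pass taps)**3."""
    return float(_DEC_LO.sum() ** 3)
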