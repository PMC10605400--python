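"""Fixed-bin-count gray-level quantization of masked intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageVolume, as_mask


@dataclass
class QuantizationConfig:
    """Bin counts per image type: original images use 32 bins; wavelet
    subbands use 8 bins for T2 and 16 for ADC."""

    bins_original: int = 32
    bins_wavelet_t2: int = 8
    bins_wavelet_adc: int = 16

    def __post_init__(self) -> None:
        if min(self.bins_original, self.bins_wavelet_t2, self.bins_wavelet_adc) < 2:
            raise ValueError("all bin counts must be >= 2")

    def bins_for(self, modality: str, image_filter: str) -> int:
        if image_filter == "original":
            return self.bins_original
        return self.bins_wavelet_t2 if modality == "T2" else self.bins_wavelet_adc


@dataclass
class QuantizedVolume:
    """Integer gray-level labels in 1..n_levels over a mask."""

    labels: np.ndarray    # int array, 0 outside the mask
    mask: np.ndarray      # boolean
    n_levels: int

    def masked_labels(self) -> np.ndarray:
        return self.labels[self.mask]


def quantize_fixed_bins(volume: ImageVolume | np.ndarray, mask,
                        n_bins: int) -> QuantizedVolume:
    """Equal-width binning over the masked intensity range.

    Bin edges span [min, max] of the masked voxels; the maximum value is
    assigned to the top bin; a constant region maps entirely to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    m = as_mask(mask)
    if not m.any():
        raise ValueError("mask is empty")
    vals = data[m]
    lo, hi = float(vals.min()), float(vals.max())
    labels = np.zeros(data.shape, dtype=np.int32)
    if hi == lo:
        labels[m] = 1
        return QuantizedVolume(labels, m, n_bins)
    width = (hi - lo) / n_bins
    binned = np.floor((vals - lo) / width).astype(np.int32) + 1
    labels[m] = np.clip(binned, 1, n_bins)
    return QuantizedVolume(labels, m, n_bins)
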