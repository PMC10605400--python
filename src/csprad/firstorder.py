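"""First-order intensity statistics over the masked raw intensities."""

from __future__ import annotations

import numpy as np

from .image import ImageVolume, as_mask
from .quantize import quantize_fixed_bins

FIRSTORDER_FEATURES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
)


def firstorder_features(volume: ImageVolume, mask, n_bins: int = 32,
                        ) -> dict[str, float]:
    """The standard 18-feature first-order set.

    Entropy and Uniformity are computed on a fixed-bin-count discretization
    (``n_bins``); moments use population (biased) estimators; Kurtosis is
    not excess-corrected (a normal distribution scores 3).
    """
    m = as_mask(mask)
    if not m.any():
        raise ValueError("mask is empty")
    v = volume.data[m].astype(np.float64)
    n = v.size
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]

    q = quantize_fixed_bins(volume, m, n_bins)
    counts = np.bincount(q.masked_labels(), minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / n

    if sd > 0:
        skew = float(((v - mean) ** 3).mean() / sd ** 3)
        kurt = float(((v - mean) ** 4).mean() / var ** 2)
    else:
        skew, kurt = 0.0, 0.0

    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": float((v ** 2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(v.max()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(v.min()),
        "Range": float(v.max() - v.min()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt((v ** 2).mean())),
        "Skewness": skew,
        "TotalEnergy": float(volume.voxel_volume * (v ** 2).sum()),
        "Uniformity": float((p ** 2).sum()),
        "Variance": var,
    }
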