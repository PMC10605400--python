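"""Image conditioning: bias-field correction, T2 normalization, resampling.

Pipeline order is bias correction -> reference-VOI normalization (T2 only;
ADC is a quantitative map and keeps its physical scale) -> resampling onto
fixed voxel grids (default 0.4 x 0.4 x 3.0 mm for T2, 0.8 x 0.8 x 3.0 mm for
ADC) with b-spline interpolation for images and thresholded linear
interpolation for masks.

The built-in bias correction is an order-2 log-domain polynomial
least-squares fit (with a passthrough mode for externally corrected input);
it is matched to the phantom's generative bias model so that ground-truth
recovery is testable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .image import ImageVolume, as_mask
from .phantom import LesionSample, _physical_coords, _poly2_design


@dataclass
class PreprocessConfig:
    t2_target_spacing: tuple[float, float, float] = (0.4, 0.4, 3.0)
    adc_target_spacing: tuple[float, float, float] = (0.8, 0.8, 3.0)
    interpolation_order: int = 3          # b-spline order for images
    bias_correction: str = "builtin"      # or "passthrough"

    def __post_init__(self) -> None:
        for sp in (self.t2_target_spacing, self.adc_target_spacing):
            if any(s <= 0 for s in sp):
                raise ValueError("target spacings must be strictly positive")
        if self.interpolation_order not in range(4):
            raise ValueError("interpolation order must be in 0..3")
        if self.bias_correction not in ("builtin", "passthrough"):
            raise ValueError("bias_correction must be 'builtin' or 'passthrough'")


class EmptyMaskWarning(UserWarning):
    """A mask became empty after resampling; the sample should be excluded."""


def correct_bias(volume: ImageVolume, mask: np.ndarray | ImageVolume | None = None,
                 ) -> ImageVolume:
    """Remove a multiplicative low-frequency component.

    Fits an order-2 polynomial to log-intensities over ``mask`` (whole volume
    when None) by least squares, divides by its exponential, and rescales so
    the mean over the mask is unchanged.
    """
    m = np.ones(volume.shape, dtype=bool) if mask is None else as_mask(mask)
    vals = volume.data[m]
    n_bad = int(np.count_nonzero(vals <= 0))
    if n_bad:
        raise ValueError(
            f"bias correction requires positive intensities: {n_bad} "
            "non-positive voxels inside the mask")
    xs, ys, zs = _physical_coords(volume.shape, volume.spacing)
    design = _poly2_design(xs, ys, zs).reshape(-1, 10)
    logv = np.log(volume.data.reshape(-1))
    sel = m.reshape(-1)
    coeffs, *_ = np.linalg.lstsq(design[sel], logv[sel], rcond=None)
    fitted = (design @ coeffs).reshape(volume.shape)
    corrected = volume.data / np.exp(fitted)
    corrected *= vals.mean() / corrected[m].mean()
    return volume.copy_with(corrected)


def estimate_log_bias(volume: ImageVolume, mask=None) -> np.ndarray:
    """The fitted log-bias surface removed by :func:`correct_bias`."""
    m = np.ones(volume.shape, dtype=bool) if mask is None else as_mask(mask)
    xs, ys, zs = _physical_coords(volume.shape, volume.spacing)
    design = _poly2_design(xs, ys, zs).reshape(-1, 10)
    logv = np.log(np.clip(volume.data.reshape(-1), 1e-12, None))
    coeffs, *_ = np.linalg.lstsq(design[m.reshape(-1)], logv[m.reshape(-1)],
                                 rcond=None)
    return (design @ coeffs).reshape(volume.shape)


def normalize_t2(volume: ImageVolume, reference_mask) -> ImageVolume:
    """Divide by the mean intensity inside the healthy-PZ reference VOI."""
    m = as_mask(reference_mask)
    if not m.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(volume.data[m].mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be > 0, got {ref_mean}")
    return volume.copy_with(volume.data / ref_mean)


def _target_grid(volume: ImageVolume, target_spacing):
    """New grid covering the same physical extent (voxel-centre convention)."""
    extent = volume.physical_extent()
    size = [max(1, int(round(e / t))) for e, t in zip(extent, target_spacing)]
    # centre the new grid on the old physical extent (voxel-centre origins)
    origin = [(o - 0.5 * s + 0.5 * n * s) - 0.5 * m * t + 0.5 * t
              for o, s, n, m, t in zip(volume.origin, volume.spacing,
                                       volume.shape, size, target_spacing)]
    return size, origin


def resample_volume(volume: ImageVolume, target_spacing, order: int = 3,
                    ) -> ImageVolume:
    """Resample onto ``target_spacing`` with b-spline interpolation.

    The output grid covers the same physical extent as the input (within one
    voxel at each face).
    """
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    if any(n * s <= 0 for n, s in zip(volume.shape, volume.spacing)):
        raise ValueError("degenerate physical extent")
    if (target_spacing == volume.spacing):
        return volume.copy_with(volume.data.copy())
    size, origin = _target_grid(volume, target_spacing)
    img = volume.to_sitk()
    interp = {0: sitk.sitkNearestNeighbor, 1: sitk.sitkLinear,
              2: sitk.sitkBSpline2, 3: sitk.sitkBSpline}[order]
    res = sitk.Resample(img, size=[int(s) for s in size],
                        transform=sitk.Transform(),
                        interpolator=interp,
                        outputOrigin=[float(o) for o in origin],
                        outputSpacing=list(target_spacing),
                        outputDirection=img.GetDirection(),
                        defaultPixelValue=float(np.median(volume.data)))
    return ImageVolume.from_sitk(res)


def resample_mask(mask: ImageVolume, target_spacing) -> ImageVolume:
    """Linear interpolation of the binary indicator, thresholded at 0.5."""
    data = as_mask(mask).astype(np.float64)
    indicator = ImageVolume(data, spacing=mask.spacing, origin=mask.origin)
    res = resample_volume(indicator, target_spacing, order=1)
    out = (res.data >= 0.5).astype(np.float64)
    if not out.any():
        warnings.warn("mask is empty after resampling; sample should be "
                      "excluded downstream", EmptyMaskWarning)
    return ImageVolume(out, spacing=res.spacing, origin=res.origin)


def preprocess_sample(sample: LesionSample,
                      config: PreprocessConfig | None = None) -> LesionSample:
    """Run the full conditioning chain on one lesion sample."""
    cfg = config or PreprocessConfig()
    t2, adc = sample.t2, sample.adc
    if cfg.bias_correction == "builtin":
        t2 = correct_bias(t2)
        adc = correct_bias(adc)
    t2 = normalize_t2(t2, sample.t2_reference_mask)
    order = cfg.interpolation_order
    t2 = resample_volume(t2, cfg.t2_target_spacing, order)
    adc = resample_volume(adc, cfg.adc_target_spacing, order)
    return replace(
        sample, t2=t2, adc=adc,
        t2_lesion_mask=resample_mask(sample.t2_lesion_mask, cfg.t2_target_spacing),
        adc_lesion_mask=resample_mask(sample.adc_lesion_mask, cfg.adc_target_spacing),
        t2_reference_mask=resample_mask(sample.t2_reference_mask,
                                        cfg.t2_target_spacing),
        adc_reference_mask=resample_mask(sample.adc_reference_mask,
                                         cfg.adc_target_spacing),
    )
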