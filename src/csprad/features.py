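"""Feature catalog assembly: 293 features per modality, 586 per lesion.

Per modality (T2, ADC): the original image contributes shape (14),
first-order (18), GLCM (24), GLRLM (16), GLSZM (16), GLDM (14) and
NGTDM (5) features (107); each stationary-wavelet subband (LLL, HHH)
contributes every non-shape class (93).  Feature names follow the
``modality-filter_class_FeatureName`` scheme, e.g.
``ADC-original_glcm_ClusterShade``.

Shape features are computed once, from the ADC-grid lesion mask, and
emitted under both modality prefixes (shape is a property of the mask,
not the intensities; the ADC grid is the fixed reference).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .image import ImageVolume
from .phantom import LesionSample
from .quantize import QuantizationConfig, quantize_fixed_bins
from .shape import SHAPE_FEATURES, shape_features
from .texture import (GLCM_FEATURES, GLDM_FEATURES, GLRLM_FEATURES,
                      GLSZM_FEATURES, NGTDM_FEATURES, glcm_features,
                      gldm_features, glrlm_features, glszm_features,
                      ngtdm_features)
from .wavelet import swt3_coif1

logger = logging.getLogger(__name__)

MODALITIES = ("T2", "ADC")
FILTERS = ("original", "wavelet-LLL", "wavelet-HHH")
CLINICAL_COVARIATES = ("age", "psa", "prostate_volume", "psa_density",
                       "mean_adc")

_TEXTURE_CLASSES = (
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("gldm", GLDM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
)


def catalog_names(modality: str | None = None) -> list[str]:
    """The deterministic ordered feature-name catalog."""
    mods = (modality,) if modality else MODALITIES
    names = []
    for mod in mods:
        for filt in FILTERS:
            if filt == "original":
                names += [f"{mod}-{filt}_shape_{f}" for f in SHAPE_FEATURES]
            names += [f"{mod}-{filt}_firstorder_{f}" for f in FIRSTORDER_FEATURES]
            for cls, feats in _TEXTURE_CLASSES:
                names += [f"{mod}-{filt}_{cls}_{f}" for f in feats]
    return names


def _texture_block(volume: ImageVolume, mask: np.ndarray, n_bins: int,
                   prefix: str) -> dict[str, float]:
    out = {}
    q = quantize_fixed_bins(volume, mask, n_bins)
    single_voxel = int(mask.sum()) < 2
    for cls, names in _TEXTURE_CLASSES:
        if cls == "glcm" and single_voxel:
            vals = dict.fromkeys(names, float("nan"))
        else:
            fn = {"glcm": glcm_features, "glrlm": glrlm_features,
                  "glszm": glszm_features, "gldm": gldm_features,
                  "ngtdm": ngtdm_features}[cls]
            vals = fn(q)
        out.update({f"{prefix}_{cls}_{k}": vals[k] for k in names})
    return out


def extract_features(sample: LesionSample,
                     quantization: QuantizationConfig | None = None,
                     ) -> dict[str, float]:
    """Extract the full 586-feature vector from one preprocessed sample."""
    qc = quantization or QuantizationConfig()
    shape_vals = shape_features(sample.adc_lesion_mask)
    out: dict[str, float] = {}
    for mod in MODALITIES:
        volume = sample.t2 if mod == "T2" else sample.adc
        mask_vol = sample.t2_lesion_mask if mod == "T2" else sample.adc_lesion_mask
        mask = mask_vol.data > 0.5
        if not mask.any():
            raise ValueError(f"{sample.lesion_id}: empty lesion mask on {mod}")
        subbands = swt3_coif1(volume)
        for filt in FILTERS:
            prefix = f"{mod}-{filt}"
            if filt == "original":
                img = volume
                out.update({f"{prefix}_shape_{k}": shape_vals[k]
                            for k in SHAPE_FEATURES})
            else:
                img = subbands[filt.split("-")[1]]
            n_bins = qc.bins_for(mod, filt)
            out.update({f"{prefix}_firstorder_{k}": v for k, v in
                        firstorder_features(img, mask, n_bins=n_bins).items()})
            out.update(_texture_block(img, mask, n_bins, prefix))
    order = catalog_names()
    return {k: out[k] for k in order}


class RadiomicsExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer: lesion samples -> feature table.

    ``transform`` accepts a list of preprocessed :class:`LesionSample` and
    returns a DataFrame (one row per lesion, 586 columns) indexed by
    lesion id.
    """

    def __init__(self, bins_original: int = 32, bins_wavelet_t2: int = 8,
                 bins_wavelet_adc: int = 16):
        self.bins_original = bins_original
        self.bins_wavelet_t2 = bins_wavelet_t2
        self.bins_wavelet_adc = bins_wavelet_adc

    def _config(self) -> QuantizationConfig:
        return QuantizationConfig(self.bins_original, self.bins_wavelet_t2,
                                  self.bins_wavelet_adc)

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: list[LesionSample]) -> pd.DataFrame:
        qc = self._config()
        rows = {s.lesion_id: extract_features(s, qc) for s in X}
        return pd.DataFrame.from_dict(rows, orient="index")

    def get_feature_names_out(self, input_features=None):
        return np.asarray(catalog_names())


def build_feature_table(samples: list[LesionSample], manifest: pd.DataFrame,
                        quantization: QuantizationConfig | None = None,
                        ) -> pd.DataFrame:
    """Tidy lesion table: clinical covariates + 586 features + zone + label.

    Lesions with any undefined (NaN) feature are dropped with a logged count.
    """
    qc = quantization or QuantizationConfig()
    extractor = RadiomicsExtractor(qc.bins_original, qc.bins_wavelet_t2,
                                   qc.bins_wavelet_adc)
    radiomic = extractor.transform(samples)
    meta = manifest.set_index("lesion_id")
    table = meta.join(radiomic, how="inner")
    n_bad = int(table.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("dropping %d lesion(s) with undefined features", n_bad)
        table = table.dropna()
    return table.reset_index().rename(columns={"index": "lesion_id"})


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Candidate predictor columns: clinical covariates + radiomic features."""
    radiomic = [c for c in table.columns if c in set(catalog_names())]
    clinical = [c for c in CLINICAL_COVARIATES if c in table.columns]
    return clinical + radiomic
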