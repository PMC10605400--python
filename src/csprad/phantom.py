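"""Synthetic mpMRI lesion phantoms with known class structure.

Generates cohorts of paired T2-weighted / ADC lesion volumes, lesion and
healthy-peripheral-zone reference masks, and patient-level clinical
covariates, with a configurable separation between clinically significant
(csPC, ISUP grade group >= 2) and non-significant lesions.

The texture model is a stationary Gaussian random field (Gaussian-smoothed
white noise with a tunable spatial correlation length), modulated inside the
lesion by class-conditional mean level and marginal SD, and multiplied by a
smooth low-order bias field emulating B1 inhomogeneity.  Class-conditional
mean levels are split around the configured marginal so that the
prevalence-weighted cohort marginal matches the configured population value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageVolume

CS_LABEL = "csPC"
NONCS_LABEL = "non-csPC"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TextureChannelParams:
    """Generative parameters for one imaging channel.

    level / level_sd: between-lesion mean intensity and its SD (channel units);
    texture_sd: within-lesion marginal SD of the random field;
    sd_jitter_cv: between-lesion coefficient of variation of the texture SD
    (lesions of the same class differ in heterogeneity — without this, any
    variance-sensitive feature would separate the classes perfectly);
    corr_mm: spatial correlation length of the field (mm).
    """

    level: float
    level_sd: float
    texture_sd: float
    corr_mm: float
    sd_jitter_cv: float = 0.4

    def __post_init__(self) -> None:
        if self.corr_mm <= 0:
            raise ValueError("correlation length must be > 0")
        if self.texture_sd < 0 or self.level_sd < 0 or self.sd_jitter_cv < 0:
            raise ValueError("SDs must be >= 0")


@dataclass
class CovariateClassParams:
    """Per-class clinical covariate distributions.

    age is normal; PSA (ng/mL) and prostate volume (mL) are lognormal with
    the given mean/SD on the natural scale.  PSA density is always computed
    as psa / prostate_volume, never drawn.
    """

    age_mean: float
    age_sd: float
    psa_mean: float
    psa_sd: float
    volume_mean: float
    volume_sd: float


# Defaults chosen so the prevalence-weighted cohort marginals reproduce the
# target population: PSA 7.9 +/- 4.8 ng/mL, prostate volume 51.6 +/- 27.3 mL,
# PSA density ~0.18, age ~69 y, at csPC prevalence 0.712.
_DEFAULT_COVARIATES = {
    CS_LABEL: CovariateClassParams(age_mean=70.0, age_sd=6.5,
                                   psa_mean=8.8, psa_sd=5.0,
                                   volume_mean=47.0, volume_sd=24.0),
    NONCS_LABEL: CovariateClassParams(age_mean=67.2, age_sd=7.0,
                                      psa_mean=5.9, psa_sd=3.2,
                                      volume_mean=63.0, volume_sd=31.0),
}

# Mean lesion ADC target 653 x 10^-6 mm^2/s; T2 level in arbitrary units.
_DEFAULT_TEXTURE = {
    "t2": TextureChannelParams(level=400.0, level_sd=60.0, texture_sd=60.0,
                               corr_mm=0.9),
    "adc": TextureChannelParams(level=653.0, level_sd=180.0, texture_sd=130.0,
                                corr_mm=1.8),
}

# csPC lesions: lower mean ADC, more heterogeneous T2 texture.
_DEFAULT_EFFECTS = {
    "t2_level": 0.0,
    "adc_level": -1.0,       # in units of adc level_sd
    "t2_texture_sd": 0.6,    # fractional SD split between classes
    "adc_texture_sd": 0.0,
}

# P(zone == PZ | PI-RADS category), from the emulated cohort structure.
_DEFAULT_ZONE_PROBS = {4: 0.919, 5: 0.487}


@dataclass
class PhantomConfig:
    """Full configuration of the synthetic cohort generator."""

    n_patients: int = 99
    # counts of patients with exactly 1, 2, 3 lesions; must sum to n_patients.
    lesion_multiplicity: tuple[int, int, int] | None = (89, 8, 2)
    # used only when lesion_multiplicity is None.
    lesions_per_patient_probs: tuple[float, float, float] = (0.9, 0.08, 0.02)
    cs_prevalence: float = 0.712
    pirads4_prob: float = 0.667
    zone_probs: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_ZONE_PROBS))
    volume_shape: tuple[int, int, int] = (40, 40, 8)  # T2 native grid
    native_spacing_t2: tuple[float, float, float] = (0.5, 0.5, 3.0)
    native_spacing_adc: tuple[float, float, float] = (1.0, 1.0, 3.0)
    bias_amplitude: float = 0.3
    texture_params: dict[str, TextureChannelParams] = field(
        default_factory=lambda: dict(_DEFAULT_TEXTURE))
    covariate_params: dict[str, CovariateClassParams] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES))
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS))
    # lesion ellipsoid radii ranges (mm): in-plane and through-plane.
    radius_range_mm: tuple[float, float] = (3.5, 7.0)
    radius_range_z_mm: tuple[float, float] = (3.2, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cs_prevalence <= 1:
            raise ValueError("cs_prevalence must be in (0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.lesion_multiplicity is not None:
            if sum(self.lesion_multiplicity) != self.n_patients:
                raise ValueError("lesion_multiplicity counts must sum to n_patients")
        probs = np.asarray(self.lesions_per_patient_probs, dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("lesions_per_patient_probs must be a probability vector")
        for sp in (self.native_spacing_t2, self.native_spacing_adc):
            if any(s <= 0 for s in sp):
                raise ValueError("spacings must be strictly positive")
        if any(n <= 0 for n in self.volume_shape):
            raise ValueError("volume_shape must be strictly positive")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")

    def adc_shape(self) -> tuple[int, int, int]:
        """ADC native grid covering the same physical extent as the T2 grid."""
        return tuple(
            max(1, int(round(n * st / sa)))
            for n, st, sa in zip(self.volume_shape, self.native_spacing_t2,
                                 self.native_spacing_adc))

    def class_level(self, channel: str, label: str) -> float:
        """Class-conditional mean level, prevalence-weighted around the marginal."""
        p = self.texture_params[channel]
        eff = self.effect_sizes.get(f"{channel}_level", 0.0)
        prev = self.cs_prevalence
        shift = eff * p.level_sd
        return p.level + ((1 - prev) * shift if label == CS_LABEL else -prev * shift)

    def class_texture_sd(self, channel: str, label: str) -> float:
        p = self.texture_params[channel]
        eff = self.effect_sizes.get(f"{channel}_texture_sd", 0.0)
        prev = self.cs_prevalence
        factor = 1 + (1 - prev) * eff if label == CS_LABEL else 1 - prev * eff
        return max(p.texture_sd * factor, 0.0)

    def to_json(self, path: str | Path) -> None:
        blob = asdict(self)
        Path(path).write_text(json.dumps(blob, indent=2, default=str))


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class ClinicalRecord:
    patient_id: str
    age: float
    psa: float
    prostate_volume: float
    psa_density: float
    mean_adc: float

    def __post_init__(self) -> None:
        if min(self.age, self.psa, self.prostate_volume, self.mean_adc) <= 0:
            raise ValueError("clinical values must be positive")
        if abs(self.psa_density - self.psa / self.prostate_volume) > 1e-9:
            raise ValueError("psa_density must equal psa / prostate_volume")


@dataclass
class LesionSample:
    """One lesion: paired T2/ADC volumes plus masks on each native grid."""

    patient_id: str
    lesion_id: str
    zone: str               # "PZ" or "TZ"
    pirads: int             # 4 or 5
    label: str              # CS_LABEL or NONCS_LABEL
    t2: ImageVolume
    adc: ImageVolume
    t2_lesion_mask: ImageVolume
    adc_lesion_mask: ImageVolume
    t2_reference_mask: ImageVolume
    adc_reference_mask: ImageVolume

    def __post_init__(self) -> None:
        for name in ("t2", "adc"):
            les = getattr(self, f"{name}_lesion_mask").data > 0.5
            ref = getattr(self, f"{name}_reference_mask").data > 0.5
            if not les.any() or not ref.any():
                raise ValueError(f"{self.lesion_id}: empty mask on {name} grid")
            if (les & ref).any():
                raise ValueError(
                    f"{self.lesion_id}: lesion and reference masks overlap on {name}")

    @property
    def is_cs(self) -> bool:
        return self.label == CS_LABEL


class PhantomGenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# field synthesis
# ---------------------------------------------------------------------------

def _physical_coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _poly2_design(xs, ys, zs):
    """Order-2 polynomial basis over coordinates normalised to [-1, 1]."""
    def norm(c):
        span = c.max() - c.min()
        return (2 * (c - c.min()) / span - 1) if span > 0 else np.zeros_like(c)

    x, y, z = norm(xs), norm(ys), norm(zs)
    return np.stack([np.ones_like(x), x, y, z, x * y, x * z, y * z,
                     x ** 2, y ** 2, z ** 2], axis=-1)


def make_bias_field(shape, spacing, amplitude, seed) -> ImageVolume:
    """Multiplicative field exp(P(x)) for a random order-2 polynomial P.

    P is demeaned then scaled so max|P| equals ``amplitude`` (mean log-field
    is exactly zero); amplitude 0 gives the identity field.
    """
    if any(n <= 0 for n in shape) or any(s <= 0 for s in spacing):
        raise ValueError("shape and spacing must be strictly positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    coeffs = rng.standard_normal(10)
    xs, ys, zs = _physical_coords(shape, spacing)
    poly = _poly2_design(xs, ys, zs) @ coeffs
    poly -= poly.mean()
    peak = np.max(np.abs(poly))
    if amplitude == 0 or peak < 1e-12:
        poly = np.zeros(shape)
    else:
        poly *= amplitude / peak
    return ImageVolume(np.exp(poly), spacing=tuple(spacing))


def gaussian_random_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    """Stationary zero-mean unit-SD field: Gaussian-smoothed white noise."""
    sigma_vox = [corr_mm / s for s in spacing]
    noise = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = fld.std()
    if sd < 1e-12:   # pathological: smoothing wiped all variance
        return np.zeros(shape)
    return (fld - fld.mean()) / sd


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm, perturbation=None):
    xs, ys, zs = _physical_coords(shape, spacing)
    q = sum(((c - m) / r) ** 2
            for c, m, r in zip((xs, ys, zs), center_mm, radii_mm))
    if perturbation is not None:
        q = q + perturbation
    return q <= 1.0


# ---------------------------------------------------------------------------
# sample and cohort generation
# ---------------------------------------------------------------------------

def _channel_volume(cfg: PhantomConfig, channel: str, label: str,
                    shape, spacing, lesion_mask, ref_mask, lesion_level,
                    lesion_sd, bias: np.ndarray, rng) -> ImageVolume:
    p = cfg.texture_params[channel]
    background_level = 0.75 * p.level if channel == "t2" else 1.6 * p.level
    tex_bg = gaussian_random_field(shape, spacing, p.corr_mm, rng)
    tex_lesion = gaussian_random_field(shape, spacing, p.corr_mm, rng)
    tex_ref = gaussian_random_field(shape, spacing, p.corr_mm, rng)
    vol = background_level + 0.10 * background_level * tex_bg
    vol = np.where(lesion_mask, lesion_level + lesion_sd * tex_lesion, vol)
    # healthy-PZ reference tissue: homogeneous, 2% noise
    ref_level = 0.9 * p.level if channel == "t2" else 1.9 * p.level
    vol = np.where(ref_mask, ref_level * (1 + 0.02 * tex_ref), vol)
    vol = vol * bias
    return ImageVolume(np.clip(vol, 1e-3, None), spacing=tuple(spacing))


def make_lesion_sample(config: PhantomConfig, class_label: str, zone: str,
                       rng, *, patient_id="P000", lesion_id="P000_L1",
                       pirads: int = 4) -> LesionSample:
    """Generate one paired T2/ADC lesion sample on the native grids."""
    if class_label not in (CS_LABEL, NONCS_LABEL):
        raise ValueError(f"unknown class label {class_label!r}")
    shape_t2 = tuple(config.volume_shape)
    shape_adc = config.adc_shape()
    sp_t2, sp_adc = config.native_spacing_t2, config.native_spacing_adc
    extent = [n * s for n, s in zip(shape_t2, sp_t2)]

    for _attempt in range(8):
        rxy = rng.uniform(*config.radius_range_mm, size=2)
        rz = rng.uniform(*config.radius_range_z_mm)
        radii = (rxy[0], rxy[1], max(rz, 1.05 * sp_adc[2] / 2))
        center = [e / 2 + rng.uniform(-0.05, 0.05) * e for e in extent]
        masks = {}
        ok = True
        for ch, shape, sp in (("t2", shape_t2, sp_t2), ("adc", shape_adc, sp_adc)):
            pert = 0.15 * gaussian_random_field(shape, sp, 2.5, rng)
            m = _ellipsoid_mask(shape, sp, center, radii, pert)
            m = _largest_component(m)
            masks[ch] = m
            if m.sum() < 30:
                ok = False
        if ok:
            break
    else:
        raise PhantomGenerationError(
            f"{lesion_id}: could not generate a lesion mask with >= 30 voxels "
            f"(grid {shape_adc}, radii range {config.radius_range_mm})")

    # reference region: a corner slab, guaranteed disjoint from the centred lesion
    refs = {}
    for ch, shape, sp in (("t2", shape_t2, sp_t2), ("adc", shape_adc, sp_adc)):
        ref_center = [0.13 * e for e in extent]
        ref = _ellipsoid_mask(shape, sp, ref_center,
                              (0.11 * extent[0], 0.11 * extent[1], extent[2]))
        ref &= ~masks[ch]
        refs[ch] = ref

    bias_seed = int(rng.integers(0, 2 ** 31))
    bias_t2 = make_bias_field(shape_t2, sp_t2, config.bias_amplitude, bias_seed)
    bias_adc = make_bias_field(shape_adc, sp_adc, config.bias_amplitude, bias_seed)

    vols = {}
    for ch, shape, sp, bias in (("t2", shape_t2, sp_t2, bias_t2.data),
                                ("adc", shape_adc, sp_adc, bias_adc.data)):
        p = config.texture_params[ch]
        level = rng.normal(config.class_level(ch, class_label), p.level_sd)
        level = max(level, 0.15 * p.level)
        cv = p.sd_jitter_cv
        if cv > 0:  # lognormal, mean 1: lesions vary in heterogeneity
            s2 = np.log1p(cv ** 2)
            jitter = rng.lognormal(-s2 / 2, np.sqrt(s2))
        else:
            jitter = 1.0
        sd = config.class_texture_sd(ch, class_label) * jitter
        vols[ch] = _channel_volume(config, ch, class_label, shape, sp,
                                   masks[ch], refs[ch], level, sd, bias, rng)

    def mk(arr, sp):
        return ImageVolume(arr.astype(np.float64), spacing=tuple(sp))

    return LesionSample(
        patient_id=patient_id, lesion_id=lesion_id, zone=zone, pirads=pirads,
        label=class_label,
        t2=vols["t2"], adc=vols["adc"],
        t2_lesion_mask=mk(masks["t2"], sp_t2),
        adc_lesion_mask=mk(masks["adc"], sp_adc),
        t2_reference_mask=mk(refs["t2"], sp_t2),
        adc_reference_mask=mk(refs["adc"], sp_adc),
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _lognormal(rng, mean, sd):
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def make_cohort(config: PhantomConfig):
    """Generate the full synthetic cohort.

    Returns ``(samples, records, manifest)`` where ``manifest`` is a
    lesion-level DataFrame joining clinical covariates, zone/PI-RADS
    metadata and the binary outcome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    if config.lesion_multiplicity is not None:
        mult = np.repeat([1, 2, 3], config.lesion_multiplicity)
        rng.shuffle(mult)
    else:
        mult = rng.choice([1, 2, 3], size=config.n_patients,
                          p=config.lesions_per_patient_probs)

    samples: list[LesionSample] = []
    records: list[ClinicalRecord] = []
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        patient_samples = []
        for j in range(int(mult[i])):
            label = CS_LABEL if rng.random() < config.cs_prevalence else NONCS_LABEL
            pirads = 4 if rng.random() < config.pirads4_prob else 5
            zone = "PZ" if rng.random() < config.zone_probs[pirads] else "TZ"
            s = make_lesion_sample(config, label, zone, rng, patient_id=pid,
                                   lesion_id=f"{pid}_L{j + 1}", pirads=pirads)
            patient_samples.append(s)
        patient_class = (CS_LABEL if any(s.is_cs for s in patient_samples)
                         else NONCS_LABEL)
        cp = config.covariate_params[patient_class]
        age = float(np.clip(rng.normal(cp.age_mean, cp.age_sd), 40, 95))
        psa = _lognormal(rng, cp.psa_mean, cp.psa_sd)
        volume = _lognormal(rng, cp.volume_mean, cp.volume_sd)
        first = patient_samples[0]
        rec_adc = float(first.adc.data[first.adc_lesion_mask.data > 0.5].mean())
        records.append(ClinicalRecord(patient_id=pid, age=age, psa=psa,
                                      prostate_volume=volume,
                                      psa_density=psa / volume,
                                      mean_adc=rec_adc))
        for s in patient_samples:
            mean_adc = float(s.adc.data[s.adc_lesion_mask.data > 0.5].mean())
            rows.append(dict(patient_id=pid, lesion_id=s.lesion_id, zone=s.zone,
                             pirads=s.pirads, label=s.label, age=age, psa=psa,
                             prostate_volume=volume, psa_density=psa / volume,
                             mean_adc=mean_adc))
        samples.extend(patient_samples)

    manifest = pd.DataFrame(rows)
    return samples, records, manifest


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

_CHANNEL_FILES = ("t2", "adc", "t2_lesion_mask", "adc_lesion_mask",
                  "t2_reference_mask", "adc_reference_mask")


def write_cohort(outdir: str | Path, samples, manifest: pd.DataFrame,
                 config: PhantomConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        d = outdir / s.lesion_id
        d.mkdir(exist_ok=True)
        for ch in _CHANNEL_FILES:
            getattr(s, ch).to_nifti(d / f"{ch}.nii.gz")
    manifest.to_csv(outdir / "manifest.csv", index=False)
    if config is not None:
        config.to_json(outdir / "phantom_config.json")


def read_cohort(indir: str | Path):
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        d = indir / row["lesion_id"]
        vols = {ch: ImageVolume.from_nifti(d / f"{ch}.nii.gz")
                for ch in _CHANNEL_FILES}
        samples.append(LesionSample(patient_id=row["patient_id"],
                                    lesion_id=row["lesion_id"], zone=row["zone"],
                                    pirads=int(row["pirads"]), label=row["label"],
                                    **vols))
    return samples, manifest
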