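"""Synthetic DSC-PWI cohorts for pipeline development and testing.

Emulates the three ingredients the analysis assumes about real stroke
perfusion data:

* time-intensity bolus curves in which lesion tissue (LT) shows a smaller
  and later intensity dip than the mirrored contralateral normal tissue
  (NT) — a gamma-variate transit curve subtracted from a flat baseline;
* a clinical covariate table with the usual admission fields (age, NIHSS,
  focal symptoms, comorbidities, lesion volume) drawn from configurable
  marginal laws;
* a 7-level 90-day modified Rankin Scale (mRS) outcome with a plantable,
  configurable dependence on clinical and imaging covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PerfusionSeries, RoiPair, mirror_roi

__all__ = [
    "SynthConfig", "SyntheticCohort", "gamma_variate",
    "generate_perfusion_series", "generate_cti_table", "generate_outcomes",
    "generate_cohort", "CTI_COLUMNS", "MRS7_PRIORS",
]

#: Clinical-table columns (admission fields recorded for each scan).
CTI_COLUMNS = [
    "age", "sex_female", "income_nihss", "outcome_nihss",
    "right_limb_weakness", "left_limb_weakness", "lisp", "confusion",
    "hypertension", "diabetes", "atrial_fibrillation",
    "intra_arterial_thrombectomy", "lesion_volume_ml",
]

#: Default marginal parameters for the clinical table: normal (mean, sd) for
#: continuous fields, Bernoulli rate for binary fields.
CTI_DEFAULTS = {
    "age": ("normal", 71.362, 10.91),
    "sex_female": ("bernoulli", 0.2679),
    "income_nihss": ("truncnormal", 9.919, 6.747),
    "outcome_nihss": ("truncnormal", 6.275, 6.875),
    "right_limb_weakness": ("bernoulli", 0.475),
    "left_limb_weakness": ("bernoulli", 0.45),
    "lisp": ("bernoulli", 0.7375),
    "confusion": ("bernoulli", 0.125),
    "hypertension": ("bernoulli", 0.7375),
    "diabetes": ("bernoulli", 0.325),
    "atrial_fibrillation": ("bernoulli", 0.35),
    "intra_arterial_thrombectomy": ("bernoulli", 0.275),
    "lesion_volume_ml": ("truncnormal", 95.583, 72.304),
}

#: Default 7-category outcome priors (cohort marginal counts out of 80).
MRS7_PRIORS = np.array([25, 11, 9, 4, 8, 9, 14], dtype=float) / 80.0


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for one synthetic cohort."""

    n_patients: int = 80
    n_timepoints: int = 50
    volume_shape: tuple = (8, 32, 32)          # (slices, rows, cols)
    baseline_intensity: float = 300.0
    bolus_amplitude_nt: float = 150.0
    bolus_amplitude_lt: float = 60.0           # <= NT amplitude
    bolus_onset_nt: float = 12.0               # timepoint index
    bolus_delay_lt: float = 4.0                # extra delay for lesion tissue
    bolus_shape_params: tuple = (3.0, 2.5)     # gamma-variate (alpha, beta)
    noise_sd: float = 20.0
    lesion_radius: tuple | None = None         # ellipsoid semi-axes, voxels
                                               # (None: scaled to the volume)
    spacing: tuple = (6.5, 0.9, 0.9)           # mm
    effect_config: dict = field(default_factory=lambda: {
        "age": 0.6, "income_nihss": 0.8, "lesion_volume_ml": 0.5,
        "imaging_dip_depth": 0.7,
    })
    noise_scale_outcome: float = 0.5           # logistic noise on the latent
    mrs_bin_probs: tuple = tuple(MRS7_PRIORS)
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.bolus_amplitude_lt > self.bolus_amplitude_nt:
            raise ValueError("LT bolus amplitude must not exceed NT's")
        if any(d < 4 for d in self.volume_shape):
            raise ValueError("volume_shape dims must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """A complete generated dataset plus the planted ground truth."""

    series: list
    rois: list
    cti: pd.DataFrame
    mrs7: np.ndarray
    truth: dict


def gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate bolus shape normalized to a peak of 1 at ``t0 + beta``:
    ``g(t) = ((t - t0)/beta)^alpha * exp(alpha - alpha*(t - t0)/beta)``."""
    u = np.clip((np.asarray(t, dtype=float) - t0) / beta, 0.0, None)
    with np.errstate(invalid="ignore"):
        g = u ** alpha * np.exp(alpha - alpha * u)
    return np.where(u > 0, g, 0.0)


def _lesion_mask(shape: tuple, radius: tuple | None, center=None) -> np.ndarray:
    """Ellipsoidal lesion in the left hemisphere (low column indices)."""
    s, r, c = shape
    if radius is None:
        # semi-axes that always fit strictly left of the midline
        radius = (max(s / 4.0, 1.0), max(r / 5.0, 1.0), max(c / 6.0, 1.0))
    if center is None:
        center = (s / 2.0 - 0.5, r / 2.0 - 0.5, c / 4.0)
    zz, yy, xx = np.ogrid[:s, :r, :c]
    d = (((zz - center[0]) / radius[0]) ** 2
         + ((yy - center[1]) / radius[1]) ** 2
         + ((xx - center[2]) / radius[2]) ** 2)
    mask = d <= 1.0
    if mask[:, :, c // 2:].any():
        raise ValueError("lesion crosses the left-right midline; "
                         "mirroring would overlap")
    return mask.astype(np.uint8)


def generate_perfusion_series(config: SynthConfig,
                              rng: np.random.Generator | None = None
                              ) -> tuple[PerfusionSeries, RoiPair]:
    """One 4D series with an LT/NT ROI pair.

    Every voxel follows ``baseline - A * g(t - onset) + noise`` (clipped at
    zero); lesion voxels use the smaller amplitude and the extra delay, all
    other tissue the NT parameters.  The NT mask is the LT mask mirrored
    across the column midline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alpha, beta = config.bolus_shape_params
    t = np.arange(config.n_timepoints, dtype=float)
    g_nt = gamma_variate(t, config.bolus_onset_nt, alpha, beta)
    g_lt = gamma_variate(t, config.bolus_onset_nt + config.bolus_delay_lt,
                         alpha, beta)

    lt_mask = _lesion_mask(config.volume_shape, config.lesion_radius)
    nt_mask = mirror_roi(lt_mask)

    curve_bg = config.baseline_intensity - config.bolus_amplitude_nt * g_nt
    curve_lt = config.baseline_intensity - config.bolus_amplitude_lt * g_lt
    data = np.empty((config.n_timepoints,) + tuple(config.volume_shape))
    data[:] = curve_bg[:, None, None, None]
    data[:, lt_mask.astype(bool)] = curve_lt[:, None]
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)
    series = PerfusionSeries(data=data, spacing=tuple(config.spacing))
    return series, RoiPair(lt_mask=lt_mask, nt_mask=nt_mask)


def generate_cti_table(n: int, seed: int | np.random.Generator = 0,
                       overrides: dict | None = None) -> pd.DataFrame:
    """Clinical table with one row per scan.

    ``overrides`` replaces entries of the default marginal map, e.g.
    ``{"hypertension": ("bernoulli", 1.0)}``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = dict(CTI_DEFAULTS)
    if overrides:
        params.update(overrides)
    cols = {}
    for name in CTI_COLUMNS:
        law = params[name]
        if law[0] == "normal":
            cols[name] = rng.normal(law[1], law[2], size=n)
        elif law[0] == "truncnormal":
            cols[name] = np.clip(rng.normal(law[1], law[2], size=n), 0.0, None)
        elif law[0] == "bernoulli":
            cols[name] = (rng.random(n) < law[1]).astype(int)
        else:                                            # pragma: no cover
            raise ValueError(f"unknown law {law[0]!r} for {name}")
    return pd.DataFrame(cols, columns=CTI_COLUMNS)


def generate_outcomes(cti: pd.DataFrame,
                      features: pd.DataFrame | None,
                      config: SynthConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """7-level mRS labels from a latent cumulative-logit score.

    latent = sum over effect_config of coef * standardized covariate
    + logistic noise; labels are the ordinal buckets whose marginal
    probabilities are ``config.mrs_bin_probs`` (sample-quantile bin edges,
    so the marginal counts imitate the configured priors while monotone
    dependence on the covariates is preserved).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(cti)
    if features is not None and len(features) != n:
        raise ValueError("cti and features row counts disagree")
    latent = np.zeros(n)
    for name, coef in config.effect_config.items():
        if name in cti.columns:
            col = cti[name].to_numpy(dtype=float)
        elif features is not None and name in features.columns:
            col = features[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"effect_config names unknown column {name!r}")
        sd = col.std()
        latent += coef * (col - col.mean()) / (sd if sd > 0 else 1.0)
    latent += config.noise_scale_outcome * rng.logistic(size=n)

    probs = np.asarray(config.mrs_bin_probs, dtype=float)
    probs = probs / probs.sum()
    cum = np.cumsum(probs)[:-1]
    edges = np.quantile(latent, cum)
    return np.searchsorted(edges, latent, side="right").astype(int)


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate the full cohort: series, ROI pairs, clinical table, labels
    and the planted truth (coefficients + truly discriminative timepoints)."""
    rng = np.random.default_rng(config.seed)
    series, rois = [], []
    dip_depth = np.empty(config.n_patients)
    for i in range(config.n_patients):
        s, r = generate_perfusion_series(config, rng=rng)
        series.append(s)
        rois.append(r)
        lt = s.data[:, r.lt_mask.astype(bool)].mean(axis=1)
        dip_depth[i] = lt.max() - lt.min()
    cti = generate_cti_table(config.n_patients, seed=rng)
    imaging = pd.DataFrame({"imaging_dip_depth": dip_depth})
    mrs7 = generate_outcomes(cti, imaging, config, rng=rng)

    alpha, beta = config.bolus_shape_params
    t = np.arange(config.n_timepoints, dtype=float)
    g = gamma_variate(t, config.bolus_onset_nt, alpha, beta)
    truth = {
        "effect_config": dict(config.effect_config),
        "discriminative_timepoints": np.flatnonzero(g > 0.5 * g.max()),
        "imaging_dip_depth": dip_depth,
    }
    return SyntheticCohort(series=series, rois=rois, cti=cti, mrs7=mrs7,
                           truth=truth)
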