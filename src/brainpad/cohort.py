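"""Synthetic cohort generation.

Produces seeded training samples and test cohorts that carry the statistical
structure assumed by the downstream analyses: a latent per-subject brain-age
offset ("true" brain-PAD, delta), voxelwise grey/white-matter phantom maps
linearly encoding brain age, fitness outcomes with configurable standardized
effects of delta, an exponential proportional-hazards survival process
calibrated to an expected death count under uniform administrative censoring,
and molecular ageing biomarkers (epigenetic-clock age, telomere length)
generated independently of delta.

Every draw derives from ``numpy.random.SeedSequence`` children of the config
seed, so identical configurations yield identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .config import (
    ALLOSTATIC_COMPONENTS,
    FITNESS_OUTCOMES,
    ConfigurationError,
    GeneratorConfig,
)

__all__ = [
    "CohortTable",
    "CohortGenerator",
    "TissuePhantom",
    "generate_training_sample",
    "generate_test_cohort",
    "generate_tissue_maps",
    "generate_fitness",
    "generate_survival",
    "expected_deaths",
    "calibrate_baseline_hazard",
]

# stream indices under the config seed
_STREAM_PHANTOM = 0
_STREAM_TRAIN = 1
_STREAM_TEST = 2


@lru_cache(maxsize=64)
def _beta_shape(mean: float, sd: float, lo: float, hi: float):
    """Beta shape parameters matching the *observed* moments on [lo, hi].

    The reported mean/sd of the bounded training-age sample are its realized
    moments, and no truncated normal on [18, 90] can attain that spread at
    that mean; a moment-matched Beta on the range can, and gives the
    young-adult-heavy shape typical of pooled healthy MRI repositories.
    """
    width = hi - lo
    m = (mean - lo) / width
    v = (sd / width) ** 2
    if not 0 < m < 1 or v >= m * (1 - m):
        raise ConfigurationError(
            f"age moments mean={mean}, sd={sd} infeasible on [{lo}, {hi}]"
        )
    s = m * (1 - m) / v - 1.0
    return m * s, (1.0 - m) * s


def _sample_ages(n, mean, sd, lo, hi, rng):
    """Sample bounded ages whose mean/sd match the configured values."""
    if sd == 0:
        return np.full(n, float(mean))
    alpha, beta = _beta_shape(float(mean), float(sd), float(lo), float(hi))
    return lo + (hi - lo) * rng.beta(alpha, beta, size=n)


# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------

class TissuePhantom:
    """Linear voxel phantom shared by the training and test cohorts.

    Each subject's grey- and white-matter maps are
    ``template + brain_age * loading + noise`` clipped at zero, with a fixed
    per-seed template and signed loading pattern (rescaled to exactly
    ``config.loading_norm``), so ordinary least squares of brain age on the
    noiseless maps is identifiable.
    """

    def __init__(self, config: GeneratorConfig):
        config.validate()
        if config.n_voxels == 0:  # pragma: no cover - blocked by validate
            raise ConfigurationError("zero voxels configured")
        self.config = config
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAM_PHANTOM,))
        )
        p = config.n_voxels
        lo, hi = config.template_range
        self.template = rng.uniform(lo, hi, size=p)
        loading = rng.standard_normal(p)
        norm = np.linalg.norm(loading)
        if norm > 0 and config.loading_norm > 0:
            loading *= config.loading_norm / norm
        elif config.loading_norm == 0:
            loading[:] = 0.0
        self.loading = loading
        self.noise_sd = config.resolved_voxel_noise_sd()

    def maps(self, brain_age, rng):
        """Return ``(gm, wm)`` maps for a vector of brain ages."""
        brain_age = np.atleast_1d(np.asarray(brain_age, dtype=float))
        if not np.all(np.isfinite(brain_age)):
            raise ValueError("brain_age must be finite")
        n, p = brain_age.shape[0], self.config.n_voxels
        values = self.template + brain_age[:, None] * self.loading
        if self.noise_sd > 0:
            values = values + rng.normal(0.0, self.noise_sd, size=(n, p))
        np.clip(values, 0.0, None, out=values)
        g = self.config.n_voxels_gm
        return values[:, :g], values[:, g:]


def generate_tissue_maps(brain_age, config: GeneratorConfig, rng=None):
    """Phantom grey/white-matter maps for one or more brain ages."""
    rng = np.random.default_rng(rng)
    return TissuePhantom(config).maps(brain_age, rng)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def expected_deaths(lambda0, eta, lo, hi):
    """Expected number of events before uniform-(lo, hi) censoring.

    Event times are exponential with rate ``lambda0 * exp(eta)``; for a
    censoring time C ~ U(lo, hi),
    ``P(death) = 1 - E[exp(-rate * C)] = 1 - (exp(-rate*lo) - exp(-rate*hi)) /
    (rate * (hi - lo))``.
    """
    rate = lambda0 * np.exp(eta)
    with np.errstate(over="ignore", invalid="ignore"):
        if hi > lo:
            surv = (np.exp(-rate * lo) - np.exp(-rate * hi)) / (rate * (hi - lo))
            surv = np.where(rate < 1e-12, np.exp(-rate * 0.5 * (lo + hi)), surv)
        else:
            surv = np.exp(-rate * lo)
    return float(np.sum(1.0 - surv))


def calibrate_baseline_hazard(eta, target_deaths, followup_range):
    """Closed-form root-find of the baseline rate hitting the expected deaths."""
    n = len(eta)
    if target_deaths >= n:
        raise ConfigurationError("target_deaths must be below the cohort size")
    lo, hi = followup_range

    def f(log_l0):
        return expected_deaths(math.exp(log_l0), eta, lo, hi) - target_deaths

    return math.exp(optimize.brentq(f, -25.0, 10.0, xtol=1e-12))


def generate_survival(delta, age, male, config: GeneratorConfig, rng=None,
                      extra_covariates: dict | None = None):
    """Draw (survival_time, event) from the calibrated exponential PH model.

    The linear predictor is built from mean-centred covariates; by default
    ``log_hr_per_pad_year * delta + log_hr_per_year_age * age + log_hr_male *
    male``. ``config.hazard_terms`` can redirect the hazard onto any columns
    supplied via ``extra_covariates`` (e.g. tissue volumes).
    """
    rng = np.random.default_rng(rng)
    delta = np.asarray(delta, float)
    age = np.asarray(age, float)
    male = np.asarray(male, float)
    columns = {"brain_pad": delta, "age": age, "male": male}
    if extra_covariates:
        columns.update({k: np.asarray(v, float) for k, v in extra_covariates.items()})
    if config.hazard_terms is None:
        terms = {
            "brain_pad": config.log_hr_per_pad_year,
            "age": config.log_hr_per_year_age,
            "male": config.log_hr_male,
        }
    else:
        terms = dict(config.hazard_terms)
    eta = np.zeros_like(delta)
    for name, coef in terms.items():
        if name not in columns:
            raise ConfigurationError(f"hazard term {name!r} has no generated column")
        x = columns[name]
        eta = eta + coef * (x - x.mean())
    lam0 = calibrate_baseline_hazard(eta, config.target_deaths, config.followup_range)
    rate = lam0 * np.exp(eta)
    event_time = rng.exponential(1.0, size=len(eta)) / rate
    lo, hi = config.followup_range
    censor_time = rng.uniform(lo, hi, size=len(eta))
    event = (event_time <= censor_time).astype(int)
    time = np.minimum(event_time, censor_time)
    return time, event


# ---------------------------------------------------------------------------
# fitness and allostatic components
# ---------------------------------------------------------------------------

def generate_fitness(delta, male, config: GeneratorConfig, rng=None):
    """Standardized fitness outcomes plus raw allostatic components.

    Each outcome is ``beta * z(delta) + gamma * male + residual`` with the
    residual variance chosen so the realized outcome has unit variance; the
    sex-adjusted standardized regression on brain-PAD then recovers ``beta``
    in expectation. Allostatic components are drawn around the latent
    allostatic outcome so the recomputed composite tracks it closely.
    """
    rng = np.random.default_rng(rng)
    delta = np.asarray(delta, float)
    male = np.asarray(male, float)
    n = len(delta)
    sd = delta.std()
    z_delta = (delta - delta.mean()) / sd if sd > 0 else np.zeros(n)
    p = male.mean()
    pq = p * (1 - p)
    # standardized male-female gap in z(delta) (sex means of brain-PAD differ)
    gap = (z_delta[male == 1].mean() - z_delta[male == 0].mean()) if 0 < p < 1 else 0.0

    out = {}
    for name in FITNESS_OUTCOMES:
        beta = float(config.fitness_betas[name])
        if not abs(beta) < 1:
            raise ConfigurationError(f"|beta| must be < 1 for {name!r}")
        gamma = float(config.fitness_sex_effects.get(name, 0.0))
        resid_var = 1.0 - beta**2 - gamma**2 * pq - 2.0 * beta * gamma * pq * gap
        if resid_var <= 0:
            raise ConfigurationError(
                f"residual variance non-positive for {name!r}; reduce effects"
            )
        out[name] = (
            beta * z_delta
            + gamma * (male - p)
            + rng.normal(0.0, math.sqrt(resid_var), size=n)
        )

    rho = config.allostatic_component_rho
    latent = out["allostatic"]
    components = {}
    for comp, (mean, sd_c, direction) in ALLOSTATIC_COMPONENTS.items():
        z_signed = rho * latent + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        components[comp] = mean + sd_c * direction * z_signed
    return out, components


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """A generated cohort: phenotype table plus optional voxel maps."""

    phenotypes: pd.DataFrame
    role: str  # "train" or "test"
    config: GeneratorConfig
    gm: np.ndarray | None = None
    wm: np.ndarray | None = None

    def __post_init__(self):
        if self.phenotypes["id"].duplicated().any():
            raise ValueError("subject ids must be unique")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def features(self) -> np.ndarray:
        """Concatenated (GM first, then WM) voxel feature matrix."""
        if self.gm is None or self.wm is None:
            raise ValueError("cohort was generated without images")
        return np.hstack([self.gm, self.wm])

    def to_csv(self, path) -> None:
        self.phenotypes.to_csv(path, index=False, float_format="%.10g")

    def write(self, outdir, images: bool = False) -> dict:
        """Write phenotypes CSV + config sidecar (+ per-subject NIfTI maps)."""
        from . import nifti_io  # local import: nibabel only needed here

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / f"{self.role}_phenotypes.csv"
        self.to_csv(csv_path)
        cfg_path = outdir / f"{self.role}_config.json"
        self.config.to_json(cfg_path)
        written = {"phenotypes": csv_path, "config": cfg_path}
        if images:
            img_dir = outdir / f"{self.role}_images"
            nifti_io.write_cohort_maps(self, img_dir)
            written["images"] = img_dir
        return written


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class CohortGenerator:
    """Seeded generator for training samples and test cohorts."""

    def __init__(self, config: GeneratorConfig | None = None, **overrides):
        if config is None:
            config = GeneratorConfig(**overrides)
        elif overrides:
            config = config.replace(**overrides)
        self.config = config.validate()
        self.phantom = TissuePhantom(self.config)

    def _rng(self, stream: int, replicate: int = 0):
        key = (stream,) if replicate == 0 else (stream, replicate)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.config.seed, spawn_key=key)
        )

    # -- training ----------------------------------------------------------
    def training_sample(self, images: bool = True, replicate: int = 0) -> CohortTable:
        """Healthy reference sample: age, sex and phantom maps only."""
        cfg = self.config
        rng = self._rng(_STREAM_TRAIN, replicate)
        lo, hi = cfg.train_age_range
        age = _sample_ages(cfg.n_train, cfg.train_age_mean, cfg.train_age_sd,
                           lo, hi, rng)
        male = (rng.random(cfg.n_train) < 0.5).astype(int)
        delta = rng.normal(0.0, cfg.train_pad_sd, size=cfg.n_train)
        brain_age = age + delta
        frame = pd.DataFrame({
            "id": [f"train{i:05d}" for i in range(cfg.n_train)],
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "male": male,
            "true_pad": delta,
        })
        gm = wm = None
        if images:
            gm, wm = self.phantom.maps(brain_age, rng)
        return CohortTable(frame, "train", cfg, gm, wm)

    # -- test ----------------------------------------------------------------
    def test_cohort(self, images: bool = False, replicate: int = 0) -> CohortTable:
        """Older narrow-age cohort with outcomes, survival and biomarkers."""
        cfg = self.config
        rng = self._rng(_STREAM_TEST, replicate)
        n = cfg.n_test
        male = np.concatenate([np.ones(cfg.n_male, int), np.zeros(cfg.n_female, int)])
        age = rng.normal(cfg.test_age_mean, cfg.test_age_sd, size=n)
        delta = np.where(
            male == 1,
            rng.normal(cfg.pad_mean_male, cfg.pad_sd_male, size=n),
            rng.normal(cfg.pad_mean_female, cfg.pad_sd_female, size=n),
        )

        gm_vol = (cfg.gm_vol_mean + cfg.gm_vol_per_pad * delta
                  + rng.normal(0, cfg.gm_vol_noise_sd, n))
        csf_vol = (cfg.csf_vol_mean + cfg.csf_vol_per_pad * delta
                   + rng.normal(0, cfg.csf_vol_noise_sd, n))
        wm_vol = cfg.wm_vol_mean + rng.normal(0, cfg.wm_vol_noise_sd, n)

        fitness, components = generate_fitness(delta, male, cfg, rng)

        dnam_age = age + rng.normal(cfg.dnam_pad_mean, cfg.dnam_pad_sd, n)
        telomere = np.where(
            male == 1,
            rng.normal(cfg.telomere_mean_male, cfg.telomere_sd, n),
            rng.normal(cfg.telomere_mean_female, cfg.telomere_sd, n),
        )
        telomere = np.clip(telomere, 1.0, None)

        time, event = generate_survival(
            delta, age, male, cfg, rng,
            extra_covariates={"gm_vol": gm_vol, "csf_vol": csf_vol,
                              "wm_vol": wm_vol, "dnam_pad": dnam_age - age,
                              "telomere_bp": telomere},
        )

        frame = pd.DataFrame({
            "id": [f"test{i:04d}" for i in range(n)],
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "male": male,
            "true_pad": delta,
            # measured brain-PAD; equals the latent value until an imaging
            # pipeline overwrites it with model predictions
            "brain_pad": delta,
            "gm_vol": gm_vol,
            "wm_vol": wm_vol,
            "csf_vol": csf_vol,
            **{name: fitness[name] for name in FITNESS_OUTCOMES},
            **components,
            "survival_time": time,
            "event": event,
            "dnam_age": dnam_age,
            "dnam_pad": dnam_age - age,
            "telomere_bp": telomere,
            "iq11": rng.normal(100, 15, n),
            "social_class": rng.integers(1, 6, n),
            "education_years": np.clip(rng.normal(10.7, 1.1, n), 9, 18),
            "apoe_e4": (rng.random(n) < cfg.prevalence_apoe_e4).astype(int),
            "smoking": rng.choice(["never", "ex", "current"], size=n,
                                  p=cfg.smoking_probs),
            "hypertension": (rng.random(n) < cfg.prevalence_hypertension).astype(int),
            "diabetes": (rng.random(n) < cfg.prevalence_diabetes).astype(int),
            "cvd": (rng.random(n) < cfg.prevalence_cvd).astype(int),
            "stroke": (rng.random(n) < cfg.prevalence_stroke).astype(int),
        })
        gm = wm = None
        if images:
            gm, wm = self.phantom.maps(age + delta, rng)
        return CohortTable(frame, "test", cfg, gm, wm)


# -- thin functional wrappers -------------------------------------------------

def generate_training_sample(config: GeneratorConfig, images: bool = True) -> CohortTable:
    return CohortGenerator(config).training_sample(images=images)


def generate_test_cohort(config: GeneratorConfig, images: bool = False) -> CohortTable:
    return CohortGenerator(config).test_cohort(images=images)
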