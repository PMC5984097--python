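"""Configuration for the synthetic-cohort generator.

The defaults encode the statistical structure of the study the package
emulates: a large healthy adult training sample (n=2001, observed age mean
36.95 y, sd 18.12 y, range 18-90 y) and a narrow-age older test cohort
(n=669, mean age 72.67 y, sd 0.73 y; 352 male, 317 female) with sex-specific
brain-PAD distributions, five fitness outcomes with known standardized
effects, right-censored all-cause mortality over 5.4-7.9 years of follow-up
with ~73 expected deaths, an epigenetic-clock age prediction uncorrelated
with brain-PAD, and leukocyte telomere length with a sex difference.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


#: The five ageing-fitness outcomes, in canonical order.
FITNESS_OUTCOMES = ("fluid_g", "grip", "fev1", "walk_time", "allostatic")

#: Standardized brain-PAD effects on each fitness outcome (sex-adjusted).
DEFAULT_FITNESS_BETAS = {
    "fluid_g": -0.121,
    "grip": -0.060,
    "fev1": -0.072,
    "walk_time": 0.133,
    "allostatic": 0.097,
}

#: Raw male-minus-female shifts on the standardized outcome scale, taken from
#: the cohort descriptives (grip and lung function strongly higher in males,
#: walk time lower, fluid intelligence near-equal, allostatic load higher).
DEFAULT_FITNESS_SEX_EFFECTS = {
    "fluid_g": -0.05,
    "grip": 1.49,
    "fev1": 1.18,
    "walk_time": -0.35,
    "allostatic": 0.24,
}

#: The 11 allostatic-load components with plausible raw-unit means/sds and the
#: direction in which each contributes to physiological burden (HDL is
#: protective, hence -1).
ALLOSTATIC_COMPONENTS = {
    # name: (mean, sd, direction)
    "fibrinogen": (3.3, 0.6, +1),
    "triglyceride": (1.6, 0.8, +1),
    "hdl": (1.5, 0.4, -1),
    "ldl": (3.2, 0.9, +1),
    "total_cholesterol": (5.4, 1.1, +1),
    "cholesterol_hdl_ratio": (3.9, 1.1, +1),
    "hba1c": (5.8, 0.7, +1),
    "crp": (3.0, 4.0, +1),
    "il6": (2.2, 1.8, +1),
    "bmi": (27.8, 4.4, +1),
    "systolic_bp": (146.0, 18.0, +1),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable parameters of the synthetic cohorts.

    Ages are in years, tissue volumes in ml, telomere length in base pairs.
    ``train_age_mean``/``train_age_sd`` are the *observed* moments of the
    bounded training-age distribution: the sampler draws from a
    moment-matched Beta on ``train_age_range``, so the generated sample
    reproduces the printed descriptives.
    """

    seed: int = 0

    # -- training sample -------------------------------------------------
    n_train: int = 2001
    train_age_mean: float = 36.95
    train_age_sd: float = 18.12
    train_age_range: tuple[float, float] = (18.0, 90.0)
    #: sd of the latent brain-PAD in the healthy training sample (not a
    #: reported quantity; chosen jointly with ``prediction_noise_sd`` so the
    #: cross-validated error of the age model matches the reported triplet).
    train_pad_sd: float = 5.0

    # -- test cohort ------------------------------------------------------
    n_male: int = 352
    n_female: int = 317
    test_age_mean: float = 72.67
    test_age_sd: float = 0.73
    pad_mean_male: float = 4.29
    pad_sd_male: float = 8.58
    pad_mean_female: float = -1.29
    pad_sd_female: float = 7.87

    # -- imaging phantom ---------------------------------------------------
    n_voxels_gm: int = 500
    n_voxels_wm: int = 500
    #: Euclidean norm of the voxel loading pattern (map units per year of
    #: brain age). Per-voxel loadings are scaled to this exact norm.
    loading_norm: float = 1.0
    #: Target total sd (years) of model prediction errors on held-out
    #: training subjects; drives the default voxel-noise calibration.
    prediction_noise_sd: float = 6.31
    #: Per-voxel i.i.d. noise sd; ``None`` means calibrate from
    #: ``prediction_noise_sd`` (see :meth:`resolved_voxel_noise_sd`).
    voxel_noise_sd: float | None = None
    template_range: tuple[float, float] = (15.0, 25.0)

    # -- fitness outcomes --------------------------------------------------
    fitness_betas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FITNESS_BETAS)
    )
    fitness_sex_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FITNESS_SEX_EFFECTS)
    )
    #: correlation between each allostatic component and the latent
    #: allostatic outcome; controls how tightly the recomputed composite
    #: tracks the generated outcome.
    allostatic_component_rho: float = 0.85

    # -- survival ----------------------------------------------------------
    log_hr_per_pad_year: float = math.log(1.061)
    log_hr_per_year_age: float = math.log(1.02)
    log_hr_male: float = math.log(1.8)
    #: Optional override of the full linear predictor: maps phenotype column
    #: names to per-unit log hazard ratios (columns are mean-centred before
    #: entering the hazard). ``None`` uses brain_pad/age/male defaults above.
    hazard_terms: Mapping[str, float] | None = None
    followup_range: tuple[float, float] = (5.4, 7.9)
    target_deaths: int = 73

    # -- tissue volumes (ml) ----------------------------------------------
    gm_vol_mean: float = 580.0
    gm_vol_per_pad: float = -2.0
    gm_vol_noise_sd: float = 30.0
    wm_vol_mean: float = 470.0
    wm_vol_noise_sd: float = 40.0
    csf_vol_mean: float = 330.0
    csf_vol_per_pad: float = 2.5
    csf_vol_noise_sd: float = 40.0

    # -- molecular biomarkers ----------------------------------------------
    dnam_pad_mean: float = -3.4
    dnam_pad_sd: float = 6.1
    telomere_mean_female: float = 4045.5
    telomere_mean_male: float = 3912.3
    telomere_sd: float = 711.7

    # -- life-course covariates (all independent of brain-PAD) -------------
    prevalence_cvd: float = 0.269
    prevalence_diabetes: float = 0.102
    prevalence_stroke: float = 0.069
    prevalence_hypertension: float = 0.49
    prevalence_apoe_e4: float = 0.28
    smoking_probs: tuple[float, float, float] = (0.51, 0.40, 0.09)

    # ------------------------------------------------------------------
    @property
    def n_test(self) -> int:
        return self.n_male + self.n_female

    @property
    def n_voxels(self) -> int:
        return self.n_voxels_gm + self.n_voxels_wm

    def resolved_voxel_noise_sd(self) -> float:
        """Voxel noise calibrated so held-out prediction error ~= target.

        The ideal map decoder has per-subject error sd
        ``sigma_v / loading_norm``; learning the decoding direction from a
        finite training sample inflates this by roughly ``sqrt(1 + p/n)``.
        Solving ``train_pad_sd**2 + m**2 * (1 + p/n) = prediction_noise_sd**2``
        for the oracle error ``m`` gives the default voxel noise.
        """
        if self.voxel_noise_sd is not None:
            return float(self.voxel_noise_sd)
        excess = self.prediction_noise_sd**2 - self.train_pad_sd**2
        if excess <= 0:
            return 0.0
        inflation = 1.0 + self.n_voxels / max(self.n_train, 1)
        return float(self.loading_norm * math.sqrt(excess / inflation))

    def validate(self) -> "GeneratorConfig":
        """Raise :class:`ConfigurationError` on inconsistent settings."""
        if self.n_train <= 0:
            raise ConfigurationError("n_train must be positive")
        if self.n_male < 0 or self.n_female < 0 or self.n_test <= 0:
            raise ConfigurationError("test cohort sizes must be non-negative and sum > 0")
        lo, hi = self.train_age_range
        if not lo < hi:
            raise ConfigurationError("train_age_range must be ordered (lo < hi)")
        lo, hi = self.followup_range
        if not 0 < lo <= hi:
            raise ConfigurationError("followup_range must be ordered and positive")
        for name in (
            "train_age_sd", "test_age_sd", "train_pad_sd", "pad_sd_male",
            "pad_sd_female", "prediction_noise_sd", "dnam_pad_sd",
            "telomere_sd", "gm_vol_noise_sd", "wm_vol_noise_sd",
            "csf_vol_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_voxels_gm <= 0 or self.n_voxels_wm <= 0:
            raise ConfigurationError("voxel counts must be positive")
        if set(self.fitness_betas) != set(FITNESS_OUTCOMES):
            raise ConfigurationError(
                f"fitness_betas keys must be exactly {FITNESS_OUTCOMES}"
            )
        for name, beta in self.fitness_betas.items():
            if not abs(beta) < 1:
                raise ConfigurationError(
                    f"fitness beta for {name!r} must satisfy |beta| < 1, got {beta}"
                )
        if self.target_deaths >= self.n_test:
            raise ConfigurationError("target_deaths must be smaller than the cohort")
        if self.target_deaths <= 0:
            raise ConfigurationError("target_deaths must be positive")
        if not 0 <= self.allostatic_component_rho < 1:
            raise ConfigurationError("allostatic_component_rho must be in [0, 1)")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9:
            raise ConfigurationError("smoking_probs must sum to 1")
        return self

    # -- (de)serialization -------------------------------------------------
    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["fitness_betas"] = dict(self.fitness_betas)
        out["fitness_sex_effects"] = dict(self.fitness_sex_effects)
        if self.hazard_terms is not None:
            out["hazard_terms"] = dict(self.hazard_terms)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        kwargs = dict(data)
        for key in ("train_age_range", "followup_range", "template_range", "smoking_probs"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
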