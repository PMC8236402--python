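"""Simulation configuration: the generative model behind the synthetic cohorts.

A :class:`SimulationConfig` fully determines a synthetic cohort.  Two designs
are supported:

``two_wave``
    Per-subject paired baseline/follow-up measurements of BMI and serum uric
    acid (UA), generated from a standardized bivariate autoregressive process
    with cross-lagged effects — the generative twin of a two-wave cross-lagged
    panel model.

``cross_sectional``
    One visit per subject with a BMI -> UA -> SBP mediation structure
    (standardized paths ``beta1`` for BMI->UA, ``beta2`` for UA->SBP given BMI,
    ``cprime`` for the direct BMI->SBP effect).

Raw scales are stratum-specific (race x sex): value = stratum mean +
linear covariate effects + stratum SD x latent z-score.  Default stratum
means/SDs mirror the published descriptive tables of the Bogalusa Heart Study
cohorts this package models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import yaml

from .errors import ConfigurationError

RACES = ("White", "Black")
SEXES = ("M", "F")

Design = Literal["two_wave", "cross_sectional"]


@dataclass
class StratumParams:
    """Raw-scale moments and behaviour prevalences for one race x sex stratum.

    Units: age in years, BMI in kg/m^2, uric acid in mg/dL, SBP/DBP in mmHg.
    """

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    ua_mean: float
    ua_sd: float
    sbp_mean: float
    sbp_sd: float
    dbp_mean: float
    dbp_sd: float
    smoking_prob: float = 0.0
    drinking_prob: float = 0.0

    def validate(self, label: str) -> list[str]:
        problems = []
        for name in ("age_sd", "bmi_sd", "ua_sd", "sbp_sd", "dbp_sd"):
            if getattr(self, name) <= 0:
                problems.append(f"{label}.{name} must be > 0")
        for name in ("smoking_prob", "drinking_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                problems.append(f"{label}.{name} must be in [0, 1]")
        return problems


@dataclass
class CovariateEffects:
    """Linear effects of covariates on raw BMI and UA.

    ``age_*`` are per year of age (centred at the stratum mean age);
    ``smoking_*``/``drinking_*`` are additive shifts for smokers/drinkers.
    Defaults are zero so stratum moments match their targets exactly; set
    nonzero values to exercise covariate residualization downstream.
    """

    age_bmi: float = 0.0
    age_ua: float = 0.0
    smoking_bmi: float = 0.0
    smoking_ua: float = 0.0
    drinking_bmi: float = 0.0
    drinking_ua: float = 0.0


@dataclass
class MedicationModel:
    """Antihypertensive-treatment assignment.

    A subject whose *true* SBP/DBP reaches ``sbp_threshold``/``dbp_threshold``
    is treated with probability ``treat_prob``.  Recorded pressures of treated
    subjects are the true values minus (``sbp_effect``, ``dbp_effect``) mmHg,
    so the standard continuous-BP medication adjustment (+10/+5) exactly
    inverts the masking.
    """

    treat_prob: float = 0.5
    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    sbp_effect: float = 10.0
    dbp_effect: float = 5.0


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic cohort.

    Path coefficients are on the standardized (z-score) scale and must lie
    strictly inside (-1, 1).  ``validate`` checks, in addition, that the
    implied latent covariance structure is positive definite: each follow-up
    error variance and the SBP/DBP noise variances must be strictly positive.
    """

    n_subjects: int
    design: Design = "two_wave"
    seed: int = 0
    # cross-lagged latent structure (two_wave)
    rho1_gen: float = 0.0          # baseline UA -> follow-up BMI
    rho2_gen: float = 0.145        # baseline BMI -> follow-up UA
    track_bmi: float = 0.7         # BMI autoregression
    track_ua: float = 0.5          # UA autoregression
    r1_gen: float = 0.25           # baseline BMI-UA correlation (= beta1 when cross_sectional)
    followup_effect_bmi: float = 0.0   # linear effect of standardized follow-up years
    followup_effect_ua: float = 0.0
    # mediation structure (SBP equation; both designs)
    cprime_gen: float = 0.289      # direct standardized BMI -> SBP effect
    beta2_gen: float = 0.076       # standardized UA -> SBP effect given BMI
    dbp_attenuation: float = 0.6   # DBP path coefficients = attenuation x SBP ones
    # composition and raw scales
    prop_white: float = 0.65
    prop_female: float = 0.50
    stratum_params: dict[tuple[str, str], StratumParams] = field(default_factory=dict)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    med_model: MedicationModel = field(default_factory=MedicationModel)
    followup_range: tuple[float, float] = (5.0, 14.0)

    # ------------------------------------------------------------------
    def latent_error_variances(self) -> tuple[float, float]:
        """Error variances keeping the follow-up latents at unit variance.

        For ``zx2 = a*zx1 + b*zu1 + g*f + e`` with Var(zx1)=Var(zu1)=1,
        corr(zx1, zu1)=r1 and f an independent standardized covariate,
        Var(e) = 1 - a^2 - b^2 - 2*a*b*r1 - g^2.
        """
        r = self.r1_gen
        vx = (1.0 - self.track_bmi**2 - self.rho1_gen**2
              - 2.0 * self.track_bmi * self.rho1_gen * r - self.followup_effect_bmi**2)
        vu = (1.0 - self.rho2_gen**2 - self.track_ua**2
              - 2.0 * self.rho2_gen * self.track_ua * r - self.followup_effect_ua**2)
        return vx, vu

    def bp_noise_variance(self) -> float:
        """Noise variance keeping standardized true SBP at unit variance."""
        c, b2, r = self.cprime_gen, self.beta2_gen, self.r1_gen
        return 1.0 - c**2 - b2**2 - 2.0 * c * b2 * r

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming every invalid parameter."""
        problems: list[str] = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if self.design not in ("two_wave", "cross_sectional"):
            problems.append(f"design must be two_wave or cross_sectional, got {self.design!r}")
        for name in ("rho1_gen", "rho2_gen", "track_bmi", "track_ua", "r1_gen"):
            if not -1.0 < getattr(self, name) < 1.0:
                problems.append(f"{name} must lie strictly inside (-1, 1)")
        for name in ("prop_white", "prop_female"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must be in [0, 1]")
        if not 0.0 <= self.med_model.treat_prob <= 1.0:
            problems.append("med_model.treat_prob must be in [0, 1]")
        if not self.followup_range[0] <= self.followup_range[1]:
            problems.append("followup_range must be (min, max) with min <= max")
        if not problems:  # structure checks only meaningful on an in-range config
            vx, vu = self.latent_error_variances()
            if vx <= 0:
                problems.append(
                    "implied follow-up BMI error variance is non-positive "
                    f"(track_bmi={self.track_bmi}, rho1_gen={self.rho1_gen}, "
                    f"r1_gen={self.r1_gen}, followup_effect_bmi={self.followup_effect_bmi})")
            if vu <= 0:
                problems.append(
                    "implied follow-up UA error variance is non-positive "
                    f"(rho2_gen={self.rho2_gen}, track_ua={self.track_ua}, "
                    f"r1_gen={self.r1_gen}, followup_effect_ua={self.followup_effect_ua})")
            if self.bp_noise_variance() <= 0:
                problems.append(
                    "implied SBP noise variance is non-positive "
                    f"(cprime_gen={self.cprime_gen}, beta2_gen={self.beta2_gen}, "
                    f"r1_gen={self.r1_gen})")
        strata = self.stratum_params or default_strata("child_longitudinal")
        for key, sp in strata.items():
            problems.extend(sp.validate(f"stratum_params[{key}]"))
        if problems:
            raise ConfigurationError("; ".join(problems))

    def resolved_strata(self) -> dict[tuple[str, str], StratumParams]:
        return self.stratum_params or default_strata("child_longitudinal")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stratum_params"] = {f"{r}/{s}": v for (r, s), v in d["stratum_params"].items()}
        d["followup_range"] = list(self.followup_range)
        return d


# ----------------------------------------------------------------------
# Default stratum moments, mirroring the published cohort descriptive tables.

_CHILD_LONGITUDINAL = {
    # (race, sex): age, bmi, ua, sbp, dbp means (SDs); children do not smoke/drink
    ("White", "M"): StratumParams(13.6, 3.3, 21.3, 4.6, 5.1, 1.4, 105, 11, 62, 9),
    ("White", "F"): StratumParams(13.4, 3.1, 21.4, 5.4, 4.1, 1.1, 104, 10, 65, 8),
    ("Black", "M"): StratumParams(12.7, 3.8, 20.6, 5.7, 4.4, 1.5, 104, 14, 62, 10),
    ("Black", "F"): StratumParams(13.0, 3.6, 21.6, 5.2, 3.7, 1.2, 103, 11, 63, 10),
}

_ADULT_LONGITUDINAL = {
    ("White", "M"): StratumParams(34.8, 4.7, 28.0, 4.9, 6.0, 1.2, 116, 10, 78, 8, 0.268, 0.341),
    ("White", "F"): StratumParams(34.4, 4.9, 27.0, 6.6, 4.2, 1.1, 109, 10, 74, 8, 0.264, 0.153),
    ("Black", "M"): StratumParams(34.4, 4.3, 28.1, 6.9, 6.1, 1.3, 122, 14, 81, 11, 0.483, 0.573),
    ("Black", "F"): StratumParams(34.0, 5.1, 31.1, 8.1, 4.2, 1.3, 117, 15, 78, 10, 0.287, 0.210),
}

_CHILD_CROSS_SECTIONAL = {
    ("White", "M"): StratumParams(11.0, 3.9, 19.2, 4.2, 4.5, 1.4, 100, 11, 58, 9),
    ("White", "F"): StratumParams(11.0, 3.5, 19.6, 4.9, 4.1, 1.1, 100, 10, 60, 10),
    ("Black", "M"): StratumParams(11.5, 3.8, 19.4, 4.7, 4.1, 1.4, 102, 12, 59, 10),
    ("Black", "F"): StratumParams(11.4, 3.7, 19.7, 4.7, 3.6, 1.0, 101, 11, 60, 11),
}

_ADULT_CROSS_SECTIONAL = {
    ("White", "M"): StratumParams(36.9, 11.0, 28.6, 6.0, 6.1, 1.3, 119, 13, 79, 10, 0.345, 0.362),
    ("White", "F"): StratumParams(37.1, 10.9, 28.0, 7.4, 4.5, 1.2, 112, 12, 74, 9, 0.332, 0.208),
    ("Black", "M"): StratumParams(34.3, 11.5, 28.2, 7.3, 6.2, 1.5, 124, 17, 80, 13, 0.387, 0.395),
    ("Black", "F"): StratumParams(35.1, 11.8, 31.4, 8.7, 4.6, 1.7, 118, 18, 77, 12, 0.240, 0.143),
}

_STRATA = {
    "child_longitudinal": _CHILD_LONGITUDINAL,
    "adult_longitudinal": _ADULT_LONGITUDINAL,
    "child_cross_sectional": _CHILD_CROSS_SECTIONAL,
    "adult_cross_sectional": _ADULT_CROSS_SECTIONAL,
}


def default_strata(which: str) -> dict[tuple[str, str], StratumParams]:
    """Return a copy of one of the built-in stratum tables."""
    try:
        table = _STRATA[which]
    except KeyError:
        raise ConfigurationError(
            f"unknown stratum table {which!r}; choose from {sorted(_STRATA)}") from None
    return {k: StratumParams(**asdict(v)) for k, v in table.items()}


def _make_config(defaults: dict, overrides: dict) -> SimulationConfig:
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def child_two_wave_config(n_subjects: int = 564, seed: int = 0, **overrides) -> SimulationConfig:
    """Children-scale two-wave cohort (childhood baseline, adult follow-up, 7-14 y)."""
    return _make_config(dict(
        n_subjects=n_subjects, design="two_wave", seed=seed,
        rho1_gen=0.0, rho2_gen=0.145, track_bmi=0.7, track_ua=0.5, r1_gen=0.25,
        stratum_params=default_strata("child_longitudinal"),
        followup_range=(7.0, 14.0)), overrides)


def adult_two_wave_config(n_subjects: int = 911, seed: int = 0, **overrides) -> SimulationConfig:
    """Adults-scale two-wave cohort (young adulthood to midlife, 5-14 y)."""
    return _make_config(dict(
        n_subjects=n_subjects, design="two_wave", seed=seed,
        rho1_gen=0.0, rho2_gen=0.068, track_bmi=0.8, track_ua=0.6, r1_gen=0.25,
        cprime_gen=0.212, beta2_gen=0.105,
        stratum_params=default_strata("adult_longitudinal"),
        followup_range=(5.0, 14.0)), overrides)


def child_mediation_config(n_subjects: int = 3102, seed: int = 0, **overrides) -> SimulationConfig:
    """Children-scale cross-sectional cohort with BMI -> UA -> SBP mediation."""
    return _make_config(dict(
        n_subjects=n_subjects, design="cross_sectional", seed=seed,
        r1_gen=0.365, cprime_gen=0.289, beta2_gen=0.076,
        stratum_params=default_strata("child_cross_sectional")), overrides)


def adult_mediation_config(n_subjects: int = 3402, seed: int = 0, **overrides) -> SimulationConfig:
    """Adults-scale cross-sectional cohort with BMI -> UA -> SBP mediation."""
    return _make_config(dict(
        n_subjects=n_subjects, design="cross_sectional", seed=seed,
        r1_gen=0.322, cprime_gen=0.212, beta2_gen=0.105,
        stratum_params=default_strata("adult_cross_sectional")), overrides)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML (or JSON) key-value file.

    Recognised top-level keys mirror the dataclass fields; ``stratum_params``
    may either name a built-in table (string) or map ``"Race/Sex"`` labels to
    per-stratum moment dictionaries.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    sp = raw.pop("stratum_params", None)
    if isinstance(sp, str):
        strata = default_strata(sp)
    elif isinstance(sp, dict):
        strata = {}
        for label, vals in sp.items():
            race, _, sex = str(label).partition("/")
            if race not in RACES or sex not in SEXES:
                raise ConfigurationError(
                    f"stratum label {label!r} must be 'Race/Sex' with race in {RACES}, sex in {SEXES}")
            strata[(race, sex)] = StratumParams(**vals)
    elif sp is None:
        strata = {}
    else:
        raise ConfigurationError("stratum_params must be a table name or a mapping")
    for nested, cls in (("covariate_effects", CovariateEffects), ("med_model", MedicationModel)):
        if nested in raw and isinstance(raw[nested], dict):
            raw[nested] = cls(**raw[nested])
    if "followup_range" in raw:
        raw["followup_range"] = tuple(raw["followup_range"])
    try:
        cfg = SimulationConfig(stratum_params=strata, **raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad config key: {exc}") from exc
    cfg.validate()
    return cfg
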