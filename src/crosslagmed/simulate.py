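"""Synthetic cohort generator.

Generates two-wave and cross-sectional cohorts with the statistical structure
the downstream analyses assume, so every pipeline stage is testable without
access to the original (non-deposited) study data.

The latent process is a minimal Gaussian structural model.  Per subject,
standardized baseline scores ``(zx1, zu1)`` for BMI and uric acid are
bivariate normal with correlation ``r1_gen``; follow-up scores are

    zx2 = track_bmi * zx1 + rho1_gen * zu1 + g_x * f + e_x
    zu2 = rho2_gen * zx1 + track_ua  * zu1 + g_u * f + e_u

with ``f`` the standardized follow-up duration and error variances chosen so
every latent has unit variance (stationarity).  Raw BMI/UA are stratum mean +
linear covariate effects + stratum SD x latent z.  True blood pressure carries
the mediation structure: standardized true SBP = cprime_gen * zx + beta2_gen *
zu + noise (unit variance), mapped onto the stratum's mmHg scale; DBP uses
attenuated paths.  Antihypertensive treatment is assigned from true pressures
and *recorded* pressures of treated subjects are true values minus (10, 5)
mmHg, so the standard medication adjustment exactly inverts the masking.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RACES, SEXES, SimulationConfig
from .errors import ConfigurationError

__all__ = ["simulate_cohort", "write_cohort", "read_cohort", "sample_with_exact_moments",
           "mediation_example_data"]

COLUMNS = ["subject_id", "visit", "age", "race", "sex", "smoker", "drinker",
           "on_bp_meds", "bmi", "uric_acid", "sbp", "dbp", "followup_years"]

# positivity/range guards on raw scales, placed far (>4 SD) outside the
# default stratum moments so clipping never distorts moments (docs/methods.md)
_BMI_FLOOR = 1.0
_UA_FLOOR = 0.1
_SBP_RANGE = (40.0, 300.0)
_DBP_FLOOR = 20.0


def _assign_strata(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    race = np.where(rng.random(cfg.n_subjects) < cfg.prop_white, "White", "Black")
    sex = np.where(rng.random(cfg.n_subjects) < cfg.prop_female, "F", "M")
    return race, sex


def _raw_scale(latent_z, stratum_mean, stratum_sd, age_c, smoker, drinker,
               age_eff, smoke_eff, drink_eff):
    return (stratum_mean + age_eff * age_c + smoke_eff * smoker
            + drink_eff * drinker + stratum_sd * latent_z)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a cohort; returns one row per subject-visit.

    Deterministic given ``config.seed``.  Raises
    :class:`~crosslagmed.errors.ConfigurationError` when the configuration
    implies a non-positive-definite latent covariance (the message names the
    offending parameters).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    strata = config.resolved_strata()
    for r in RACES:
        for s in SEXES:
            if (r, s) not in strata:
                raise ConfigurationError(f"stratum_params missing stratum ({r}, {s})")

    race, sex = _assign_strata(config, rng)
    ce = config.covariate_effects

    # per-stratum raw-scale parameters, vectorised over subjects
    def stratum_attr(name):
        return np.array([getattr(strata[(r, s)], name) for r, s in zip(race, sex)])

    age = stratum_attr("age_mean") + stratum_attr("age_sd") * rng.standard_normal(n)
    age = np.maximum(age, 1.0)
    smoker = (rng.random(n) < stratum_attr("smoking_prob")).astype(int)
    drinker = (rng.random(n) < stratum_attr("drinking_prob")).astype(int)
    age_c = age - stratum_attr("age_mean")

    # baseline latents
    r1 = config.r1_gen
    z = rng.standard_normal((n, 2))
    zx1 = z[:, 0]
    if config.design == "two_wave":
        zu1 = r1 * z[:, 0] + np.sqrt(1.0 - r1**2) * z[:, 1]
    else:
        # cross-sectional: UA is downstream of BMI with path beta1 = r1_gen
        zu1 = r1 * z[:, 0] + np.sqrt(1.0 - r1**2) * z[:, 1]

    def raw_bmi(latent, idx_sd="bmi_sd", idx_mean="bmi_mean"):
        v = _raw_scale(latent, stratum_attr(idx_mean), stratum_attr(idx_sd),
                       age_c, smoker, drinker, ce.age_bmi, ce.smoking_bmi, ce.drinking_bmi)
        return np.maximum(v, _BMI_FLOOR)

    def raw_ua(latent):
        v = _raw_scale(latent, stratum_attr("ua_mean"), stratum_attr("ua_sd"),
                       age_c, smoker, drinker, ce.age_ua, ce.smoking_ua, ce.drinking_ua)
        return np.maximum(v, _UA_FLOOR)

    def bp_block(zx, zu):
        """True and recorded SBP/DBP plus medication flag from latent scores."""
        noise_var = config.bp_noise_variance()
        zsbp = (config.cprime_gen * zx + config.beta2_gen * zu
                + np.sqrt(noise_var) * rng.standard_normal(n))
        a = config.dbp_attenuation
        dvar = 1.0 - (a * config.cprime_gen)**2 - (a * config.beta2_gen)**2 \
            - 2.0 * a * a * config.cprime_gen * config.beta2_gen * r1
        zdbp = (a * config.cprime_gen * zx + a * config.beta2_gen * zu
                + np.sqrt(max(dvar, 1e-12)) * rng.standard_normal(n))
        sbp_true = stratum_attr("sbp_mean") + stratum_attr("sbp_sd") * zsbp
        dbp_true = stratum_attr("dbp_mean") + stratum_attr("dbp_sd") * zdbp
        sbp_true = np.clip(sbp_true, *_SBP_RANGE)
        # keep DBP at least (sbp_effect - dbp_effect) + 5 below SBP so the gap
        # survives medication masking, which lowers SBP by more than DBP
        mm = config.med_model
        gap = mm.sbp_effect - mm.dbp_effect + 5.0
        dbp_true = np.clip(dbp_true, _DBP_FLOOR, sbp_true - gap)
        eligible = (sbp_true >= mm.sbp_threshold) | (dbp_true >= mm.dbp_threshold)
        on_meds = (eligible & (rng.random(n) < mm.treat_prob)).astype(int)
        sbp_rec = sbp_true - mm.sbp_effect * on_meds
        dbp_rec = dbp_true - mm.dbp_effect * on_meds
        return sbp_rec, dbp_rec, on_meds

    subject_id = np.array([f"S{i:06d}" for i in range(n)])

    if config.design == "cross_sectional":
        sbp, dbp, on_meds = bp_block(zx1, zu1)
        df = pd.DataFrame({
            "subject_id": subject_id, "visit": "baseline", "age": age,
            "race": race, "sex": sex, "smoker": smoker, "drinker": drinker,
            "on_bp_meds": on_meds, "bmi": raw_bmi(zx1), "uric_acid": raw_ua(zu1),
            "sbp": sbp, "dbp": dbp, "followup_years": np.nan,
        })
        return df[COLUMNS]

    # two-wave design
    fu_years = rng.uniform(*config.followup_range, size=n)
    span = config.followup_range[1] - config.followup_range[0]
    if span > 0:
        fu_z = (fu_years - fu_years.mean()) / fu_years.std(ddof=1)
    else:
        fu_z = np.zeros(n)
    vx, vu = config.latent_error_variances()
    zx2 = (config.track_bmi * zx1 + config.rho1_gen * zu1
           + config.followup_effect_bmi * fu_z + np.sqrt(vx) * rng.standard_normal(n))
    zu2 = (config.rho2_gen * zx1 + config.track_ua * zu1
           + config.followup_effect_ua * fu_z + np.sqrt(vu) * rng.standard_normal(n))

    sbp1, dbp1, meds1 = bp_block(zx1, zu1)
    sbp2, dbp2, meds2 = bp_block(zx2, zu2)

    base = pd.DataFrame({
        "subject_id": subject_id, "visit": "baseline", "age": age,
        "race": race, "sex": sex, "smoker": smoker, "drinker": drinker,
        "on_bp_meds": meds1, "bmi": raw_bmi(zx1), "uric_acid": raw_ua(zu1),
        "sbp": sbp1, "dbp": dbp1, "followup_years": fu_years,
    })
    fu = pd.DataFrame({
        "subject_id": subject_id, "visit": "followup", "age": age + fu_years,
        "race": race, "sex": sex, "smoker": smoker, "drinker": drinker,
        "on_bp_meds": meds2, "bmi": raw_bmi(zx2), "uric_acid": raw_ua(zu2),
        "sbp": sbp2, "dbp": dbp2, "followup_years": fu_years,
    })
    df = pd.concat([base, fu], ignore_index=True)
    return df[COLUMNS]


def write_cohort(df: pd.DataFrame, path: str | Path, config: SimulationConfig | None = None) -> None:
    """Write a cohort as CSV (UTF-8, '.' decimal) with seed metadata.

    Metadata (at minimum the seed) is recorded as ``# key=value`` comment
    lines before the header so the file remains a plain delimited table.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config is not None:
            fh.write(f"# seed={config.seed}\n")
            fh.write(f"# design={config.design}\n")
            fh.write(f"# n_subjects={config.n_subjects}\n")
        df.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (skips '#' metadata)."""
    return pd.read_csv(path, comment="#")


# ----------------------------------------------------------------------
# Exact-moment sampling, used for worked examples whose fitted coefficients
# must equal specified standardized paths to machine precision.

def sample_with_exact_moments(corr: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Draw an ``n x p`` sample whose *sample* correlation matrix equals ``corr``.

    Columns have sample mean exactly 0 and sample SD exactly 1 (n-1
    denominator).  Works by empirically whitening an i.i.d. Gaussian draw and
    re-colouring with the Cholesky factor of the target matrix; requires
    ``n > p`` and a positive-definite target.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if corr.shape != (p, p) or not np.allclose(corr, corr.T):
        raise ValueError("corr must be a symmetric square matrix")
    if n <= p:
        raise ValueError(f"need n > p ({n} <= {p})")
    try:
        target_chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("corr must be positive definite") from None
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    x -= x.mean(axis=0)
    cov = x.T @ x / (n - 1)
    white = x @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return white @ target_chol.T


def mediation_example_data(beta1: float, beta2: float, cprime: float,
                           n: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Exposure/mediator/outcome triple whose fitted standardized mediation
    paths equal ``beta1`` (x->m), ``beta2`` (m->y | x) and ``cprime`` (x->y | m)
    exactly.

    The implied correlation matrix of standardized (x, m, y) under the linear
    mediation model is::

        corr(x, m) = beta1
        corr(m, y) = beta2 + cprime * beta1
        corr(x, y) = cprime + beta2 * beta1   (= total effect c)

    and the sample is moment-matched to it exactly, so an OLS mediation fit
    returns the requested paths to machine precision.
    """
    r_xm = beta1
    r_my = beta2 + cprime * beta1
    r_xy = cprime + beta2 * beta1
    corr = np.array([[1.0, r_xm, r_xy],
                     [r_xm, 1.0, r_my],
                     [r_xy, r_my, 1.0]])
    data = sample_with_exact_moments(corr, n, seed)
    return pd.DataFrame(data, columns=["x", "m", "y"])


def simulation_metadata(config: SimulationConfig) -> str:
    """JSON blob describing a simulation run (seed always included)."""
    return json.dumps(config.to_dict(), default=str, indent=2)
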