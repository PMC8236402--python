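"""Measurement-derived transforms and covariate residualization.

The analysis pipeline prepares raw cohort variables in a fixed order:
medication adjustment of continuous BP, complete-case filtering, per-stratum
covariate residualization (OLS residuals), then per-stratum z-standardization.
Residualize-then-standardize is the documented order; reversing it changes the
result because residualization alters the scale that standardization divides
out.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EstimationError

logger = logging.getLogger(__name__)

__all__ = ["compute_bmi", "adjust_bp_for_medication", "classify_hypertension",
           "residualize", "zstandardize", "build_two_wave_panel", "covariates_for"]

#: covariates removed before the cross-lagged analysis, by cohort type
COHORT_COVARIATES = {
    "child": ["age"],
    "adult": ["age", "smoker", "drinker"],
}


def covariates_for(cohort_type: str) -> list[str]:
    try:
        return list(COHORT_COVARIATES[cohort_type])
    except KeyError:
        raise ValueError(f"cohort_type must be 'child' or 'adult', got {cohort_type!r}") from None


def compute_bmi(weight, height):
    """Body mass index: weight (kg) divided by height (m) squared."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def adjust_bp_for_medication(sbp, dbp, on_meds):
    """Medication adjustment for continuous BP analyses.

    Treated subjects' recorded pressures approximate post-treatment values;
    adding the average treatment effects (+10 mmHg SBP, +5 mmHg DBP) restores
    an estimate of the untreated pressure.  Untreated rows pass through
    unchanged.  Pure: apply exactly once per record.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    meds = np.asarray(on_meds).astype(bool)
    sbp_adj = sbp + 10.0 * meds
    dbp_adj = dbp + 5.0 * meds
    if sbp_adj.ndim == 0:
        return float(sbp_adj), float(dbp_adj)
    return sbp_adj, dbp_adj


def classify_hypertension(sbp, dbp, on_meds):
    """Hypertension: SBP >= 130 or DBP >= 80 mmHg, or on antihypertensives.

    Operates on *recorded* pressures — the medication flag already enters the
    definition, so no +10/+5 adjustment is applied here.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    meds = np.asarray(on_meds).astype(bool)
    out = (sbp >= 130.0) | (dbp >= 80.0) | meds
    return bool(out) if out.ndim == 0 else out.astype(int)


def _as_strata(strata, n):
    s = pd.Series(strata)
    if len(s) != n:
        raise ValueError("strata length does not match values length")
    return s.reset_index(drop=True)


def residualize(values, covariates, strata) -> np.ndarray:
    """Within-stratum OLS residuals of ``values`` on ``covariates`` + intercept.

    ``covariates`` is an (n, k) matrix (k may be 0).  Residuals within each
    stratum are orthogonal to every covariate column and have mean ~0.  Raises
    :class:`EstimationError` naming the stratum on rank deficiency or when a
    stratum has fewer rows than covariates + 2.
    """
    y = np.asarray(values, dtype=float).ravel()
    n = y.shape[0]
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((n, 0))
    if X.shape[0] != n:
        raise ValueError("covariates row count does not match values length")
    s = _as_strata(strata, n)
    resid = np.empty(n)
    for label, idx in s.groupby(s).groups.items():
        idx = np.asarray(idx)
        k = X.shape[1]
        if len(idx) < k + 2:
            raise EstimationError(
                f"stratum {label!r} has {len(idx)} rows; need at least {k + 2} "
                f"for {k} covariate(s)")
        Xg = X[idx]
        # constant columns carry no information beyond the intercept
        if Xg.size:
            keep = Xg.std(axis=0) > 1e-12 * (1.0 + np.abs(Xg).max(axis=0))
        else:
            keep = np.zeros(0, dtype=bool)
        Xs = np.column_stack([np.ones(len(idx)), Xg[:, keep]])
        rank = np.linalg.matrix_rank(Xs)
        if rank < Xs.shape[1]:
            raise EstimationError(f"rank-deficient covariate matrix in stratum {label!r}")
        beta, *_ = np.linalg.lstsq(Xs, y[idx], rcond=None)
        resid[idx] = y[idx] - Xs @ beta
    return resid


def zstandardize(values, strata) -> np.ndarray:
    """Within-stratum z-scores ((v - mean) / SD, sample SD with n-1)."""
    y = np.asarray(values, dtype=float).ravel()
    s = _as_strata(strata, y.shape[0])
    out = np.empty_like(y)
    for label, idx in s.groupby(s).groups.items():
        idx = np.asarray(idx)
        v = y[idx]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise EstimationError(f"zero-variance stratum {label!r} cannot be standardized")
        out[idx] = (v - v.mean()) / sd
    return out


def build_two_wave_panel(cohort: pd.DataFrame, cohort_type: str = "child") -> pd.DataFrame:
    """Assemble the standardized two-wave panel from a long cohort table.

    Pivots baseline/follow-up rows to one row per subject, drops incomplete
    cases (logged), then residualizes each of the four BMI/UA measurements on
    the cohort-type covariates and z-standardizes, both within race x sex
    strata.

    Returns columns ``bmi_z_base, ua_z_base, bmi_z_fu, ua_z_fu,
    followup_years, stratum, race, sex`` (one row per subject).
    """
    required = {"subject_id", "visit", "age", "race", "sex", "bmi", "uric_acid",
                "followup_years"}
    missing = required - set(cohort.columns)
    if missing:
        from .errors import SchemaError
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")

    covariate_names = covariates_for(cohort_type)
    base = cohort[cohort["visit"] == "baseline"].set_index("subject_id")
    fu = cohort[cohort["visit"] == "followup"].set_index("subject_id")
    common = base.index.intersection(fu.index)
    wide = pd.DataFrame({
        "bmi_base": base.loc[common, "bmi"],
        "ua_base": base.loc[common, "uric_acid"],
        "bmi_fu": fu.loc[common, "bmi"],
        "ua_fu": fu.loc[common, "uric_acid"],
        "age_base": base.loc[common, "age"],
        "age_fu": fu.loc[common, "age"],
        "smoker": base.loc[common, "smoker"] if "smoker" in base else 0,
        "drinker": base.loc[common, "drinker"] if "drinker" in base else 0,
        "followup_years": base.loc[common, "followup_years"],
        "race": base.loc[common, "race"],
        "sex": base.loc[common, "sex"],
    })
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide) + (len(base.index.union(fu.index)) - len(common))
    if dropped:
        logger.info("complete-case filter dropped %d subject(s)", dropped)
    wide = wide.reset_index()
    strata = wide["race"].astype(str) + "/" + wide["sex"].astype(str)

    def covmat(age_col):
        cols = []
        for name in covariate_names:
            cols.append(wide[age_col].to_numpy() if name == "age"
                        else wide[name].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(wide), 0))

    panel = pd.DataFrame({"subject_id": wide["subject_id"]})
    for out_col, raw_col, age_col in (
            ("bmi_z_base", "bmi_base", "age_base"), ("ua_z_base", "ua_base", "age_base"),
            ("bmi_z_fu", "bmi_fu", "age_fu"), ("ua_z_fu", "ua_fu", "age_fu")):
        resid = residualize(wide[raw_col].to_numpy(), covmat(age_col), strata)
        panel[out_col] = zstandardize(resid, strata)
    panel["followup_years"] = wide["followup_years"].to_numpy()
    panel["stratum"] = strata.to_numpy()
    panel["race"] = wide["race"].to_numpy()
    panel["sex"] = wide["sex"].to_numpy()
    panel.attrs["dropped_rows"] = dropped
    return panel
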