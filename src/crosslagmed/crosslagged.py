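"""Two-wave cross-lagged panel model.

The model regresses each standardized follow-up measurement on both
standardized baseline measurements (and optionally on standardized follow-up
duration):

    bmi_fu = track_bmi * bmi_base + rho1 * ua_base + g1 * f + e1
    ua_fu  = rho2 * bmi_base + track_ua * ua_base + g2 * f + e2

``rho1`` (baseline UA -> follow-up BMI) and ``rho2`` (baseline BMI ->
follow-up UA) are the cross-lagged paths whose relative significance
disentangles temporal precedence.  Exogenous covariances are free and the
follow-up residual covariance cov(e1, e2) is fixed at 0 by default (one
testable restriction, model df = 1; set ``residual_cov_free=True`` for the
saturated variant).  The model is recursive with uncorrelated errors, so
maximum-likelihood point estimates coincide with equation-wise OLS; the
model-implied covariance matrix is assembled explicitly to obtain the ML
discrepancy chi-square and the CFI / RMR fit indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError

__all__ = ["CrossLaggedResult", "FisherZComparison", "fit_cross_lagged",
           "compute_fit_indices", "fisher_z_compare"]

MIN_N = 30


@dataclass
class PathEstimate:
    estimate: float
    se: float
    p: float


@dataclass
class CrossLaggedResult:
    """Estimates, correlations and fit indices for one panel fit."""

    rho1: PathEstimate              # baseline UA -> follow-up BMI
    rho2: PathEstimate              # baseline BMI -> follow-up UA
    track_bmi: PathEstimate         # BMI autoregressive path
    track_ua: PathEstimate          # UA autoregressive path
    gamma_bmi: PathEstimate | None  # follow-up-years nuisance paths
    gamma_ua: PathEstimate | None
    r1: float                       # synchronous baseline correlation
    r2: float                       # BMI tracking correlation
    r3: float                       # UA tracking correlation
    rsq_bmi: float
    rsq_ua: float
    cfi: float
    rmr: float
    chisq: float
    df: int
    n: int
    observed_cov: np.ndarray = field(repr=False, default=None)
    implied_cov: np.ndarray = field(repr=False, default=None)

    @property
    def good_fit(self) -> bool:
        """Conventional rule of thumb: CFI > 0.90 and RMR < 0.05."""
        return self.cfi > 0.90 and self.rmr < 0.05

    def to_frame(self) -> pd.DataFrame:
        """One row per path (estimate, SE, p) plus model-level statistics."""
        rows = []
        for name, pe in (("rho1_ua_to_bmi", self.rho1), ("rho2_bmi_to_ua", self.rho2),
                         ("track_bmi", self.track_bmi), ("track_ua", self.track_ua),
                         ("gamma_followup_bmi", self.gamma_bmi),
                         ("gamma_followup_ua", self.gamma_ua)):
            if pe is not None:
                rows.append({"path": name, "estimate": pe.estimate, "se": pe.se, "p": pe.p})
        out = pd.DataFrame(rows)
        for k, v in (("r1", self.r1), ("r2", self.r2), ("r3", self.r3),
                     ("rsq_bmi", self.rsq_bmi), ("rsq_ua", self.rsq_ua),
                     ("cfi", self.cfi), ("rmr", self.rmr), ("chisq", self.chisq),
                     ("df", self.df), ("n", self.n)):
            out[k] = v
        return out


@dataclass
class FisherZComparison:
    """Fisher r-to-z comparison of one coefficient between two strata."""

    group1: str
    group2: str
    coef1: float
    coef2: float
    n1: int
    n2: int
    z: float
    p: float


def _path(result, name) -> PathEstimate:
    return PathEstimate(float(result.params[name]), float(result.bse[name]),
                        float(result.pvalues[name]))


def fit_cross_lagged(panel: pd.DataFrame, adjust_followup: bool = True,
                     residual_cov_free: bool = False, min_n: int = MIN_N) -> CrossLaggedResult:
    """Fit the cross-lagged model to a standardized two-wave panel.

    ``panel`` needs columns ``bmi_z_base, ua_z_base, bmi_z_fu, ua_z_fu`` and,
    when ``adjust_followup``, ``followup_years`` (standardized internally).
    Point estimates and t-based SEs/p-values come from equation-wise OLS;
    fit indices from the explicit ML discrepancy.  Refuses panels with
    n < ``min_n`` (default 30); lower the floor explicitly only for
    algebraic checks on toy data, where SEs and indices are not meaningful.
    """
    required = ["bmi_z_base", "ua_z_base", "bmi_z_fu", "ua_z_fu"]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        from .errors import SchemaError
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    n = len(panel)
    if n < min_n:
        raise EstimationError(f"panel has n={n}; at least {min_n} subjects required")

    x1 = panel["bmi_z_base"].to_numpy(dtype=float)
    u1 = panel["ua_z_base"].to_numpy(dtype=float)
    x2 = panel["bmi_z_fu"].to_numpy(dtype=float)
    u2 = panel["ua_z_fu"].to_numpy(dtype=float)

    exog = {"bmi_z_base": x1, "ua_z_base": u1}
    if adjust_followup:
        if "followup_years" not in panel.columns:
            from .errors import SchemaError
            raise SchemaError("missing required column(s): followup_years")
        fy = panel["followup_years"].to_numpy(dtype=float)
        sd = fy.std(ddof=1)
        if sd <= 0:
            raise EstimationError("followup_years has zero variance; cannot standardize")
        exog["followup_z"] = (fy - fy.mean()) / sd
    X = sm.add_constant(pd.DataFrame(exog))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise EstimationError("singular design matrix in cross-lagged fit")

    fit_bmi = sm.OLS(x2, X).fit()
    fit_ua = sm.OLS(u2, X).fit()

    # observed covariance of (exogenous..., endogenous) in a fixed order
    names = ["bmi_z_base", "ua_z_base"] + (["followup_z"] if adjust_followup else [])
    W = np.column_stack([exog[k] for k in names])
    data = np.column_stack([W, x2, u2])
    S = np.cov(data, rowvar=False, ddof=1)

    # model-implied covariance: exog block free (MLE = sample), endo = B w + e
    k = W.shape[1]
    Phi = S[:k, :k]
    B = np.vstack([fit_bmi.params[1:].to_numpy(), fit_ua.params[1:].to_numpy()])
    psi1 = float(fit_bmi.resid @ fit_bmi.resid) / (n - 1)
    psi2 = float(fit_ua.resid @ fit_ua.resid) / (n - 1)
    if residual_cov_free:
        psi12 = float(fit_bmi.resid @ fit_ua.resid) / (n - 1)
        df_model = 0
    else:
        psi12 = 0.0
        df_model = 1
    Psi = np.array([[psi1, psi12], [psi12, psi2]])
    Sigma = np.empty_like(S)
    Sigma[:k, :k] = Phi
    Sigma[:k, k:] = Phi @ B.T
    Sigma[k:, :k] = B @ Phi
    Sigma[k:, k:] = B @ Phi @ B.T + Psi

    cfi, rmr, chisq = compute_fit_indices(S, Sigma, n, df_model)

    r1 = float(np.corrcoef(x1, u1)[0, 1])
    r2 = float(np.corrcoef(x1, x2)[0, 1])
    r3 = float(np.corrcoef(u1, u2)[0, 1])

    return CrossLaggedResult(
        rho1=_path(fit_bmi, "ua_z_base"),
        rho2=_path(fit_ua, "bmi_z_base"),
        track_bmi=_path(fit_bmi, "bmi_z_base"),
        track_ua=_path(fit_ua, "ua_z_base"),
        gamma_bmi=_path(fit_bmi, "followup_z") if adjust_followup else None,
        gamma_ua=_path(fit_ua, "followup_z") if adjust_followup else None,
        r1=r1, r2=r2, r3=r3,
        rsq_bmi=float(fit_bmi.rsquared), rsq_ua=float(fit_ua.rsquared),
        cfi=cfi, rmr=rmr, chisq=chisq, df=df_model, n=n,
        observed_cov=S, implied_cov=Sigma)


def compute_fit_indices(observed_cov: np.ndarray, implied_cov: np.ndarray, n: int,
                        df_model: int, df_baseline: int | None = None) -> tuple[float, float, float]:
    """ML chi-square, CFI and RMR for a covariance-structure fit.

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p;  chi2 = (n - 1) F_ML.
    CFI compares the model's excess chi-square over its df with that of the
    independence (diagonal-covariance) baseline.  RMR is the root mean square
    of the unique residual covariances; on standardized inputs it coincides
    with SRMR.  Returns ``(cfi, rmr, chisq)``.
    """
    S = np.asarray(observed_cov, dtype=float)
    Sigma = np.asarray(implied_cov, dtype=float)
    p = S.shape[0]
    if S.shape != Sigma.shape or S.shape != (p, p):
        raise ValueError("covariance matrices must be square and the same dimension")
    for name, M in (("observed", S), ("implied", Sigma)):
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError(f"{name} covariance is not symmetric")
        if np.any(np.linalg.eigvalsh(M) <= 0):
            raise ValueError(f"{name} covariance is not positive definite")

    def f_ml(Sig):
        sign, logdet = np.linalg.slogdet(Sig)
        _, logdet_s = np.linalg.slogdet(S)
        return float(logdet - logdet_s + np.trace(S @ np.linalg.inv(Sig)) - p)

    chisq = max((n - 1) * f_ml(Sigma), 0.0)
    if df_baseline is None:
        df_baseline = p * (p - 1) // 2
    chisq_b = max((n - 1) * f_ml(np.diag(np.diag(S))), 0.0)
    excess_m = max(chisq - df_model, 0.0)
    denom = max(chisq_b - df_baseline, excess_m, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess_m / denom
    cfi = float(min(max(cfi, 0.0), 1.0))

    tri = np.tril_indices(p)
    rmr = float(np.sqrt(np.sum((S[tri] - Sigma[tri]) ** 2) / (p * (p + 1) / 2)))
    return cfi, rmr, chisq


def fisher_z_compare(coef1: float, n1: int, coef2: float, n2: int,
                     group1: str = "group1", group2: str = "group2") -> FisherZComparison:
    """Compare two correlation-scale coefficients across independent strata.

    z = (atanh(c1) - atanh(c2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal
    p-value.  Applied here to standardized path coefficients, which is an
    approximation (they are treated as correlation-scale quantities).
    """
    for c, n, g in ((coef1, n1, group1), (coef2, n2, group2)):
        if not abs(c) < 1.0:
            raise ValueError(f"coefficient for {g} must satisfy |coef| < 1, got {c}")
        if n <= 3:
            raise ValueError(f"group {g} needs n > 3, got {n}")
    z = (np.arctanh(coef1) - np.arctanh(coef2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return FisherZComparison(group1, group2, coef1, coef2, n1, n2, float(z), min(p, 1.0))
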