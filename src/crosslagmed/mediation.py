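"""Product-of-coefficients mediation analysis.

The four-step decomposition for exposure X, mediator M and outcome Y:

1. regress Y on X (+ covariates)            -> total effect c
2. regress M on X (+ covariates)            -> beta1 (X -> M)
3. regress Y on M and X (+ covariates)      -> beta2 (M -> Y | X), c' (direct)
4. indirect effect beta_ind = beta1 * beta2; mediation % = 100 * beta_ind / c

X, M and Y are z-standardized before fitting so every coefficient is a
standardized regression coefficient; covariates stay on their natural scale.
With a continuous outcome and identical covariate sets in all three OLS fits,
the decomposition is exact: c = c' + beta1 * beta2 to machine precision.  With
a binary outcome, steps 1 and 3 are ML logistic regressions on the log-odds
scale and the additivity identity is *not* asserted (logistic coefficients are
non-collapsible: adding the mediator rescales c' even without confounding).

The Sobel (delta-method) standard error for the product is
sqrt(beta2^2 SE(beta1)^2 + beta1^2 SE(beta2)^2); a seeded percentile bootstrap
is available (and on by default for binary outcomes) as the more robust
interval for a product of coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError

__all__ = ["MediationResult", "fit_mediation", "fit_mediation_binary",
           "subgroup_interaction_test"]


@dataclass
class MediationResult:
    """Standardized mediation decomposition with per-path inference."""

    c: float
    c_prime: float
    beta1: float
    beta2: float
    beta_ind: float
    mediation_pct: float | None     # None when |c| is numerically zero
    se_c: float
    se_c_prime: float
    se_beta1: float
    se_beta2: float
    se_beta_ind: float              # Sobel
    p_c: float
    p_c_prime: float
    p_beta1: float
    p_beta2: float
    p_beta_ind: float               # Sobel, normal reference
    outcome_type: str               # "continuous" | "binary"
    n: int
    ci_beta_ind: tuple[float, float] | None = None   # percentile bootstrap

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("c_total", self.c, self.se_c, self.p_c),
            ("c_prime_direct", self.c_prime, self.se_c_prime, self.p_c_prime),
            ("beta1_x_to_m", self.beta1, self.se_beta1, self.p_beta1),
            ("beta2_m_to_y", self.beta2, self.se_beta2, self.p_beta2),
            ("beta_ind", self.beta_ind, self.se_beta_ind, self.p_beta_ind),
        ]
        out = pd.DataFrame(rows, columns=["path", "estimate", "se", "p"])
        out["mediation_pct"] = np.nan if self.mediation_pct is None else self.mediation_pct
        out["outcome_type"] = self.outcome_type
        out["n"] = self.n
        if self.ci_beta_ind is not None:
            out["ci_low"], out["ci_high"] = self.ci_beta_ind
        return out


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd <= 0:
        raise EstimationError("zero-variance variable cannot be standardized")
    return (v - v.mean()) / sd


def _prep(x, m, y, covariates, standardize_y=True):
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if not (m.shape[0] == y.shape[0] == n):
        raise ValueError("x, m, y must have equal lengths")
    if covariates is None:
        C = np.empty((n, 0))
        cov_names: list[str] = []
    else:
        C = pd.DataFrame(covariates)
        cov_names = [str(c) for c in C.columns]
        C = C.to_numpy(dtype=float)
        if C.shape[0] != n:
            raise ValueError("covariates row count does not match x")
    if n < C.shape[1] + 4:
        raise EstimationError(f"n={n} too small for {C.shape[1]} covariate(s)")
    xz, mz = _zscore(x), _zscore(m)
    yz = _zscore(y) if standardize_y else y
    return xz, mz, yz, C, cov_names, n


def _design(cols: dict[str, np.ndarray], C: np.ndarray, cov_names) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    for j, name in enumerate(cov_names):
        df[name] = C[:, j]
    X = sm.add_constant(df)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise EstimationError("collinear design matrix in mediation fit")
    return X


def _sobel(beta1, se1, beta2, se2):
    se = float(np.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2))
    p = float(2.0 * stats.norm.sf(abs(beta1 * beta2) / se)) if se > 0 else 1.0
    return se, p


def fit_mediation(x, m, y, covariates=None, n_boot: int = 0,
                  seed: int | None = None) -> MediationResult:
    """Continuous-outcome mediation decomposition (three OLS fits).

    Set ``n_boot > 0`` for a seeded percentile-bootstrap CI on the indirect
    effect.  ``mediation_pct`` is ``None`` when the total effect is
    numerically zero.
    """
    xz, mz, yz, C, cov_names, n = _prep(x, m, y, covariates)
    fit_c = sm.OLS(yz, _design({"x": xz}, C, cov_names)).fit()
    fit_b1 = sm.OLS(mz, _design({"x": xz}, C, cov_names)).fit()
    fit_dir = sm.OLS(yz, _design({"m": mz, "x": xz}, C, cov_names)).fit()

    c = float(fit_c.params["x"])
    beta1 = float(fit_b1.params["x"])
    beta2 = float(fit_dir.params["m"])
    c_prime = float(fit_dir.params["x"])
    beta_ind = beta1 * beta2
    se_ind, p_ind = _sobel(beta1, float(fit_b1.bse["x"]), beta2, float(fit_dir.bse["m"]))
    pct = None if abs(c) < 1e-12 else 100.0 * beta_ind / c

    ci = None
    if n_boot > 0:
        ci = _bootstrap_indirect(xz, mz, yz, C, cov_names, n_boot, seed, binary=False)

    return MediationResult(
        c=c, c_prime=c_prime, beta1=beta1, beta2=beta2, beta_ind=beta_ind,
        mediation_pct=pct,
        se_c=float(fit_c.bse["x"]), se_c_prime=float(fit_dir.bse["x"]),
        se_beta1=float(fit_b1.bse["x"]), se_beta2=float(fit_dir.bse["m"]),
        se_beta_ind=se_ind,
        p_c=float(fit_c.pvalues["x"]), p_c_prime=float(fit_dir.pvalues["x"]),
        p_beta1=float(fit_b1.pvalues["x"]), p_beta2=float(fit_dir.pvalues["m"]),
        p_beta_ind=p_ind, outcome_type="continuous", n=n, ci_beta_ind=ci)


def _logit_fit(y, X):
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise EstimationError("logistic fit did not converge within the iteration limit")
    return fit


def fit_mediation_binary(x, m, y, covariates=None, n_boot: int = 1000,
                         seed: int | None = None) -> MediationResult:
    """Mediation with a dichotomous outcome (e.g. hypertension).

    Steps 1 and 3 are ML logistic regressions; coefficients are on the
    log-odds scale with standardized continuous predictors.  Step 2 stays
    OLS.  The bootstrap is on by default (1000 resamples, seeded); pass
    ``n_boot=0`` to skip it.
    """
    yb = np.asarray(y)
    vals = set(np.unique(yb).tolist())
    if not vals <= {0, 1, 0.0, 1.0, False, True}:
        raise ValueError("binary outcome must contain only 0/1")
    if len(vals) < 2:
        raise EstimationError("binary outcome must contain both classes")
    yb = yb.astype(float)
    xz, mz, _, C, cov_names, n = _prep(x, m, yb, covariates, standardize_y=False)

    fit_c = _logit_fit(yb, _design({"x": xz}, C, cov_names))
    fit_b1 = sm.OLS(mz, _design({"x": xz}, C, cov_names)).fit()
    fit_dir = _logit_fit(yb, _design({"m": mz, "x": xz}, C, cov_names))

    c = float(fit_c.params["x"])
    beta1 = float(fit_b1.params["x"])
    beta2 = float(fit_dir.params["m"])
    c_prime = float(fit_dir.params["x"])
    beta_ind = beta1 * beta2
    se_ind, p_ind = _sobel(beta1, float(fit_b1.bse["x"]), beta2, float(fit_dir.bse["m"]))
    pct = None if abs(c) < 1e-12 else 100.0 * beta_ind / c

    ci = None
    if n_boot > 0:
        ci = _bootstrap_indirect(xz, mz, yb, C, cov_names, n_boot, seed, binary=True)

    return MediationResult(
        c=c, c_prime=c_prime, beta1=beta1, beta2=beta2, beta_ind=beta_ind,
        mediation_pct=pct,
        se_c=float(fit_c.bse["x"]), se_c_prime=float(fit_dir.bse["x"]),
        se_beta1=float(fit_b1.bse["x"]), se_beta2=float(fit_dir.bse["m"]),
        se_beta_ind=se_ind,
        p_c=float(fit_c.pvalues["x"]), p_c_prime=float(fit_dir.pvalues["x"]),
        p_beta1=float(fit_b1.pvalues["x"]), p_beta2=float(fit_dir.pvalues["m"]),
        p_beta_ind=p_ind, outcome_type="binary", n=n, ci_beta_ind=ci)


def _bootstrap_indirect(xz, mz, y, C, cov_names, n_boot, seed, binary):
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    n = len(xz)
    prods = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb1 = sm.add_constant(pd.DataFrame(
            {"x": xz[idx], **{nm: C[idx, j] for j, nm in enumerate(cov_names)}}))
        Xb2 = sm.add_constant(pd.DataFrame(
            {"m": mz[idx], "x": xz[idx], **{nm: C[idx, j] for j, nm in enumerate(cov_names)}}))
        try:
            b1 = float(sm.OLS(mz[idx], Xb1).fit().params["x"])
            if binary:
                b2 = float(sm.Logit(y[idx], Xb2).fit(disp=0, maxiter=100).params["m"])
            else:
                b2 = float(sm.OLS(y[idx], Xb2).fit().params["m"])
        except Exception:
            prods[b] = np.nan
            continue
        prods[b] = b1 * b2
    prods = prods[np.isfinite(prods)]
    if len(prods) < max(50, n_boot // 2):
        raise EstimationError("too many failed bootstrap resamples")
    lo, hi = np.percentile(prods, [2.5, 97.5])
    return float(lo), float(hi)


def subgroup_interaction_test(x, m, y, covariates, group, n_boot: int = 0,
                              seed: int | None = None) -> pd.DataFrame:
    """Test whether mediation parameters differ between two subgroups.

    Fits pooled interaction models: a group main effect plus group-by-x terms
    for the total, mediator and direct models (and a group-by-m term for the
    beta2 difference), each tested with a Wald test.  Group labels are coded
    0/1 in sorted order, so the interaction estimate is (group-1 parameter)
    minus (group-0 parameter).  Optionally appends a grouped-bootstrap test of
    the mediation-percentage difference (seeded).

    Returns a tidy frame: ``parameter, diff, se, p``.
    """
    g = pd.Series(group).reset_index(drop=True)
    levels = sorted(g.unique().tolist())
    if len(levels) != 2:
        raise EstimationError(f"group must have exactly 2 levels, got {levels}")
    gi = (g == levels[1]).to_numpy(dtype=float)
    xz, mz, yz, C, cov_names, n = _prep(x, m, y, covariates)

    def interaction(yvec, cols, term):
        X = _design(cols, C, cov_names)
        fit = sm.OLS(yvec, X).fit()
        return {"parameter": term["label"], "diff": float(fit.params[term["name"]]),
                "se": float(fit.bse[term["name"]]), "p": float(fit.pvalues[term["name"]])}

    rows = [
        interaction(yz, {"x": xz, "g": gi, "g_x": gi * xz},
                    {"label": "c_total_diff", "name": "g_x"}),
        interaction(mz, {"x": xz, "g": gi, "g_x": gi * xz},
                    {"label": "beta1_diff", "name": "g_x"}),
        interaction(yz, {"m": mz, "x": xz, "g": gi, "g_x": gi * xz, "g_m": gi * mz},
                    {"label": "c_prime_diff", "name": "g_x"}),
        interaction(yz, {"m": mz, "x": xz, "g": gi, "g_x": gi * xz, "g_m": gi * mz},
                    {"label": "beta2_diff", "name": "g_m"}),
    ]
    out = pd.DataFrame(rows)

    if n_boot > 0:
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        idx0 = np.flatnonzero(gi == 0)
        idx1 = np.flatnonzero(gi == 1)
        diffs = []
        for _ in range(n_boot):
            s0 = rng.choice(idx0, size=len(idx0), replace=True)
            s1 = rng.choice(idx1, size=len(idx1), replace=True)
            pcts = []
            for s in (s0, s1):
                cov_s = C[s] if C.shape[1] else None
                try:
                    res = fit_mediation(xz[s], mz[s], yz[s], cov_s)
                except EstimationError:
                    pcts.append(np.nan)
                    continue
                pcts.append(np.nan if res.mediation_pct is None else res.mediation_pct)
            diffs.append(pcts[1] - pcts[0])
        diffs = np.asarray(diffs)
        diffs = diffs[np.isfinite(diffs)]
        est = float(np.mean(diffs))
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        # two-sided percentile p: smallest alpha whose CI excludes 0
        p = float(2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean()))
        out = pd.concat([out, pd.DataFrame([{
            "parameter": "mediation_pct_diff", "diff": est,
            "se": float(np.std(diffs, ddof=1)), "p": min(max(p, 1.0 / len(diffs)), 1.0),
            "ci_low": float(lo), "ci_high": float(hi)}])], ignore_index=True)
    return out
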