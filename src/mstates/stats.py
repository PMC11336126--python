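"""Group comparisons, FDR, covariate-adjusted correlation, stepwise regression.

The statistical battery applied to the per-subject microstate metrics:

* chi-square test for sex-by-group contingency;
* per-variable two-group comparison, choosing an equal-variance t-test when
  Shapiro-Wilk accepts normality in both groups (alpha = 0.05) and a
  tie-corrected Mann-Whitney U (reported as a normal-approximation z)
  otherwise, with Benjamini-Hochberg FDR applied within declared variable
  families;
* partial rank correlation: x and y are rank-transformed (average ranks for
  ties), residualized on an intercept plus the covariates by least squares,
  and the Pearson correlation of the residuals is tested on
  n - n_covariates - 2 degrees of freedom;
* classic forward-entry / backward-removal stepwise linear regression on
  coefficient p-values (defaults 0.05 in / 0.10 out, the common statistical-
  package convention).

All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError

ALPHA_NORMALITY = 0.05


def chi_square_2x2(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table.

    Returns (chi2, p, df=1).  All row and column margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InvalidArgumentError("table must be 2x2 nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidArgumentError("all margins must be positive")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p), int(df)


def fdr_bh(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U as a tie-corrected normal-approximation z with two-sided p."""
    n1, n2 = len(x), len(y)
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        raise InvalidArgumentError("degenerate Mann-Whitney variance (all ties)")
    z = (u - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def compare_groups(
    metrics: pd.DataFrame,
    grouping: str = "group",
    variables: list[str] | None = None,
    families: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Two-group comparison of every variable, with FDR within families.

    For each variable: Shapiro-Wilk in both groups; both normal at
    alpha=0.05 -> equal-variance t-test; otherwise Mann-Whitney U (z).
    ``families`` maps a family label to its member columns; BH correction is
    applied within each family separately (unlisted variables form their own
    singleton families).  Returns a tidy StatTable DataFrame.
    """
    if grouping not in metrics.columns:
        raise InvalidArgumentError(f"no {grouping!r} column")
    levels = sorted(metrics[grouping].dropna().unique())
    if len(levels) != 2:
        raise InvalidArgumentError("grouping must have exactly two levels")
    g1, g2 = levels
    if variables is None:
        variables = [c for c in metrics.columns
                     if c != grouping and pd.api.types.is_numeric_dtype(metrics[c])]
    fam_of: dict[str, str] = {}
    if families:
        for fam, cols in families.items():
            for col in cols:
                fam_of[col] = fam

    rows = []
    for var in variables:
        x = metrics.loc[metrics[grouping] == g1, var].dropna().to_numpy(dtype=float)
        y = metrics.loc[metrics[grouping] == g2, var].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"{var}: fewer than 2 observations per group; skipped")
            continue
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            warnings.warn(f"{var}: constant in both groups; skipped")
            continue
        sw1 = sps.shapiro(x).pvalue if np.ptp(x) > 0 and len(x) >= 3 else 0.0
        sw2 = sps.shapiro(y).pvalue if np.ptp(y) > 0 and len(y) >= 3 else 0.0
        if sw1 > ALPHA_NORMALITY and sw2 > ALPHA_NORMALITY:
            res = sps.ttest_ind(x, y, equal_var=True)
            test, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            z, p = _mannwhitney_z(x, y)
            test, stat = "mannwhitney_z", z
        rows.append({
            "variable": var,
            f"mean_{g1}": x.mean(), f"sd_{g1}": x.std(ddof=1),
            f"mean_{g2}": y.mean(), f"sd_{g2}": y.std(ddof=1),
            "test": test, "statistic": stat,
            "shapiro_p_1": sw1, "shapiro_p_2": sw2,
            "p_raw": p,
            "family": fam_of.get(var, var),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_fdr"] = np.nan
    for fam in out["family"].unique():
        mask = out["family"] == fam
        out.loc[mask, "p_fdr"] = fdr_bh(out.loc[mask, "p_raw"].to_numpy())
    return out


@dataclass
class CorrelationResult:
    """Covariate-adjusted rank correlation."""

    rho: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_rank_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    covariate_names: tuple[str, ...] = (),
) -> CorrelationResult:
    """Spearman-style partial correlation of x and y given covariates.

    x and y are rank-transformed (average ranks for ties) and residualized
    on [1, covariates]; the Pearson correlation of the residuals is returned
    with a t-distributed p on n - n_covariates - 2 degrees of freedom.
    Rows with any missing value are dropped (complete cases).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            covariate_names = tuple(covariates.columns)
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if not (len(x) == len(y) == len(cov)):
        raise InvalidArgumentError("x, y and covariates must have equal length")
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[ok], y[ok], cov[ok]
    n, q = len(x), cov.shape[1]
    if n <= q + 2:
        raise InvalidArgumentError(f"need n > n_covariates + 2 (n={n}, q={q})")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n), cov])
    ex = _residualize(rx, design)
    ey = _residualize(ry, design)
    denom = np.sqrt(np.sum(ex**2) * np.sum(ey**2))
    if denom == 0:
        raise InvalidArgumentError("zero residual variance; correlation undefined")
    rho = float(np.clip(np.sum(ex * ey) / denom, -1.0, 1.0))
    df = n - q - 2
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(rho=rho, p=p, n=n, covariates=covariate_names)


@dataclass
class RegressionResult:
    """Stepwise linear model: retained terms and the selection trace."""

    selected: list[str]
    table: pd.DataFrame  # per term: coef, ci_low, ci_high, beta_std, t, p
    r2: float
    trace: list[tuple[str, str, float]]  # (action, variable, p at decision)


def stepwise_regression(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_iter: int = 100,
) -> RegressionResult:
    """Forward-entry / backward-removal stepwise OLS on coefficient p-values.

    At each step the excluded candidate with the smallest p below
    ``p_enter`` is added, then any included term with p above ``p_remove``
    is removed (largest first); iteration stops at a fixed point.  Near-
    collinear candidates (R^2 > 1 - 1e-8 on the included set) are never
    entered.  An empty model is a valid outcome, not an error.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise InvalidArgumentError("y and X must have equal length")
    ok = np.isfinite(y) & np.all(np.isfinite(X.to_numpy(dtype=float)), axis=1)
    y = y[ok]
    X = X.loc[ok].reset_index(drop=True)
    included: list[str] = []
    trace: list[tuple[str, str, float]] = []

    def _fit(cols: list[str]):
        design = sm.add_constant(X[cols].to_numpy(dtype=float)) if cols \
            else np.ones((len(y), 1))
        return sm.OLS(y, design).fit()

    def _collinear(cand: str) -> bool:
        if not included:
            return False
        d = sm.add_constant(X[included].to_numpy(dtype=float))
        v = X[cand].to_numpy(dtype=float)
        resid = v - d @ np.linalg.lstsq(d, v, rcond=None)[0]
        ss_tot = np.sum((v - v.mean()) ** 2)
        return ss_tot <= 0 or np.sum(resid**2) / ss_tot < 1e-8

    for _ in range(max_iter):
        changed = False
        candidates = [c for c in X.columns if c not in included]
        best_p, best_c = None, None
        for c in candidates:
            if X[c].std(ddof=0) == 0 or _collinear(c):
                continue
            fit = _fit(included + [c])
            p = fit.pvalues[-1]
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            trace.append(("add", best_c, float(best_p)))
            changed = True
        if included:
            fit = _fit(included)
            pvals = fit.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                removed = included.pop(worst)
                trace.append(("remove", removed, float(pvals[worst])))
                changed = True
        if not changed:
            break

    fit = _fit(included)
    if included:
        ci = fit.conf_int()
        sd_y = y.std(ddof=0)
        rows = []
        for i, name in enumerate(included, start=1):
            coef = fit.params[i]
            rows.append({
                "term": name,
                "coef": coef,
                "ci_low": ci[i, 0],
                "ci_high": ci[i, 1],
                "beta_std": coef * X[name].to_numpy(dtype=float).std(ddof=0) / sd_y,
                "t": fit.tvalues[i],
                "p": fit.pvalues[i],
            })
        table = pd.DataFrame(rows)
        r2 = float(fit.rsquared)
    else:
        table = pd.DataFrame(columns=["term", "coef", "ci_low", "ci_high",
                                      "beta_std", "t", "p"])
        r2 = 0.0
    return RegressionResult(selected=included, table=table, r2=r2, trace=trace)
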