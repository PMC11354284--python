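"""Cohort definitions and cohort-level statistics.

Covers the study's statistical toolkit: one-way least-squares means by breed
proportion / survival / lactation class (for a single fixed factor the LSM is
the plain class mean, with pooled-variance standard errors and unadjusted
pairwise t-tests), 95% bias-corrected bootstrap confidence intervals for mean
differences, Cronbach's alpha as a consistency measure across inbreeding
coefficients, and the Pearson correlation matrix of inbreeding coefficients.
No multiple-testing adjustment is applied (group letters in the source tables
are based on unadjusted p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import BS_CLASSES, LACT_GROUPS, SURV_TRAITS, CohortTable


def bs_class_of(proportion: float) -> str:
    """US Brown Swiss breed-proportion class (boundaries: <60, [60,70), ...)."""
    if not (0 <= proportion <= 100):
        raise ValueError(f"breed proportion {proportion} out of [0, 100]")
    if proportion < 60:
        return BS_CLASSES[0]
    if proportion >= 100:
        return BS_CLASSES[4]
    return BS_CLASSES[1 + int((proportion - 60) // 10)]


def _lact_group(n_lactations: int) -> str:
    if n_lactations <= 1:
        return "Lact1"
    if n_lactations <= 3:
        return "Lact2"
    if n_lactations <= 5:
        return "Lact4"
    if n_lactations <= 8:
        return "Lact6-8"
    if n_lactations <= 12:
        return "Lact9-12"
    return "Lact13-17"


def assign_cohorts(metadata: pd.DataFrame) -> CohortTable:
    """Deterministic cohort assignment from per-animal metadata.

    ``metadata`` columns: ``id``; ``us_bs_proportion`` (percent);
    ``n_calvings`` (number of calvings recorded); ``culled`` (bool; False =
    still in the herd, i.e. censored).

    Survival trait Surv_k (k = 1,3,5,7,9) is Yes (1) when the cow reached
    calving k+1, No (0) when she was culled before it, and missing when she
    is still alive but has not reached it yet.
    """
    t = metadata.copy()
    t["id"] = t["id"].astype(str)
    t["bs_class"] = t["us_bs_proportion"].map(bs_class_of)
    nc = t["n_calvings"].to_numpy()
    culled = t["culled"].to_numpy(dtype=bool)
    for k in (1, 3, 5, 7, 9):
        col = np.where(nc >= k + 1, 1.0, np.where(culled, 0.0, np.nan))
        t[f"Surv{k}"] = pd.array(col, dtype="Int64")
    t["lact_group"] = pd.Categorical(
        [_lact_group(int(v)) for v in nc], categories=LACT_GROUPS)
    cols = ["id", "us_bs_proportion", "bs_class", *SURV_TRAITS, "lact_group"]
    extra = [c for c in t.columns if c not in cols]
    return CohortTable(t[cols + extra])


@dataclass
class OneWayFit:
    """One-way fixed-effect fit: class means, SEs and pairwise tests."""

    response: str
    classes: list[str]
    lsm: pd.Series
    se: pd.Series
    n: pd.Series
    residual_variance: float
    pairwise_p: pd.DataFrame


def oneway_lsm(response: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
               response_name: str = "y") -> OneWayFit:
    """Least-squares means for y = mu + class_i + e.

    With one factor and no covariates the LSM equals the class mean; SEs use
    the pooled residual variance, and pairwise differences are tested with
    unadjusted t-tests on the residual degrees of freedom.
    """
    y = np.asarray(response, dtype=float)
    lab = pd.Series(labels).astype(str).to_numpy()
    ok = ~np.isnan(y)
    y, lab = y[ok], lab[ok]
    classes = sorted(pd.unique(lab))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    groups = {c: y[lab == c] for c in classes}
    n = pd.Series({c: len(v) for c, v in groups.items()})
    if (n == 0).any():
        raise ValueError("every class must be non-empty")
    means = pd.Series({c: v.mean() for c, v in groups.items()})
    df_res = len(y) - len(classes)
    if df_res > 0:
        ss_res = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        s2 = ss_res / df_res
    else:
        s2 = np.nan
    se = pd.Series({c: np.sqrt(s2 / n[c]) if n[c] > 1 or df_res > 0 else np.nan
                    for c in classes})
    pmat = pd.DataFrame(np.nan, index=classes, columns=classes)
    for a, b in combinations(classes, 2):
        tstat = (means[a] - means[b]) / np.sqrt(s2 * (1 / n[a] + 1 / n[b]))
        p = 2 * sps.t.sf(abs(tstat), df_res)
        pmat.loc[a, b] = pmat.loc[b, a] = p
    return OneWayFit(response_name, classes, means, se, n, float(s2), pmat)


def oneway_lsm_crossed(response, factor_a, factor_b, response_name: str = "y") -> OneWayFit:
    """Two-way interaction model (e.g. BS x Surv) realised as a cell-means
    one-way fit on the crossed factor."""
    crossed = (pd.Series(factor_a).astype(str) + " x "
               + pd.Series(factor_b).astype(str)).to_numpy()
    return oneway_lsm(response, crossed, response_name)


def bootstrap_bc_ci(values_a: np.ndarray, values_b: np.ndarray | None = None,
                    n_boot: int = 10_000, seed: int | None = None,
                    confidence: float = 0.95,
                    rng: np.random.Generator | None = None) -> tuple[float, float]:
    """95% bias-corrected (BC) bootstrap CI for the mean (difference).

    With two samples the statistic is ``mean(a) - mean(b)`` with independent
    resampling of each sample.  Degenerate resample distributions (all boot
    statistics identical) collapse the CI to a point.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    boot_a = rng.integers(0, a.size, size=(n_boot, a.size))
    thetas = a[boot_a].mean(axis=1)
    theta_hat = a.mean()
    if values_b is not None:
        b = np.asarray(values_b, dtype=float)
        if b.size == 0:
            raise ValueError("empty sample")
        boot_b = rng.integers(0, b.size, size=(n_boot, b.size))
        thetas = thetas - b[boot_b].mean(axis=1)
        theta_hat -= b.mean()
    if np.ptp(thetas) == 0:
        return (float(thetas[0]), float(thetas[0]))
    # bias correction: z0 from the fraction of bootstrap stats below the estimate
    prop = np.clip((thetas < theta_hat).mean(), 1.0 / n_boot, 1 - 1.0 / n_boot)
    z0 = sps.norm.ppf(prop)
    zcrit = sps.norm.ppf(1 - (1 - confidence) / 2)
    lo_q = sps.norm.cdf(2 * z0 - zcrit)
    hi_q = sps.norm.cdf(2 * z0 + zcrit)
    lo, hi = np.quantile(thetas, [lo_q, hi_q])
    return (float(lo), float(hi))


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / variance of sum)."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >=2 items and >=2 individuals")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def corr_matrix(profiles: pd.DataFrame,
                columns: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix (with p-values) of inbreeding coefficients.

    Returns (r, p); constant columns yield NaN entries (flagged by a warning
    from numpy suppressed here in favour of NaN).
    """
    cols = columns or [c for c in profiles.columns
                       if profiles[c].dtype.kind in "fc"]
    if len(profiles) < 3:
        raise ValueError("need at least 3 individuals")
    x = profiles[cols]
    r = x.corr(method="pearson")
    n = len(x)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        rv = r.loc[a, b]
        if np.isnan(rv) or abs(rv) >= 1:
            pv = np.nan if np.isnan(rv) else 0.0
        else:
            t = rv * np.sqrt((n - 2) / (1 - rv ** 2))
            pv = 2 * sps.t.sf(abs(t), n - 2)
        p.loc[a, b] = p.loc[b, a] = pv
    np.fill_diagonal(p.values, 0.0)
    return r, p


def normality_diagnostic(values: np.ndarray) -> tuple[float, float]:
    """Optional a-priori distribution check (Shapiro-Wilk W and p)."""
    w, p = sps.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)
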