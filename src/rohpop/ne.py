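"""Effective population size (Ne) by three routes.

1. **LD decay** (Sved): for SNP pairs binned by distance,
   ``Ne = (1 - r^2) / (4 c r^2)`` with c the recombination distance in
   Morgans (100 Mb = 1 Morgan by default), probing ancestral generation
   ``t = round(1 / (2c))``; multiple bins mapping to one t are averaged and
   the per-generation rate of inbreeding is ``dF = 1 / (2 Ne)``.
2. **F_ROH with generation equivalents**: a minimum ROH length of L Mb
   probes ``GE = 100 / (2 L)`` generations (1 cM = 1 Mb), and
   ``dF = 1 - (1 - F_ROH)^(1/(GE-1))``, ``Ne = 1 / (2 dF)``.
3. **Regression on time**: OLS slope b of ``ln(1 - F_ROH)`` on birth year
   gives ``dF_yr = 1 - exp(b)`` and ``Ne_reg = 1 / (2 L dF_yr)`` with L the
   generation interval in years; the 95% CI uses b +/- 1.96 SE_b.

r^2 is the squared Pearson correlation of genotype dosages (composite LD,
appropriate for unphased data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MISSING, GenotypeMatrix

MORGANS_PER_MB = 0.01  # study convention: 100 Mb = 1 Morgan


def pairwise_r2_binned(g: GenotypeMatrix, max_dist_mb: float = 33.3,
                       bin_width_mb: float = 0.1) -> pd.DataFrame:
    """Mean r^2 of intra-chromosomal SNP pairs per distance bin.

    Bins cover (0, max_dist_mb] with the given width.  Monomorphic SNPs are
    skipped (their pair count is reported in ``.attrs['n_monomorphic']``).
    Missing calls are mean-imputed per marker before correlation.
    """
    n_bins = int(np.ceil(max_dist_mb / bin_width_mb))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_mono_pairs = 0
    max_bp = max_dist_mb * 1e6
    for chrom in g.marker_map.chromosomes:
        cidx = g.marker_map.chrom_indices(chrom)
        if cidx.size < 2:
            continue
        pos = g.marker_map.table["pos"].to_numpy()[cidx].astype(np.float64)
        x = g.calls[:, cidx].astype(np.float64)
        miss = x == MISSING
        if miss.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.where(miss, np.nan, x).mean(axis=0, where=~miss)
            x[miss] = np.take(col_mean, np.where(miss)[1])
        sd = x.std(axis=0)
        poly = sd > 0
        z = np.zeros_like(x)
        z[:, poly] = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]
        n_ind, m = x.shape
        for k in range(1, m):
            d = pos[k:] - pos[:-k]
            within = d <= max_bp
            if not within.any():
                break
            r = (z[:, :-k] * z[:, k:]).sum(axis=0) / n_ind
            pair_poly = poly[:-k] & poly[k:]
            use = within & pair_poly
            n_mono_pairs += int((within & ~pair_poly).sum())
            if not use.any():
                continue
            b = np.minimum((np.ceil(d[use] / (bin_width_mb * 1e6)) - 1).astype(int),
                           n_bins - 1)
            np.add.at(sums, b, (r[use] ** 2))
            np.add.at(counts, b, 1)
    mid = (np.arange(n_bins) + 0.5) * bin_width_mb
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({
        "bin_left_mb": np.arange(n_bins) * bin_width_mb,
        "bin_mid_mb": mid,
        "bin_right_mb": (np.arange(n_bins) + 1) * bin_width_mb,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })
    out.attrs["n_monomorphic"] = n_mono_pairs
    return out


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def ne_from_ld(bins: pd.DataFrame, morgans_per_mb: float = MORGANS_PER_MB,
               use_midpoint: bool = True) -> pd.DataFrame:
    """Ne curve per ancestral generation from binned LD.

    ``c`` is the bin representative distance (midpoint by default) converted
    to Morgans; ``Ne = (1 - r2)/(4 c r2)``; ``t = round(1/(2c))`` half-up;
    bins sharing a t are averaged; ``dF = 1/(2 Ne)``.  Bins with r2 == 0 or
    no pairs are dropped (flagged in ``.attrs``); r2 == 1 yields Ne = 0
    (degenerate).
    """
    b = bins[bins["n_pairs"] > 0].copy()
    dist = b["bin_mid_mb"] if use_midpoint else b["bin_left_mb"]
    c = dist.to_numpy() * morgans_per_mb
    r2 = b["mean_r2"].to_numpy()
    zero_r2 = int((r2 == 0).sum())
    keep = (r2 > 0) & (c > 0)
    c, r2 = c[keep], r2[keep]
    npairs = b["n_pairs"].to_numpy()[keep]
    ne = (1.0 - r2) / (4.0 * c * r2)
    t = _round_half_up(1.0 / (2.0 * c))
    df = pd.DataFrame({"t": t, "c_morgan": c, "mean_r2": r2, "Ne": ne,
                       "n_pairs": npairs})
    df = df[df["t"] >= 1]
    out = df.groupby("t").agg(
        mean_r2=("mean_r2", "mean"), c_morgan=("c_morgan", "mean"),
        Ne=("Ne", "mean"), n_pairs=("n_pairs", "sum"),
    ).reset_index()
    with np.errstate(divide="ignore"):
        out["delta_F"] = 1.0 / (2.0 * out["Ne"])
    out.attrs["n_zero_r2_bins"] = zero_r2
    return out


def generation_equivalents(min_length_mb: float) -> float:
    """Ancestral generations probed by ROH of at least ``min_length_mb``:
    GE = 100 / (2 L) under 1 cM = 1 Mb (e.g. 4 Mb -> 12.5)."""
    if min_length_mb <= 0:
        raise ValueError("min_length_mb must be positive")
    return 100.0 / (2.0 * min_length_mb)


@dataclass
class NeRohEstimate:
    """Ne from a mean F_ROH and its generation equivalents."""

    source: str
    generation_equivalents: float
    delta_f: float
    ne: float


def ne_from_froh(f: float, ge: float, source: str = "F_ROH") -> NeRohEstimate:
    """Ne from mean F_ROH: dF = 1 - (1-F)^(1/(GE-1)); Ne = 1/(2 dF).

    F = 0 implies an infinite Ne (returned as ``inf``).
    """
    if not (0 <= f < 1):
        raise ValueError("F must be in [0, 1)")
    if ge <= 1:
        raise ValueError("generation equivalents must exceed 1")
    if f == 0:
        return NeRohEstimate(source, ge, 0.0, float("inf"))
    delta = 1.0 - (1.0 - f) ** (1.0 / (ge - 1.0))
    return NeRohEstimate(source, ge, delta, 1.0 / (2.0 * delta))


@dataclass
class NeRegEstimate:
    """Ne from the temporal trend of ln(1 - F_ROH)."""

    slope: float
    slope_se: float
    delta_f_yr: float
    generation_interval_years: float
    ne: float
    ci_low: float
    ci_high: float


def ne_from_regression(froh: np.ndarray, birth_year: np.ndarray,
                       generation_interval_years: float = 6.5) -> NeRegEstimate:
    """OLS of ln(1 - F_ROH) on birth year; dF_yr = 1 - exp(b);
    Ne_reg = 1/(2 L dF_yr) with 95% CI from b +/- 1.96 SE_b.

    A non-negative slope (no inbreeding trend) yields dF_yr <= 0 and the Ne
    point estimate is flagged ``inf`` (no finite effective size).
    """
    f = np.asarray(froh, dtype=float)
    yr = np.asarray(birth_year, dtype=float)
    if len(np.unique(yr)) < 2:
        raise ValueError("need at least 2 distinct birth years")
    y = np.log(1.0 - f)
    fit = sm.OLS(y, sm.add_constant(yr)).fit()
    b = float(fit.params[1])
    se = float(fit.bse[1])
    d = 1.0 - np.exp(b)
    L = generation_interval_years

    def _ne(delta: float) -> float:
        return 1.0 / (2.0 * L * delta) if delta > 0 else float("inf")

    lo_d = 1.0 - np.exp(b + 1.96 * se)
    hi_d = 1.0 - np.exp(b - 1.96 * se)
    bounds = sorted((_ne(lo_d), _ne(hi_d)))
    return NeRegEstimate(b, se, d, L, _ne(d), bounds[0], bounds[1])
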