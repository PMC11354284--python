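"""Genomic inbreeding coefficients from ROH segments and genotype homozygosity.

``F_ROH`` is the proportion of the SNP-covered autosomal genome lying inside
runs of homozygosity: ``F_ROH = sum(L_ROH) / L_AUTO``.  Thresholded variants
``F_ROH>L`` count only segments strictly longer than L Mb and reflect
progressively more recent inbreeding.

``F_IS`` is the per-individual excess of observed over Hardy-Weinberg-expected
homozygous genotypes, ``(O_i - E_i) / (n_SNP,i - E_i)``, with
``E_i = sum_j (1 - 2 p_j (1 - p_j))`` over the markers genotyped in i.
Allele frequencies default to sample frequencies of the analyzed cohort
(computed from non-missing calls) but can be supplied externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

#: Thresholds (Mb) of the standard F_ROH variants.
FROH_THRESHOLDS_MB = [0.0, 4.0, 8.0, 16.0, 32.0]
FROH_LABELS = ["F_ROH", "F_ROH>4", "F_ROH>8", "F_ROH>16", "F_ROH>32"]


def f_roh(segments: pd.DataFrame, l_auto_bp: int, min_length_mb: float = 0.0) -> float:
    """F_ROH for one individual's segment table.

    Sums lengths (bp) of segments strictly longer than ``min_length_mb`` and
    divides by ``l_auto_bp``.
    """
    if l_auto_bp <= 0:
        raise ValueError("L_AUTO must be positive")
    if len(segments) == 0:
        return 0.0
    length_bp = (segments["end_bp"] - segments["start_bp"] + 1).to_numpy(dtype=np.int64)
    keep = segments["length_kb"].to_numpy() / 1000.0 > min_length_mb
    return float(length_bp[keep].sum() / l_auto_bp)


def froh_profile(segments: pd.DataFrame, individuals: list[str],
                 l_auto_bp: int) -> pd.DataFrame:
    """Per-individual F_ROH and its thresholded variants (>4/8/16/32 Mb).

    The untresholded column uses every detected segment (detection already
    enforces the calibrated minimum length).
    """
    out = pd.DataFrame({"individual": individuals})
    by_ind = dict(tuple(segments.groupby("individual"))) if len(segments) else {}
    empty = segments.iloc[0:0]
    for label, thr in zip(FROH_LABELS, FROH_THRESHOLDS_MB):
        out[label] = [
            f_roh(by_ind.get(ind, empty), l_auto_bp, min_length_mb=thr)
            for ind in individuals
        ]
    out.attrs["l_auto_bp"] = int(l_auto_bp)
    return out


@dataclass
class FisValue:
    """Observed/expected homozygosity and the resulting F_IS for one animal."""

    individual: str
    observed_hom: int
    expected_hom: float
    n_snp: int
    f_is: float


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Sample frequency of the designated allele per marker (non-missing calls)."""
    calls = g.calls.astype(float)
    calls[g.calls == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    return p


def f_is(g: GenotypeMatrix, individual: str,
         frequencies: np.ndarray | None = None) -> FisValue:
    """Excess-of-homozygosity F_IS = (O_i - E_i) / (n_SNP,i - E_i).

    Markers missing in the individual are excluded from O, E and n alike.
    """
    p = allele_frequencies(g) if frequencies is None else np.asarray(frequencies, float)
    i = g.individual_index(individual)
    calls = g.calls[i]
    ok = calls != MISSING
    if not ok.any():
        raise ValueError(f"all markers missing for individual {individual!r}")
    n = int(ok.sum())
    o = int(((calls == 0) | (calls == 2))[ok].sum())
    pj = p[ok]
    e = float(np.sum(1.0 - 2.0 * pj * (1.0 - pj)))
    return FisValue(individual, o, e, n, (o - e) / (n - e))


def f_is_all(g: GenotypeMatrix, frequencies: np.ndarray | None = None) -> pd.DataFrame:
    """Vectorised F_IS for every individual in the cohort."""
    p = allele_frequencies(g) if frequencies is None else np.asarray(frequencies, float)
    ok = g.calls != MISSING
    hom = ((g.calls == 0) | (g.calls == 2)) & ok
    e_term = 1.0 - 2.0 * p * (1.0 - p)
    o = hom.sum(axis=1)
    n = ok.sum(axis=1)
    e = ok @ np.nan_to_num(e_term)
    return pd.DataFrame({
        "individual": g.individuals,
        "observed_hom": o,
        "expected_hom": e,
        "n_snp": n,
        "F_IS": (o - e) / (n - e),
    })


def cumulative_froh_curve(segments: pd.DataFrame, l_auto_bp: int,
                          cutoffs_mb: np.ndarray) -> np.ndarray:
    """F_ROH contributed by segments of length <= cutoff, per cutoff.

    Non-decreasing in the cutoff; the right endpoint (cutoff -> inf) equals
    the unthresholded F_ROH.
    """
    cutoffs = np.asarray(cutoffs_mb, dtype=float)
    if len(segments) == 0:
        return np.zeros_like(cutoffs)
    mb = segments["length_kb"].to_numpy() / 1000.0
    bp = (segments["end_bp"] - segments["start_bp"] + 1).to_numpy(dtype=np.int64)
    order = np.argsort(mb)
    mb_sorted, bp_sorted = mb[order], bp[order]
    csum = np.concatenate(([0], np.cumsum(bp_sorted)))
    k = np.searchsorted(mb_sorted, cutoffs, side="right")
    return csum[k] / l_auto_bp


def merge_profiles(froh: pd.DataFrame, fis: pd.DataFrame,
                   pedigree_coeffs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join the genomic (and optionally pedigree) coefficients into one
    per-individual inbreeding profile table."""
    out = froh.merge(fis[["individual", "F_IS"]], on="individual", how="left")
    if pedigree_coeffs is not None:
        cols = [c for c in pedigree_coeffs.columns
                if c == "individual" or not c.endswith("_se")]
        out = out.merge(pedigree_coeffs[cols], on="individual", how="left")
    return out
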