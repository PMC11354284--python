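"""Sliding-window detection of runs of homozygosity (ROH).

The scanner reimplements the PLINK 1.9 ``--homozyg`` sliding-window logic on a
:class:`~rohpop.io.GenotypeMatrix`:

1. every contiguous window of ``window_snp`` SNPs on a chromosome is a *hit*
   iff it contains at most ``window_het`` heterozygous and ``window_missing``
   missing calls;
2. each SNP's hit rate is the fraction of windows containing it that are
   hits; a SNP is run-eligible iff its hit rate >= ``hit_threshold``;
3. maximal stretches of consecutive run-eligible SNPs are split wherever
   adjacent SNPs are more than ``max_gap_kb`` apart;
4. stretches failing the minimum SNP count, minimum length or maximum
   kb-per-SNP density bound are discarded.

The minimum SNP count is calibrated against chance runs of homozygosity with
the false-positive formula of Lencz et al.:
``l = ln(alpha / (n_s * n_i)) / ln(1 - het)``, and the minimum length is the
SNP density times that count.

Final segments may contain heterozygous calls admitted by the window
smoothing; no per-segment heterozygote cap is applied unless requested
(``segment_het``), matching the study parameterisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Column order of the segment table (mirrors PLINK's .hom fields).
SEGMENT_COLUMNS = ["individual", "chrom", "start_bp", "end_bp", "n_snp", "length_kb"]

#: ROH length classes in Mb: <=4, >4-8, >8-16, >16-32, >32 (upper edge inclusive).
LENGTH_CLASS_EDGES_MB = [4.0, 8.0, 16.0, 32.0]
LENGTH_CLASS_LABELS = ["<=4", ">4-8", ">8-16", ">16-32", ">32"]


@dataclass
class LenczInputs:
    """Inputs to the false-positive minimum-SNP calibration."""

    alpha: float      # tolerated proportion of false-positive ROH, in (0, 1]
    n_s: int          # number of SNPs
    n_i: int          # number of individuals
    het: float        # mean SNP heterozygosity, in (0, 1)

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.n_s < 1 or self.n_i < 1:
            raise ValueError("n_s and n_i must be >= 1")
        if not (0 < self.het < 1):
            raise ValueError("het must be strictly inside (0, 1)")


def lencz_min_snps(inputs: LenczInputs) -> int:
    """Minimum number of SNPs per ROH so that at most ``alpha`` ROH are
    expected to be identical-by-state artifacts: ceil of
    ``ln(alpha/(n_s n_i)) / ln(1 - het)``."""
    l = math.log(inputs.alpha / (inputs.n_s * inputs.n_i)) / math.log(1.0 - inputs.het)
    return max(0, math.ceil(l))


def calibrate_params(g: GenotypeMatrix, alpha: float = 0.05,
                     **overrides) -> ROHParams:
    """ROH parameters calibrated to the cohort at hand.

    Computes the mean SNP heterozygosity of the cohort, derives the minimum
    SNP count from the false-positive formula (``lencz_min_snps``), sets the
    minimum length to that count times the observed SNP density, and leaves
    the remaining parameters at their defaults (overridable by keyword).
    """
    from .io import snp_density  # deferred: io does not depend on roh

    ok = g.calls != MISSING
    het = float(((g.calls == 1) & ok).sum() / ok.sum())
    n_s = g.n_markers
    n_i = g.n_individuals
    min_snp = lencz_min_snps(LenczInputs(alpha, n_s, n_i, het))
    density = snp_density(g.marker_map)
    min_length = min_length_from_density(min_snp, density)
    kwargs = dict(min_snp=min_snp, min_length_kb=float(min_length))
    kwargs.update(overrides)
    return ROHParams(**kwargs)


def min_length_from_density(min_snp: int, density_kb: float) -> int:
    """Minimum ROH length in kb: floor(min_snp * density); 64 x 49.86 -> 3191."""
    if min_snp <= 0 or density_kb <= 0:
        raise ValueError("min_snp and density must be positive")
    return math.floor(min_snp * density_kb)


@dataclass
class ROHParams:
    """Scanner parameters; defaults are the study's PLINK settings."""

    window_snp: int = 15
    window_het: int = 1
    window_missing: int = 0
    hit_threshold: float = 0.05   # PLINK --homozyg-window-threshold default
    min_snp: int = 64
    min_length_kb: float = 3191.0
    max_gap_kb: float = 500.0
    max_kb_per_snp: float = 100.0  # PLINK --homozyg-density semantics
    segment_het: int | None = None  # optional post-hoc per-segment het cap

    def __post_init__(self) -> None:
        for name in ("window_snp", "min_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hit_threshold", "min_length_kb", "max_gap_kb", "max_kb_per_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_het < 0 or self.window_missing < 0:
            raise ValueError("window_het and window_missing must be >= 0")
        if self.hit_threshold > 1:
            raise ValueError("hit_threshold must be <= 1")


def _eligible_snps(calls: np.ndarray, p: ROHParams) -> np.ndarray:
    """Boolean run-eligibility per SNP on one chromosome for one individual."""
    m = calls.shape[0]
    w = p.window_snp
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    kern = np.ones(w, dtype=np.int32)
    hw = np.convolve(het, kern, mode="valid")
    mw = np.convolve(mis, kern, mode="valid")
    hit = (hw <= p.window_het) & (mw <= p.window_missing)
    n_windows = m - w + 1
    chit = np.concatenate(([0], np.cumsum(hit)))
    j = np.arange(m)
    lo = np.maximum(j - w + 1, 0)
    hi = np.minimum(j, n_windows - 1)
    n_containing = hi - lo + 1
    n_hits = chit[hi + 1] - chit[lo]
    return n_hits / n_containing >= p.hit_threshold


def _runs_to_segments(eligible: np.ndarray, pos: np.ndarray, calls: np.ndarray,
                      p: ROHParams) -> list[tuple[int, int, int]]:
    """Maximal eligible stretches, gap-split and filtered.

    Returns (start_idx, end_idx inclusive, n_snp) triples.
    """
    out = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return out
    # break where SNPs are non-consecutive in the map or > max_gap_kb apart
    gap_bp = p.max_gap_kb * 1000.0
    brk = (np.diff(idx) != 1) | (np.diff(pos[idx]) > gap_bp)
    pieces = np.split(idx, np.flatnonzero(brk) + 1)
    for piece in pieces:
        n = piece.size
        if n < p.min_snp:
            continue
        start, end = int(pos[piece[0]]), int(pos[piece[-1]])
        length_kb = (end - start + 1) / 1000.0
        if length_kb < p.min_length_kb:
            continue
        if length_kb / n > p.max_kb_per_snp:
            continue
        if p.segment_het is not None:
            if int((calls[piece[0]: piece[-1] + 1] == 1).sum()) > p.segment_het:
                continue
        out.append((int(piece[0]), int(piece[-1]), n))
    return out


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect runs of homozygosity for every individual.

    Returns a DataFrame with columns ``individual, chrom, start_bp, end_bp,
    n_snp, length_kb``, sorted by (individual, chrom, start).
    """
    p = params or ROHParams()
    rows = []
    short_chroms: set[int] = set()
    for chrom in g.marker_map.chromosomes:
        cidx = g.marker_map.chrom_indices(chrom)
        pos = g.marker_map.table["pos"].to_numpy()[cidx]
        if cidx.size < p.window_snp:
            short_chroms.add(int(chrom))
            continue
        sub = g.calls[:, cidx]
        for i, ind in enumerate(g.individuals):
            calls = sub[i]
            eligible = _eligible_snps(calls, p)
            for s, e, n in _runs_to_segments(eligible, pos, calls, p):
                start, end = int(pos[s]), int(pos[e])
                rows.append((ind, int(chrom), start, end, n, (end - start + 1) / 1000.0))
    if short_chroms:
        logger.warning(
            "chromosome(s) %s have fewer SNPs than the window size; no ROH called there",
            sorted(short_chroms),
        )
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    order = pd.Index(g.individuals)
    seg["_i"] = seg["individual"].map({v: k for k, v in enumerate(order)})
    seg = seg.sort_values(["_i", "chrom", "start_bp"]).drop(columns="_i")
    return seg.reset_index(drop=True)


def classify_lengths(segments: pd.DataFrame) -> pd.DataFrame:
    """Count and total length of segments per length class.

    Classes (Mb): <=4, >4-8, >8-16, >16-32, >32; a segment of exactly 8 Mb
    falls in >4-8 (upper edge inclusive).
    """
    mb = segments["length_kb"].to_numpy() / 1000.0
    edges = [0.0] + LENGTH_CLASS_EDGES_MB + [np.inf]
    cls = pd.cut(mb, bins=edges, labels=LENGTH_CLASS_LABELS, right=True,
                 include_lowest=True)
    out = pd.DataFrame({"length_class": pd.Categorical(cls, LENGTH_CLASS_LABELS),
                        "length_mb": mb})
    res = out.groupby("length_class", observed=False).agg(
        n=("length_mb", "size"), total_length_mb=("length_mb", "sum")
    ).reset_index()
    return res


def per_individual_summary(segments: pd.DataFrame,
                           individuals: list[str]) -> pd.DataFrame:
    """Per-individual ROH count, mean length (Mb; NaN when no ROH) and
    combined length (Mb)."""
    grp = segments.groupby("individual")["length_kb"]
    n = grp.size()
    total = grp.sum() / 1000.0
    mean = grp.mean() / 1000.0
    out = pd.DataFrame({"individual": individuals})
    out["n_roh"] = out["individual"].map(n).fillna(0).astype(int)
    out["mean_length_mb"] = out["individual"].map(mean)  # NaN flags 0-ROH animals
    out["combined_length_mb"] = out["individual"].map(total).fillna(0.0)
    return out


def segments_to_hom(segments: pd.DataFrame, g: GenotypeMatrix) -> pd.DataFrame:
    """PLINK .hom-style table (IID, CHR, SNP1, SNP2, POS1, POS2, KB, NSNP, DENSITY)."""
    t = g.marker_map.table
    lookup = {(c, p): s for c, p, s in zip(t["chrom"], t["pos"], t["id"])}
    out = pd.DataFrame({
        "IID": segments["individual"],
        "CHR": segments["chrom"],
        "SNP1": [lookup.get((c, p), ".") for c, p in
                 zip(segments["chrom"], segments["start_bp"])],
        "SNP2": [lookup.get((c, p), ".") for c, p in
                 zip(segments["chrom"], segments["end_bp"])],
        "POS1": segments["start_bp"],
        "POS2": segments["end_bp"],
        "KB": segments["length_kb"],
        "NSNP": segments["n_snp"],
        "DENSITY": segments["length_kb"] / segments["n_snp"],
    })
    return out


def segments_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """BED (0-based half-open) export of segments."""
    return pd.DataFrame({
        "chrom": segments["chrom"],
        "start": segments["start_bp"] - 1,
        "end": segments["end_bp"],
        "name": segments["individual"],
    })
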