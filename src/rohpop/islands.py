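"""ROH incidence, percentile-threshold ROH islands and consensus ROH.

The per-SNP *incidence* is the fraction of individuals whose ROH cover the
SNP.  *ROH islands* are contiguous runs of SNPs whose incidence strictly
exceeds a high percentile (99th or 95th) of the genome-wide incidence
distribution — footprints of directional selection.  *Consensus ROH* are runs
of SNPs covered in at least a fixed fraction (30/40/50%) of the animals.
Runs are never merged across chromosomes; member SNPs further apart than
``max_gap_kb`` start a new region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable, GenotypeMatrix

logger = logging.getLogger(__name__)

ISLAND_COLUMNS = ["chrom", "start_bp", "end_bp", "n_snp", "peak_incidence"]


@dataclass
class IncidenceTrack:
    """Per-SNP ROH incidence for a set of individuals."""

    table: pd.DataFrame  # chrom, pos, incidence
    n_individuals: int


def incidence_track(segments: pd.DataFrame, g: GenotypeMatrix,
                    individuals: list[str] | None = None) -> IncidenceTrack:
    """Fraction of individuals with >=1 ROH covering each map SNP."""
    subset = list(g.individuals) if individuals is None else list(individuals)
    if not subset:
        raise ValueError("individual subset must be non-empty")
    t = g.marker_map.table
    count = np.zeros(len(t), dtype=np.int64)
    seg = segments[segments["individual"].isin(subset)]
    pos_by_chrom = {c: (g.marker_map.chrom_indices(c), g.marker_map.positions(c))
                    for c in g.marker_map.chromosomes}
    for ind, sub in seg.groupby("individual"):
        covered = np.zeros(len(t), dtype=bool)
        for row in sub.itertuples():
            cidx, pos = pos_by_chrom[row.chrom]
            i0 = np.searchsorted(pos, row.start_bp, side="left")
            i1 = np.searchsorted(pos, row.end_bp, side="right")
            covered[cidx[i0:i1]] = True
        count += covered
    out = pd.DataFrame({"chrom": t["chrom"], "pos": t["pos"],
                        "incidence": count / len(subset)})
    return IncidenceTrack(out, len(subset))


def _members_to_regions(track: pd.DataFrame, member: np.ndarray,
                        max_gap_kb: float) -> pd.DataFrame:
    rows = []
    chrom = track["chrom"].to_numpy()
    pos = track["pos"].to_numpy()
    inc = track["incidence"].to_numpy()
    idx = np.flatnonzero(member)
    if idx.size:
        brk = (np.diff(chrom[idx]) != 0) | (np.diff(pos[idx]) > max_gap_kb * 1000.0)
        for piece in np.split(idx, np.flatnonzero(brk) + 1):
            rows.append((int(chrom[piece[0]]), int(pos[piece[0]]),
                         int(pos[piece[-1]]), int(piece.size),
                         float(inc[piece].max())))
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def call_islands(track: IncidenceTrack, percentile: float = 99,
                 max_gap_kb: float = 500.0) -> pd.DataFrame:
    """ROH islands: runs of SNPs with incidence strictly above the given
    percentile of the genome-wide incidence distribution.

    The percentile is computed over all autosomal SNPs with linear
    interpolation; a degenerate (all-equal) distribution therefore yields no
    islands.
    """
    inc = track.table["incidence"].to_numpy()
    thr = float(np.percentile(inc, percentile))
    out = _members_to_regions(track.table, inc > thr, max_gap_kb)
    out.attrs["threshold"] = thr
    out.attrs["percentile"] = percentile
    return out


def call_consensus(track: IncidenceTrack, sharing: float,
                   max_gap_kb: float = 500.0) -> pd.DataFrame:
    """Consensus ROH: runs of SNPs covered in at least ``sharing`` of the
    animals (inclusive threshold)."""
    if not (0 < sharing <= 1):
        raise ValueError("sharing must be in (0, 1]")
    inc = track.table["incidence"].to_numpy()
    out = _members_to_regions(track.table, inc >= sharing, max_gap_kb)
    out.attrs["sharing"] = sharing
    return out


def stratified_islands(segments: pd.DataFrame, g: GenotypeMatrix,
                       cohorts: CohortTable, stratify_by: str,
                       percentile: float = 99, max_gap_kb: float = 500.0,
                       min_stratum_size: int = 10) -> dict[str, pd.DataFrame]:
    """Islands recomputed independently within each stratum of a cohort
    column (e.g. ``bs_class`` or a survival trait)."""
    ct = cohorts.table
    out = {}
    for level, sub in ct.groupby(stratify_by, observed=True, dropna=True):
        members = [i for i in sub["id"] if i in g.individuals]
        if not members:
            continue
        if len(members) < min_stratum_size:
            logger.warning("stratum %r has only %d genotyped animal(s)",
                           level, len(members))
        track = incidence_track(segments, g, members)
        out[str(level)] = call_islands(track, percentile, max_gap_kb)
    return out


def track_to_bedgraph(track: IncidenceTrack, path) -> None:
    """Write the incidence track as bedGraph (0-based half-open, one SNP per line)."""
    t = track.table
    with open(path, "w") as fh:
        for row in t.itertuples():
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{row.incidence:.6g}\n")


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """Write island/consensus regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in regions.itertuples():
            fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\n")
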