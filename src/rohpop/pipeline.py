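"""End-to-end analysis driver chaining all stages.

``run_pipeline`` takes a :class:`RunConfig` (whose defaults are exactly the
study parameterisation: 3191-kb / 64-SNP minimum ROH, 100 kb/SNP density
bound, 500-kb gap, 15-SNP windows with <=1 heterozygote and 0 missing,
0.1-Mb LD bins to 33.3 Mb, L = 6.5 years, island percentiles 95/99 and
consensus sharing 30/40/50%) and writes per-stage TSV outputs plus a JSON
manifest echoing the effective parameters and seed.  Runs are idempotent
given the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inbreeding import FROH_LABELS, FROH_THRESHOLDS_MB, f_is_all, froh_profile, merge_profiles
from .io import (GenotypeMatrix, Pedigree, autosome_length, read_genotypes,
                 read_pedigree, snp_density, write_cohorts, write_ped_map,
                 write_pedigree)
from .islands import call_consensus, call_islands, incidence_track, track_to_bedgraph
from .ne import (generation_equivalents, ne_from_froh, ne_from_ld,
                 ne_from_regression, pairwise_r2_binned)
from .pedigree import f_ped, gene_drop_coefficients
from .roh import ROHParams, classify_lengths, detect_roh, per_individual_summary, segments_to_hom
from .stats import cronbach_alpha, corr_matrix, oneway_lsm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study settings."""

    genotypes: str | None = None
    dialect: str = "ped_map"
    pedigree: str | None = None
    cohorts: str | None = None
    out_dir: str = "results/run"
    seed: int = 1
    roh: ROHParams = field(default_factory=ROHParams)
    lencz_alpha: float = 0.05
    ld_max_dist_mb: float = 33.3
    ld_bin_width_mb: float = 0.1
    morgans_per_mb: float = 0.01
    generation_interval_years: float = 6.5
    island_percentiles: tuple = (99, 95)
    consensus_sharing: tuple = (0.30, 0.40, 0.50)
    gene_drop_replicates: int = 100_000
    log_level: str = "INFO"


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig, genotypes: GenotypeMatrix | None = None,
                 pedigree: Pedigree | None = None,
                 cohorts=None) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON).

    Inputs may be given as paths in the config or as in-memory objects.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genotypes is None:
        if config.genotypes is None:
            raise ValueError("no genotype input configured")
        genotypes = read_genotypes(config.genotypes, config.dialect)
    if pedigree is None and config.pedigree:
        pedigree = read_pedigree(config.pedigree)

    manifest = {
        "tool": "rohpop",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            **dataclasses.asdict(config.roh),
            "lencz_alpha": config.lencz_alpha,
            "ld_max_dist_mb": config.ld_max_dist_mb,
            "ld_bin_width_mb": config.ld_bin_width_mb,
            "morgans_per_mb": config.morgans_per_mb,
            "generation_interval_years": config.generation_interval_years,
            "island_percentiles": list(config.island_percentiles),
            "consensus_sharing": list(config.consensus_sharing),
        },
        "outputs": {},
    }

    def save(key: str, df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"][key] = str(path)

    l_auto = autosome_length(genotypes.marker_map)
    density = snp_density(genotypes.marker_map)
    manifest["l_auto_bp"] = l_auto
    manifest["snp_density_kb"] = density

    # 1. ROH detection
    segments = _stage("roh")(detect_roh)(genotypes, config.roh)
    save("segments", segments_to_hom(segments, genotypes), "roh_segments.tsv")
    save("roh_length_classes", classify_lengths(segments), "roh_length_classes.tsv")
    save("roh_per_individual",
         per_individual_summary(segments, genotypes.individuals),
         "roh_per_individual.tsv")

    # 2. genomic inbreeding
    froh = _stage("inbreeding")(froh_profile)(segments, genotypes.individuals, l_auto)
    fis = f_is_all(genotypes)
    ped_coef = None
    if pedigree is not None:
        gd = _stage("pedigree_inbreeding")(gene_drop_coefficients)(
            pedigree, config.gene_drop_replicates, seed=config.seed)
        coef = gd.coefficients
        coef.insert(1, "F_PED", f_ped(pedigree).reindex(coef["individual"]).to_numpy())
        save("pedigree_coefficients", coef, "pedigree_coefficients.tsv")
        ped_coef = coef
    profiles = merge_profiles(froh, fis, ped_coef)
    save("inbreeding_profiles", profiles, "inbreeding_profiles.tsv")

    # 3. effective population size
    bins = _stage("ne")(pairwise_r2_binned)(
        genotypes, config.ld_max_dist_mb, config.ld_bin_width_mb)
    save("ld_bins", bins, "ld_bins.tsv")
    save("ne_ld", ne_from_ld(bins, config.morgans_per_mb), "ne_by_generation.tsv")
    ne_roh_rows = []
    for label, thr in zip(FROH_LABELS, FROH_THRESHOLDS_MB):
        min_len = thr if thr > 0 else config.roh.min_length_kb / 1000.0
        ge = generation_equivalents(min_len)
        mean_f = float(froh[label].mean())
        if 0 < mean_f < 1:
            est = ne_from_froh(mean_f, ge, source=label)
            ne_roh_rows.append((label, mean_f, ge, est.delta_f, est.ne))
        else:
            ne_roh_rows.append((label, mean_f, ge, np.nan, np.nan))
    save("ne_roh", pd.DataFrame(
        ne_roh_rows, columns=["source", "mean_F", "GE", "delta_F", "Ne"]), "ne_roh.tsv")
    if pedigree is not None and pedigree.table["birth_year"].notna().sum() >= 2:
        yr = pedigree.table.set_index("id")["birth_year"]
        years = yr.reindex(froh["individual"]).astype(float).to_numpy()
        okyr = ~np.isnan(years)
        if len(np.unique(years[okyr])) >= 2:
            reg = ne_from_regression(froh["F_ROH"].to_numpy()[okyr], years[okyr],
                                     config.generation_interval_years)
            save("ne_regression", pd.DataFrame([dataclasses.asdict(reg)]),
                 "ne_regression.tsv")

    # 4. islands and consensus
    track = _stage("islands")(incidence_track)(segments, genotypes)
    track_to_bedgraph(track, out / "roh_incidence.bedgraph")
    manifest["outputs"]["incidence_track"] = str(out / "roh_incidence.bedgraph")
    def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        nonempty = [f for f in frames if len(f)]
        return pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]

    island_frames = []
    for pct in config.island_percentiles:
        isl = call_islands(track, pct, config.roh.max_gap_kb)
        isl.insert(0, "percentile", pct)
        island_frames.append(isl)
    save("islands", _concat(island_frames), "roh_islands.tsv")
    cons_frames = []
    for sh in config.consensus_sharing:
        cons = call_consensus(track, sh, config.roh.max_gap_kb)
        cons.insert(0, "sharing", sh)
        cons_frames.append(cons)
    save("consensus", _concat(cons_frames), "consensus_roh.tsv")

    # 5. cohort statistics
    if cohorts is not None:
        ct = cohorts.table.merge(profiles, left_on="id", right_on="individual")
        if len(ct) and ct["bs_class"].nunique() >= 2:
            fit = oneway_lsm(ct["F_ROH"], ct["bs_class"], "F_ROH")
            lsm = pd.DataFrame({"bs_class": fit.classes,
                                "n": fit.n.values,
                                "lsm_F_ROH": fit.lsm.values,
                                "se": fit.se.values})
            save("lsm_by_bs_class", lsm, "lsm_by_bs_class.tsv")
        gen_cols = [c for c in ("F_IS", *FROH_LABELS) if c in ct.columns]
        if len(ct) >= 2 and len(gen_cols) >= 2:
            alpha = cronbach_alpha(ct[gen_cols])
            manifest["cronbach_alpha"] = alpha
        if len(ct) >= 3:
            r, p = corr_matrix(ct, [c for c in ct.columns if c in
                                    ("F_PED", "F_IS", *FROH_LABELS,
                                     "F_a_Kal", "F_New", "F_a_Bal", "Ahc")])
            save("correlations", r.reset_index(), "inbreeding_correlations.tsv")
        write_cohorts(cohorts, out / "cohorts.tsv")
        manifest["outputs"]["cohorts"] = str(out / "cohorts.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def simulate_inputs(out_dir: str, seed: int, **sim_kwargs) -> dict:
    """Generate a synthetic cohort and write its files (PED/MAP, pedigree
    TSV, cohort TSV, truth TSV) for consumption by the other subcommands."""
    from .sim import SimConfig, simulate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed, **sim_kwargs)
    sim = simulate_cohort(config)
    write_ped_map(sim.genotypes, out / "synthetic")
    write_pedigree(sim.pedigree, out / "pedigree.tsv")
    write_cohorts(sim.cohorts, out / "cohorts.tsv")
    sim.true_ibd.to_csv(out / "true_ibd_segments.tsv", sep="\t", index=False)
    return {"prefix": str(out / "synthetic"),
            "pedigree": str(out / "pedigree.tsv"),
            "cohorts": str(out / "cohorts.tsv"),
            "true_ibd": str(out / "true_ibd_segments.tsv")}
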