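"""Shared synthetic study cohort for the numbered analysis scripts.

Each script rebuilds the same cohort deterministically from a fixed seed
(cheaper and more reproducible than shipping multi-megabyte genotype files):
a 4-generation random-mating population of 150 animals per generation from
30 founders, genotyped for everyone, on 10 autosomes of 100 Mb with one SNP
per 50 kb, and survival outcomes that depend negatively on inbreeding.
"""

from pathlib import Path

from rohpop.sim import SimConfig, simulate_cohort

SEED = 20240809
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def get_cohort():
    cfg = SimConfig(seed=SEED, n_founders=30, n_generations=4,
                    n_per_generation=150, n_chromosomes=10,
                    chrom_length_mb=100.0, n_snps_per_chrom=2000)
    return simulate_cohort(cfg, outcome_effect=-12.0, genotype_all=True)


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
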