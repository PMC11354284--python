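import numpy as np
import pandas as pd
import pytest

from rohpop.io import GenotypeMatrix, MarkerMap, Pedigree


def make_map(positions_by_chrom: dict[int, list[int]]) -> MarkerMap:
    rows = []
    for c, positions in sorted(positions_by_chrom.items()):
        for k, p in enumerate(positions):
            rows.append((c, p, f"snp{c}_{k}", "A", "C"))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id", "a1", "a2"]))


def make_genotypes(calls, positions_by_chrom=None, spacing_bp=50_000) -> GenotypeMatrix:
    """Genotype matrix from an array; default map = one chromosome, uniform grid."""
    calls = np.asarray(calls, dtype=np.int8)
    if positions_by_chrom is None:
        positions_by_chrom = {1: [1 + k * spacing_bp for k in range(calls.shape[1])]}
    mm = make_map(positions_by_chrom)
    inds = [f"ind{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(inds, calls, mm)


def random_pedigree(rng: np.random.Generator, n_founders: int = 6,
                    n_extra: int = 24) -> Pedigree:
    """Random overlapping-mating pedigree: each new animal picks two distinct
    earlier animals (or unknowns) as parents — loops arise naturally."""
    ids = [f"A{k}" for k in range(n_founders)]
    rows = [(i, "0", "0", 2000) for i in ids]
    for k in range(n_extra):
        a, b = rng.choice(len(ids), size=2, replace=False)
        iid = f"A{n_founders + k}"
        rows.append((iid, ids[a], ids[b], 2001 + k))
        ids.append(iid)
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "birth_year"]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240809)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort reused across test modules."""
    from rohpop.sim import SimConfig, simulate_cohort

    cfg = SimConfig(seed=77, n_founders=20, n_per_generation=60, n_generations=4,
                    n_chromosomes=6, chrom_length_mb=50.0, n_snps_per_chrom=1000)
    return simulate_cohort(cfg, outcome_effect=-8.0)
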