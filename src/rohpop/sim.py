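"""Synthetic pedigree + genotype generator with known ground truth.

The generator emulates the structure of a genotyped livestock cohort: a
multi-generation pedigree, founder haplotypes with given allele frequencies,
recombination during meiosis (Poisson crossover counts at the configured
Morgan length, uniform placement — Haldane model, no interference), and the
resulting genotypes.  Because every transmitted chromosome is tracked as a
mosaic of founder haplotypes, the *true* IBD segments (regions where an
individual's two gametes descend from the same founder allele copy) and the
exact pedigree inbreeding are known, so ROH detection and the inbreeding
coefficients can be validated without any external data.

Defaults describe a small closed nucleus population: 40 founders, 5 discrete
generations of 200 offspring under random mating, 29 autosomes of 100 Mb
with one SNP per 50 kb (the study's marker density), founder minor-allele
frequencies uniform on [0.05, 0.5], 1 cM = 1 Mb, and no genotyping error or
missingness unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap, Pedigree
from .stats import assign_cohorts


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort."""

    n_founders: int = 40
    n_generations: int = 5
    n_per_generation: int = 200
    mating: str = "random"          # random | circular | full_sib_line
    n_chromosomes: int = 29
    chrom_length_mb: float = 100.0
    n_snps_per_chrom: int = 2000
    maf_low: float = 0.05           # founder MAF ~ Uniform(maf_low, maf_high)
    maf_high: float = 0.5
    morgans_per_mb: float = 0.01    # 100 Mb = 1 Morgan
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    birth_year_start: int = 1990
    generation_interval_years: float = 6.5
    seed: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("n_founders", "n_generations", "n_per_generation",
                     "n_chromosomes", "n_snps_per_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("genotyping_error_rate", "missing_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mating not in ("random", "circular", "full_sib_line"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        if self.mating == "full_sib_line" and self.n_founders < 2:
            raise ValueError("full-sib line needs at least 2 founders")

    @property
    def chrom_length_bp(self) -> int:
        return int(self.chrom_length_mb * 1e6)


def simulate_pedigree(config: SimConfig,
                      rng: np.random.Generator | None = None) -> Pedigree:
    """Generation-stamped pedigree under the configured mating scheme.

    Sexes alternate within each generation so both sexes are always present.
    Birth years advance by the generation interval (rounded to whole years).
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []

    def year(gen: int) -> int:
        return config.birth_year_start + round(gen * config.generation_interval_years)

    if config.mating == "full_sib_line":
        founders = ["G0_0", "G0_1"]
        rows += [(founders[0], "0", "0", year(0), "M", 0),
                 (founders[1], "0", "0", year(0), "F", 0)]
        sire, dam = founders
        for g in range(1, config.n_generations + 1):
            a, b = f"G{g}_0", f"G{g}_1"
            rows += [(a, sire, dam, year(g), "M", g),
                     (b, sire, dam, year(g), "F", g)]
            sire, dam = a, b
    else:
        prev = []
        for k in range(config.n_founders):
            iid = f"G0_{k}"
            sex = "M" if k % 2 == 0 else "F"
            rows.append((iid, "0", "0", year(0), sex, 0))
            prev.append((iid, sex))
        for g in range(1, config.n_generations + 1):
            males = [i for i, s in prev if s == "M"]
            females = [i for i, s in prev if s == "F"]
            cur = []
            if config.mating == "circular":
                n_off = len(prev)
                for k in range(n_off):
                    sire = males[k % len(males)]
                    dam = females[(k + 1) % len(females)]
                    iid = f"G{g}_{k}"
                    sex = "M" if k % 2 == 0 else "F"
                    rows.append((iid, sire, dam, year(g), sex, g))
                    cur.append((iid, sex))
            else:  # random mating
                for k in range(config.n_per_generation):
                    sire = males[rng.integers(len(males))]
                    dam = females[rng.integers(len(females))]
                    iid = f"G{g}_{k}"
                    sex = "M" if k % 2 == 0 else "F"
                    rows.append((iid, sire, dam, year(g), sex, g))
                    cur.append((iid, sex))
            prev = cur
    t = pd.DataFrame(rows, columns=["id", "sire", "dam", "birth_year", "sex",
                                    "generation"])
    return Pedigree(t)


# A gamete on one chromosome: mosaic of founder haplotypes as
# (ends, haps) -- piece j covers the half-open bp interval
# [ends[j-1], ends[j]) (ends[-1] == chromosome length) with founder
# haplotype id haps[j].

def _slice_gamete(ends: np.ndarray, haps: np.ndarray, lo: int, hi: int):
    i0 = int(np.searchsorted(ends, lo, side="right"))
    i1 = int(np.searchsorted(ends, hi, side="left"))
    return np.append(ends[i0:i1], hi), haps[i0:i1 + 1]


def _compact(ends: np.ndarray, haps: np.ndarray):
    keep = np.append(haps[:-1] != haps[1:], True)
    return ends[keep], haps[keep]


def _meiosis(gametes, len_bp: int, len_morgan: float, rng: np.random.Generator):
    n_cross = rng.poisson(len_morgan)
    phase = int(rng.integers(2))
    if n_cross == 0:
        return gametes[phase]
    cuts = np.unique(rng.integers(1, len_bp, size=n_cross))
    bounds = np.concatenate(([0], cuts, [len_bp]))
    ends_out: list[np.ndarray] = []
    haps_out: list[np.ndarray] = []
    for k in range(len(bounds) - 1):
        ends, haps = gametes[(phase + k) % 2]
        e, h = _slice_gamete(ends, haps, int(bounds[k]), int(bounds[k + 1]))
        ends_out.append(e)
        haps_out.append(h)
    return _compact(np.concatenate(ends_out), np.concatenate(haps_out))


def _ibd_segments(g1, g2, min_bp: int = 1):
    """Maximal intervals where the two gametes carry the same founder hap."""
    e1, h1 = g1
    e2, h2 = g2
    ends = np.union1d(e1, e2)
    i1 = np.searchsorted(e1, ends, side="left")
    i2 = np.searchsorted(e2, ends, side="left")
    same = h1[i1] == h2[i2]
    out = []
    start = 0
    k = 0
    while k < len(ends):
        if same[k]:
            j = k
            while j + 1 < len(ends) and same[j + 1]:
                j += 1
            lo = 0 if k == 0 else int(ends[k - 1])
            hi = int(ends[j])
            if hi - lo >= min_bp:
                out.append((lo + 1, hi))  # 1-based inclusive
            k = j + 1
        else:
            k += 1
    return out


def _make_map(config: SimConfig) -> MarkerMap:
    rows = []
    spacing = config.chrom_length_bp / config.n_snps_per_chrom
    for c in range(1, config.n_chromosomes + 1):
        for j in range(config.n_snps_per_chrom):
            pos = int(spacing * (j + 0.5)) + 1
            rows.append((c, pos, f"snp{c}_{j}", "A", "C"))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id", "a1", "a2"]))


def gene_drop_genotypes(ped: Pedigree, config: SimConfig,
                        individuals: list[str] | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop founder haplotypes through the pedigree with recombination.

    Returns the genotype matrix for ``individuals`` (default: every animal)
    and the table of true IBD segments (columns ``individual, chrom,
    start_bp, end_bp``) for those individuals.  Optional genotyping error
    (a call replaced by a uniform draw from the other two states) and
    missingness are applied after the truth is recorded.
    """
    rng = rng or np.random.default_rng(config.seed)
    marker_map = _make_map(config)
    order = ped.topological_order()
    targets = list(ped.ids) if individuals is None else list(individuals)
    target_set = set(targets)
    t = ped.table.set_index("id")
    len_bp = config.chrom_length_bp
    len_morgan = config.chrom_length_mb * config.morgans_per_mb

    # founder haplotype pool: one fresh haplotype per unknown-parent gamete
    n_unknown_sides = int((t[["sire", "dam"]] == "0").to_numpy().sum())
    maf = rng.uniform(config.maf_low, config.maf_high,
                      size=(config.n_chromosomes, config.n_snps_per_chrom))
    founder_haps = (
        rng.random((config.n_chromosomes, n_unknown_sides, config.n_snps_per_chrom))
        < maf[:, None, :]
    ).astype(np.int8)

    pos_per_chrom = [marker_map.positions(c) for c in range(1, config.n_chromosomes + 1)]
    state: dict[str, list] = {}
    next_hap = [0]
    calls = np.zeros((len(targets), marker_map.n_markers), dtype=np.int8)
    row_of = {ind: i for i, ind in enumerate(targets)}
    ibd_rows = []
    whole = np.array([len_bp], dtype=np.int64)

    for a in order:
        row = t.loc[a]
        pair = []
        for parent in (row["sire"], row["dam"]):
            if parent == "0":
                hap = next_hap[0]
                next_hap[0] += 1
                gam = [(whole, np.array([hap])) for _ in range(config.n_chromosomes)]
            else:
                pg = state[parent]
                gam = [_meiosis(pg[c], len_bp, len_morgan, rng)
                       for c in range(config.n_chromosomes)]
            pair.append(gam)
        state[a] = list(zip(pair[0], pair[1]))
        if a in target_set:
            i = row_of[a]
            off = 0
            for c in range(config.n_chromosomes):
                pos = pos_per_chrom[c]
                dose = np.zeros(config.n_snps_per_chrom, dtype=np.int8)
                for ends, haps in (pair[0][c], pair[1][c]):
                    lo = 0
                    for e, h in zip(ends, haps):
                        j0 = np.searchsorted(pos, lo, side="right")
                        j1 = np.searchsorted(pos, e, side="right")
                        dose[j0:j1] += founder_haps[c, h, j0:j1]
                        lo = e
                calls[i, off:off + config.n_snps_per_chrom] = dose
                off += config.n_snps_per_chrom
                for s, e in _ibd_segments(pair[0][c], pair[1][c]):
                    ibd_rows.append((a, c + 1, s, e))

    if config.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls[err] = (calls[err] + shift[err]) % 3
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    g = GenotypeMatrix(targets, calls, marker_map)
    ibd = pd.DataFrame(ibd_rows, columns=["individual", "chrom", "start_bp", "end_bp"])
    return g, ibd


def attach_outcomes(ped: Pedigree, inbreeding: pd.Series, effect_size: float = 0.0,
                    seed: int | None = None, base_survival: float = 0.8,
                    censor_rate: float = 0.15, max_lactations: int = 17,
                    rng: np.random.Generator | None = None):
    """Binary survival outcomes with an optional logistic dependence on
    inbreeding.

    Each cow's per-lactation probability of continuing to the next calving is
    ``expit(logit(base_survival) + effect_size * F)``; a negative effect makes
    more-inbred cows leave the herd earlier.  ``effect_size = 0`` decouples
    survival from inbreeding.  A ``censor_rate`` fraction of cows is still
    alive (culled = False), giving missing survival indicators beyond their
    current lactation.  Breed proportions are drawn to mimic the study cohort
    (normal with mean 73.8, SD 10.4, clipped to [19, 98]).
    """
    from scipy.special import expit, logit

    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    ids = ped.ids
    f = inbreeding.reindex(ids).fillna(0.0).to_numpy()
    p_cont = expit(logit(base_survival) + effect_size * f)
    n_calv = np.ones(len(ids), dtype=int)
    alive = np.ones(len(ids), dtype=bool)
    for _ in range(max_lactations - 1):
        cont = rng.random(len(ids)) < p_cont
        n_calv += alive & cont
        alive &= cont
    culled = rng.random(len(ids)) >= censor_rate
    bs = np.clip(rng.normal(73.8, 10.4, size=len(ids)), 19, 98)
    meta = pd.DataFrame({
        "id": ids,
        "us_bs_proportion": bs,
        "n_calvings": n_calv,
        "culled": culled,
    })
    return assign_cohorts(meta)


@dataclass
class SimResult:
    """Bundle of one synthetic cohort."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    true_ibd: pd.DataFrame
    cohorts: object  # CohortTable


def simulate_cohort(config: SimConfig, outcome_effect: float = 0.0,
                    genotype_all: bool = False) -> SimResult:
    """End-to-end synthetic cohort: pedigree, genotypes of the final
    generation (or everyone), true IBD segments and cohort metadata."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    if genotype_all:
        targets = None
    else:
        gen = ped.table["generation"]
        targets = ped.table.loc[gen == gen.max(), "id"].tolist()
    g, ibd = gene_drop_genotypes(ped, config, individuals=targets, rng=rng)
    from .pedigree import f_ped

    cohorts = attach_outcomes(ped, f_ped(ped), effect_size=outcome_effect, rng=rng)
    return SimResult(config, ped, g, ibd, cohorts)
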