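"""Domain types and file I/O for genotype, marker-map, pedigree and cohort data.

Conventions used throughout the package:

* Coordinates are 1-based inclusive base pairs (PLINK convention); segment
  lengths are ``end - start + 1`` and reported in kb or Mb.
* Genotype calls count copies of the *designated* allele of each marker
  (the alphabetically second of the two observed alleles for PED input, the
  ALT allele for VCF input); homozygosity calls are invariant to this choice.
* Missing calls are the sentinel :data:`MISSING` (``-1``), distinct from
  {0, 1, 2}.  PED ``0 0`` and VCF ``./.`` both map to it.
* Only autosomes are retained; non-numeric chromosome labels (X, Y, MT, ...)
  and chromosome 0 are dropped with a warning.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING = np.int8(-1)

_NON_AUTOSOME_LABELS = {"X", "Y", "XY", "MT", "M", "0"}


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered autosomal SNP map.

    ``table`` has columns ``chrom`` (int), ``pos`` (1-based bp, int),
    ``id`` (str), ``a1``/``a2`` (single-character allele codes; ``a2`` is the
    designated/counted allele).  Markers must be strictly sorted by
    (chrom, pos) with no duplicate positions per chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"chrom", "pos", "id", "a1", "a2"}
        if not required.issubset(t.columns):
            raise ValueError(f"MarkerMap table needs columns {sorted(required)}")
        if (t["pos"] <= 0).any():
            bad = t.loc[t["pos"] <= 0, "id"].iloc[0]
            raise ValueError(f"non-positive position at marker {bad!r}")
        key = t["chrom"].to_numpy() * np.int64(2**40) + t["pos"].to_numpy()
        if not np.all(np.diff(key) > 0):
            i = int(np.argmax(np.diff(key) <= 0)) + 1
            raise ValueError(
                f"map not strictly sorted by (chrom, pos) at marker {t['id'].iloc[i]!r}"
            )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.table["chrom"].to_numpy())

    def positions(self, chrom: int) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def chrom_indices(self, chrom: int) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())


def autosome_length(marker_map: MarkerMap) -> int:
    """Total autosomal length covered by SNPs, in bp.

    Sum over chromosomes of (last SNP position − first SNP position).  This
    span-sum convention reproduces the study value 2,477,795,166 bp for the
    49,693-SNP cattle map.
    """
    g = marker_map.table.groupby("chrom")["pos"]
    return int((g.max() - g.min()).sum())


def snp_density(marker_map: MarkerMap) -> float:
    """Average SNP density in kb per SNP: autosome_length / n_markers / 1000."""
    if marker_map.n_markers < 2:
        raise ValueError("snp_density needs at least 2 markers")
    return autosome_length(marker_map) / marker_map.n_markers / 1000.0


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for a cohort, aligned to a :class:`MarkerMap`.

    ``calls`` is an int8 array of shape (n_individuals, n_markers) with values
    in {0, 1, 2, MISSING} counting copies of the designated allele.
    """

    individuals: list[str]
    calls: np.ndarray
    marker_map: MarkerMap = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), self.marker_map.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {self.marker_map.n_markers} markers"
            )
        ok = np.isin(self.calls, [0, 1, 2, MISSING])
        if not ok.all():
            raise ValueError("genotype calls must be in {0,1,2,missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.marker_map.n_markers

    def missing_rate(self) -> np.ndarray:
        """Per-marker missing rate in [0, 1]."""
        return (self.calls == MISSING).mean(axis=0)

    def individual_index(self, individual: str) -> int:
        return self.individuals.index(individual)


def _filter_autosomes(map_df: pd.DataFrame, calls: np.ndarray | None):
    """Drop non-autosomal markers; returns (map_df, calls, n_dropped)."""
    lab = map_df["chrom"].astype(str).str.upper()
    is_num = lab.str.fullmatch(r"\d+")
    keep = (is_num & (lab != "0")).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d non-autosomal marker(s)", n_drop)
    out = map_df.loc[keep].copy()
    out["chrom"] = out["chrom"].astype(int)
    if calls is not None:
        calls = calls[:, keep]
    return out, calls, n_drop


# ---------------------------------------------------------------------------
# PED/MAP dialect
# ---------------------------------------------------------------------------

def _read_map_file(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] not in (3, 4):
        raise ValueError(f"{path}: MAP file must have 3 or 4 columns")
    if df.shape[1] == 3:  # chrom, id, pos (no cM column)
        df.columns = ["chrom", "id", "pos"]
    else:
        df.columns = ["chrom", "id", "cm", "pos"]
    df["pos"] = df["pos"].astype(np.int64)
    return df[["chrom", "id", "pos"]]


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_df = _read_map_file(prefix.with_suffix(".map"))
    m = len(map_df)
    ped = pd.read_csv(prefix.with_suffix(".ped"), sep=r"\s+", header=None, dtype=str)
    if ped.shape[1] != 6 + 2 * m:
        raise ValueError(
            f"{prefix}.ped has {ped.shape[1]} columns; expected {6 + 2 * m} "
            f"for {m} markers in {prefix}.map"
        )
    individuals = ped[1].tolist()
    al = ped.iloc[:, 6:].to_numpy(dtype="U1").reshape(len(individuals), m, 2)
    # observed alleles per marker; '0' means missing
    a1 = np.empty(m, dtype="U1")
    a2 = np.empty(m, dtype="U1")
    calls = np.full((len(individuals), m), MISSING, dtype=np.int8)
    for j in range(m):
        obs = np.unique(al[:, j, :])
        obs = obs[obs != "0"]
        if len(obs) > 2:
            raise ValueError(f"non-biallelic marker {map_df['id'].iloc[j]!r}")
        if len(obs) == 0:
            a1[j] = a2[j] = "0"
            continue
        # designated (counted) allele = alphabetically second
        a1[j] = obs[0]
        a2[j] = obs[-1]
        pair = al[:, j, :]
        miss = (pair == "0").any(axis=1)
        calls[:, j] = (pair == a2[j]).sum(axis=1).astype(np.int8)
        calls[miss, j] = MISSING
    map_df = map_df.assign(a1=a1, a2=a2)
    map_df, calls, _ = _filter_autosomes(map_df, calls)
    order = np.lexsort((map_df["pos"].to_numpy(), map_df["chrom"].to_numpy()))
    if not np.all(order == np.arange(len(map_df))):
        raise ValueError("MAP file is not sorted by (chrom, pos)")
    return GenotypeMatrix(individuals, calls, MarkerMap(map_df))


def write_ped_map(g: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    t = g.marker_map.table
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in t.itertuples():
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\n")
    a1 = t["a1"].to_numpy()
    a2 = t["a2"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(g.individuals):
            row = g.calls[i]
            pairs = np.empty((len(row), 2), dtype="U1")
            pairs[row == 0] = np.stack([a1[row == 0]] * 2, axis=1)
            pairs[row == 1] = np.stack([a1[row == 1], a2[row == 1]], axis=1)
            pairs[row == 2] = np.stack([a2[row == 2]] * 2, axis=1)
            pairs[row == MISSING] = "0"
            geno = " ".join(" ".join(p) for p in pairs)
            fh.write(f"FAM {ind} 0 0 0 -9 {geno}\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM dialect (PLINK 1.9 binary, SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of a2:  00=hom a1, 01=missing, 10=het, 11=hom a2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _read_bed_bim_fam(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    bim["pos"] = bim["pos"].astype(np.int64)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    individuals = fam[1].tolist()
    n, m = len(individuals), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK .bed file")
    bpm = (n + 3) // 4  # bytes per marker
    body = raw[3:]
    if len(body) != bpm * m:
        raise ValueError(
            f"{prefix}.bed size mismatch: {len(body)} bytes for {m} markers x {n} individuals"
        )
    body = body.reshape(m, bpm)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts) & 0b11  # (m, bpm, 4)
    codes = codes.reshape(m, bpm * 4)[:, :n]
    calls = _BED_DECODE[codes].T.copy()  # (n, m)
    map_df = bim[["chrom", "id", "pos", "a1", "a2"]].copy()
    map_df, calls, _ = _filter_autosomes(map_df, calls)
    return GenotypeMatrix(individuals, calls, MarkerMap(map_df))


def write_bed_bim_fam(g: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    t = g.marker_map.table
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in t.itertuples():
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for ind in g.individuals:
            fh.write(f"FAM {ind} 0 0 0 -9\n")
    n, m = g.calls.shape
    enc = np.zeros_like(g.calls, dtype=np.uint8)
    for dose, code in _BED_ENCODE.items():
        enc[g.calls == dose] = code
    bpm = (n + 3) // 4
    padded = np.zeros((m, bpm * 4), dtype=np.uint8)
    padded[:, :n] = enc.T
    packed = (
        padded.reshape(m, bpm, 4) << (np.arange(4, dtype=np.uint8) * 2)
    ).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    rows, chroms, poss, ids, a1s, a2s = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"non-biallelic SNP at {var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 = dosage ALT, 3 = missing
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        a1s.append(var.REF)
        a2s.append(var.ALT[0])
    calls = np.stack(rows, axis=1) if rows else np.zeros((len(individuals), 0), np.int8)
    map_df = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "id": ids,
         "a1": a1s, "a2": a2s}
    )
    map_df, calls, _ = _filter_autosomes(map_df, calls)
    return GenotypeMatrix(individuals, calls, MarkerMap(map_df))


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    t = g.marker_map.table
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(t["chrom"])):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individuals) + "\n")
        for j, row in enumerate(t.itertuples()):
            ref = row.a1 if row.a1 not in ("0", row.a2) else ("A" if row.a2 != "A" else "C")
            gts = "\t".join(gt_str[int(v)] for v in g.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{ref}\t{row.a2}\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes(path: str | Path, dialect: str = "ped_map") -> GenotypeMatrix:
    """Read genotypes from one of the supported dialects.

    Parameters
    ----------
    path:
        For ``ped_map`` / ``bed_bim_fam``, the file-set prefix (with or
        without extension); for ``vcf``, the VCF path.
    dialect:
        One of ``{"ped_map", "bed_bim_fam", "vcf"}``.
    """
    path = Path(path)
    if dialect in ("ped_map", "bed_bim_fam") and path.suffix in (
        ".ped", ".map", ".bed", ".bim", ".fam"
    ):
        path = path.with_suffix("")
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "bed_bim_fam":
        return _read_bed_bim_fam(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Parent records with birth years.

    ``table`` columns: ``id``, ``sire``, ``dam`` (string ids, ``"0"``/None =
    unknown), ``birth_year`` (nullable int).  Validated to be acyclic, with
    referenced parents present, and parents born before offspring where years
    are known.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        for col in ("id", "sire", "dam"):
            t[col] = t[col].astype(str)
        t.loc[t["sire"].isin(("0", "nan", "None", "")), "sire"] = "0"
        t.loc[t["dam"].isin(("0", "nan", "None", "")), "dam"] = "0"
        if "birth_year" not in t.columns:
            t["birth_year"] = pd.NA
        t["birth_year"] = t["birth_year"].astype("Int64")
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate animal id {dup!r}")
        known = set(t["id"])
        for col in ("sire", "dam"):
            missing = set(t[col]) - known - {"0"}
            if missing:
                raise ValueError(f"{col} id(s) not in pedigree: {sorted(missing)[:5]}")
        # acyclicity + topological order
        ts = graphlib.TopologicalSorter()
        for row in t.itertuples():
            preds = [p for p in (row.sire, row.dam) if p != "0"]
            ts.add(row.id, *preds)
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as e:
            raise ValueError(f"pedigree contains a cycle: {e.args[1]}") from None
        by = dict(zip(t["id"], t["birth_year"]))
        for row in t.itertuples():
            for p in (row.sire, row.dam):
                if p != "0" and pd.notna(by.get(p)) and pd.notna(row.birth_year):
                    if by[p] >= row.birth_year:
                        raise ValueError(
                            f"parent {p!r} not born before offspring {row.id!r}"
                        )
        self.table = t
        self._topological = order

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def topological_order(self) -> list[str]:
        """Animal ids ordered so that parents precede offspring."""
        return list(self._topological)

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["id"] == animal].iloc[0]
        return (None if row["sire"] == "0" else row["sire"],
                None if row["dam"] == "0" else row["dam"])


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 4-column TSV pedigree (id, sire, dam, birth_year; 0 = unknown)."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    t.columns = [c.lower() for c in t.columns]
    if "birth_year" in t.columns:
        t["birth_year"] = pd.to_numeric(t["birth_year"], errors="coerce").replace(0, pd.NA)
    return Pedigree(t)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    out = ped.table[["id", "sire", "dam", "birth_year"]].copy()
    out["birth_year"] = out["birth_year"].fillna(0)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------

BS_CLASSES = ["<60", "60-69", "70-79", "80-89", "90-99"]
SURV_TRAITS = ["Surv1", "Surv3", "Surv5", "Surv7", "Surv9"]
LACT_GROUPS = ["Lact1", "Lact2", "Lact4", "Lact6-8", "Lact9-12", "Lact13-17"]


@dataclass
class CohortTable:
    """Per-animal cohort metadata.

    ``table`` columns: ``id``, ``us_bs_proportion`` (percent in [0, 100]),
    ``bs_class``, ``Surv1``..``Surv9`` (1/0/NA), ``lact_group``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        p = t["us_bs_proportion"]
        if ((p < 0) | (p > 100)).any():
            raise ValueError("us_bs_proportion out of [0, 100]")
        from .stats import bs_class_of  # local import to avoid a cycle

        expect = p.map(bs_class_of)
        if not (t["bs_class"] == expect).all():
            bad = t.loc[t["bs_class"] != expect, "id"].iloc[0]
            raise ValueError(f"bs_class inconsistent with us_bs_proportion for {bad!r}")
        # monotone survival: surviving lactation k implies surviving all j < k,
        # i.e. no known 0 followed by a known 1 (NA comparisons are skipped)
        surv = t[SURV_TRAITS].to_numpy(dtype=float)
        seen_zero = np.cumsum(surv == 0, axis=1) > 0
        if ((surv == 1) & seen_zero).any():
            raise ValueError("survival indicators are not monotone")
        self.table = t


def read_cohorts(path: str | Path) -> CohortTable:
    t = pd.read_csv(path, sep="\t", dtype={"id": str})
    for c in SURV_TRAITS:
        t[c] = pd.to_numeric(t[c], errors="coerce").astype("Int64")
    return CohortTable(t)


def write_cohorts(cohorts: CohortTable, path: str | Path) -> None:
    cohorts.table.to_csv(path, sep="\t", index=False)
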