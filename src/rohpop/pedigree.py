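"""Classical and ancestral inbreeding coefficients from pedigree.

``f_ped`` computes Wright's inbreeding coefficient exactly via the tabular
kinship recursion (phi(x, y) = average kinship of x's parents with y;
F(x) = phi(sire, dam)).

``gene_drop_coefficients`` estimates the ancestral coefficients by
Monte-Carlo gene dropping of a single abstract locus: per replicate, each
founder receives two unique alleles which are transmitted with fair Mendelian
sampling down the pedigree.  At each animal the replicate contributes to

* ``F_PED`` - the two gametes carry copies of the same founder allele
  (autozygous);
* ``F_a_Kal`` - autozygous *and* the allele had already been autozygous in an
  ancestor (Kalinowski's ancestral inbreeding);
* ``F_New`` - autozygous for the first time; by construction
  ``F_New + F_a_Kal = F_PED`` holds exactly per replicate;
* ``F_a_Bal`` - probability that a random allele of the animal has been
  autozygous in at least one ancestor (Ballou);
* ``Ahc`` - expected number of ancestral generations in which a random allele
  has been autozygous (Baumung's ancestral history coefficient).

Unknown parents are treated as unique unrelated founders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Pedigree


def f_ped(ped: Pedigree) -> pd.Series:
    """Exact classical inbreeding coefficient per animal (founders: 0)."""
    order = ped.topological_order()
    idx = {a: k for k, a in enumerate(order)}
    n = len(order)
    t = ped.table.set_index("id")
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for a in order:
        row = t.loc[a]
        if row["sire"] != "0":
            sire[idx[a]] = idx[row["sire"]]
        if row["dam"] != "0":
            dam[idx[a]] = idx[row["dam"]]
    phi = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        phi_sd = phi[s, d] if (s >= 0 and d >= 0) else 0.0
        phi[i, i] = 0.5 * (1.0 + phi_sd)
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * phi[s, j]
            if d >= 0:
                v += 0.5 * phi[d, j]
            phi[i, j] = phi[j, i] = v
    f = np.array([
        phi[sire[i], dam[i]] if (sire[i] >= 0 and dam[i] >= 0) else 0.0
        for i in range(n)
    ])
    return pd.Series(f, index=order, name="F_PED").loc[ped.ids]


@dataclass
class GeneDropResult:
    """Per-animal coefficient table plus the replicate count used."""

    coefficients: pd.DataFrame
    n_replicates: int


def gene_drop_coefficients(ped: Pedigree, n_replicates: int = 100_000,
                           seed: int | None = None,
                           rng: np.random.Generator | None = None) -> GeneDropResult:
    """Monte-Carlo gene dropping; vectorised across replicates.

    Returns per-animal ``F_PED_hat, F_a_Kal, F_New, F_a_Bal, Ahc`` with
    binomial standard errors (columns suffixed ``_se``).  Reproducible
    bit-exactly for a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    order = ped.topological_order()
    t = ped.table.set_index("id")
    R = n_replicates
    state: dict[str, tuple] = {}  # id -> (ids2, flags2, counts2, aut)
    next_allele = [0]

    def founder_gamete():
        a = next_allele[0]
        next_allele[0] += 1
        return (np.full(R, a, dtype=np.int32),
                np.zeros(R, dtype=bool),
                np.zeros(R, dtype=np.int16))

    def transmit(parent: str):
        p_ids, p_flags, p_cnts, p_aut = state[parent]
        pick = rng.random(R) < 0.5
        ids = np.where(pick, p_ids[0], p_ids[1])
        flags = np.where(pick, p_flags[0], p_flags[1]) | p_aut
        cnts = np.where(pick, p_cnts[0], p_cnts[1]) + p_aut
        return ids, flags, cnts

    rows = []
    for a in order:
        row = t.loc[a]
        gametes = []
        for parent in (row["sire"], row["dam"]):
            if parent == "0":
                gametes.append(founder_gamete())
            else:
                gametes.append(transmit(parent))
        (i1, f1, c1), (i2, f2, c2) = gametes
        aut = i1 == i2
        state[a] = ((i1, i2), (f1, f2), (c1, c2), aut)
        anc = f1 | f2
        fped = aut.mean()
        fakal = (aut & anc).mean()
        fnew = (aut & ~anc).mean()
        fabal = 0.5 * (f1.mean() + f2.mean())
        ahc_rep = 0.5 * (c1.astype(np.float64) + c2)
        ahc = ahc_rep.mean()
        ahc_se = ahc_rep.std(ddof=1) / np.sqrt(R) if R > 1 else np.nan
        rows.append((a, fped, fakal, fnew, fabal, ahc, ahc_se))

    coef = pd.DataFrame(rows, columns=[
        "individual", "F_PED_hat", "F_a_Kal", "F_New", "F_a_Bal", "Ahc", "Ahc_se"])
    for col in ("F_PED_hat", "F_a_Kal", "F_New", "F_a_Bal"):
        p = coef[col].to_numpy()
        coef[col + "_se"] = np.sqrt(np.clip(p * (1 - p), 0, None) / R)
    coef = coef.set_index("individual").loc[ped.ids].reset_index()
    return GeneDropResult(coef, R)
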