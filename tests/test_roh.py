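"""ROH scanner: calibration formulas, window logic vs a naive oracle,
length classes and per-individual summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from rohpop.io import MISSING
from rohpop.roh import (LenczInputs, ROHParams, classify_lengths, detect_roh,
                        lencz_min_snps, min_length_from_density,
                        per_individual_summary)

from conftest import make_genotypes


def naive_roh_oracle(calls, pos, p: ROHParams):
    """Brute-force re-implementation: enumerate every window and stretch."""
    m = len(pos)
    w = p.window_snp
    segments = []
    if m < w:
        return segments
    hits = []
    for s in range(m - w + 1):
        win = calls[s:s + w]
        hits.append(int((win == 1).sum()) <= p.window_het
                    and int((win == MISSING).sum()) <= p.window_missing)
    eligible = []
    for j in range(m):
        containing = [s for s in range(m - w + 1) if s <= j <= s + w - 1]
        rate = sum(hits[s] for s in containing) / len(containing)
        eligible.append(rate >= p.hit_threshold)
    # maximal eligible stretches, then gap splitting
    stretches, cur = [], []
    for j in range(m):
        if eligible[j]:
            cur.append(j)
        elif cur:
            stretches.append(cur)
            cur = []
    if cur:
        stretches.append(cur)
    pieces = []
    for st in stretches:
        piece = [st[0]]
        for j in st[1:]:
            if pos[j] - pos[piece[-1]] > p.max_gap_kb * 1000:
                pieces.append(piece)
                piece = []
            piece.append(j)
        pieces.append(piece)
    for piece in pieces:
        n = len(piece)
        length_kb = (pos[piece[-1]] - pos[piece[0]] + 1) / 1000
        if (n >= p.min_snp and length_kb >= p.min_length_kb
                and length_kb / n <= p.max_kb_per_snp):
            segments.append((int(pos[piece[0]]), int(pos[piece[-1]]), n))
    return segments


class TestLencz:
    def test_alpha_one_single_snp_gives_zero(self):
        assert lencz_min_snps(LenczInputs(1.0, 1, 1, 0.3)) == 0

    def test_direct_evaluation(self):
        # ln(0.05/1e8)/ln(0.75) = 74.45 -> 75
        assert lencz_min_snps(LenczInputs(0.05, 50_000, 2_000, 0.25)) == 75

    def test_study_choice_implies_het_near_026(self):
        # the 64-SNP minimum corresponds to an (unprinted) mean heterozygosity
        # recoverable by root finding
        def l_of_het(h):
            return np.log(0.05 / (49_693 * 2_364)) / np.log(1 - h) - 64.0

        het = brentq(l_of_het, 0.05, 0.6)
        # closed form: het = 1 - exp(ln(alpha/(n_s n_i)) / 64)
        closed = 1.0 - np.exp(np.log(0.05 / (49_693 * 2_364)) / 64.0)
        assert het == pytest.approx(closed, abs=1e-9)
        assert het == pytest.approx(0.2862, abs=0.001)
        assert lencz_min_snps(LenczInputs(0.05, 49_693, 2_364, het + 1e-9)) == 64

    def test_degenerate_het_rejected(self):
        with pytest.raises(ValueError):
            LenczInputs(0.05, 10, 10, 0.0)
        with pytest.raises(ValueError):
            LenczInputs(0.05, 10, 10, 1.0)


def test_min_length_from_density():
    assert min_length_from_density(64, 49.86) == 3191
    assert min_length_from_density(1, 50.0) == 50
    assert min_length_from_density(15, 49.86) == 747


class TestDetect:
    def test_fully_homozygous_chromosome_is_one_segment(self):
        g = make_genotypes(np.zeros((1, 100)), spacing_bp=50_000)
        seg = detect_roh(g)
        assert len(seg) == 1
        row = seg.iloc[0]
        assert row["n_snp"] == 100
        assert row["start_bp"] == 1 and row["end_bp"] == 1 + 99 * 50_000

    def test_alternating_heterozygous_calls_give_nothing(self):
        calls = np.zeros((1, 200))
        calls[0, ::2] = 1
        g = make_genotypes(calls, spacing_bp=50_000)
        assert len(detect_roh(g)) == 0

    def test_short_chromosome_yields_no_calls(self):
        g = make_genotypes(np.zeros((1, 5)), spacing_bp=50_000)
        assert len(detect_roh(g, ROHParams(window_snp=15, min_snp=2,
                                           min_length_kb=1))) == 0

    def test_matches_naive_oracle_with_het_blocks(self, rng):
        p = ROHParams(min_snp=25, min_length_kb=500.0)
        calls = np.zeros((1, 200), dtype=np.int8)
        for start in (40, 90, 160):
            calls[0, start:start + 3] = 1
        pos = np.arange(200) * 40_000 + 1
        g = make_genotypes(calls, {1: pos.tolist()})
        got = detect_roh(g, p)
        exp = naive_roh_oracle(calls[0], pos, p)
        assert [(r.start_bp, r.end_bp, r.n_snp) for r in got.itertuples()] == exp

    def test_monotone_in_filters(self, rng):
        calls = (rng.random((3, 250)) < 0.3).astype(np.int8)
        g = make_genotypes(calls, spacing_bp=50_000)
        base = ROHParams(min_snp=20, min_length_kb=500.0)
        seg0 = detect_roh(g, base)
        for stricter in (ROHParams(min_snp=40, min_length_kb=500.0),
                         ROHParams(min_snp=20, min_length_kb=2000.0)):
            seg1 = detect_roh(g, stricter)
            assert len(seg1) <= len(seg0)
            key0 = set(map(tuple, seg0[["individual", "chrom", "start_bp", "end_bp"]].values))
            key1 = set(map(tuple, seg1[["individual", "chrom", "start_bp", "end_bp"]].values))
            assert key1 <= key0


def test_length_classification_boundaries():
    seg = pd.DataFrame({"length_kb": [3500.0, 6000.0, 12_000.0, 20_000.0, 40_000.0]})
    res = classify_lengths(seg)
    assert res["n"].tolist() == [1, 1, 1, 1, 1]
    # exactly 8 Mb sits in >4-8 (upper edge inclusive)
    res8 = classify_lengths(pd.DataFrame({"length_kb": [8000.0]}))
    assert res8.set_index("length_class")["n"][">4-8"] == 1
    assert res8["n"].sum() == 1


def test_length_classification_matches_brute_force(rng):
    kb = rng.uniform(100, 60_000, size=1000)
    res = classify_lengths(pd.DataFrame({"length_kb": kb}))
    mb = kb / 1000
    brute = [int(((mb > lo) & (mb <= hi)).sum())
             for lo, hi in [(0, 4), (4, 8), (8, 16), (16, 32), (32, np.inf)]]
    assert res["n"].tolist() == brute
    assert res["n"].sum() == 1000


def test_per_individual_summary():
    seg = pd.DataFrame({
        "individual": ["a", "a"], "chrom": [1, 1],
        "start_bp": [1, 10_000_001], "end_bp": [4_000_000, 16_000_000],
        "n_snp": [80, 120], "length_kb": [4000.0, 6000.0]})
    out = per_individual_summary(seg, ["a", "b"])
    row_a = out.set_index("individual").loc["a"]
    assert row_a["n_roh"] == 2
    assert row_a["mean_length_mb"] == pytest.approx(5.0)
    assert row_a["combined_length_mb"] == pytest.approx(10.0)
    row_b = out.set_index("individual").loc["b"]
    assert row_b["n_roh"] == 0 and row_b["combined_length_mb"] == 0
    assert np.isnan(row_b["mean_length_mb"])


def test_mean_count_identity(small_cohort):
    from rohpop.roh import calibrate_params

    seg = detect_roh(small_cohort.genotypes, calibrate_params(small_cohort.genotypes))
    summ = per_individual_summary(seg, small_cohort.genotypes.individuals)
    assert summ["n_roh"].mean() == pytest.approx(
        len(seg) / small_cohort.genotypes.n_individuals)
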