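"""Effective population size: LD binning vs a naive pairwise oracle,
the Sved closed form, generation equivalents and the regression route."""

import numpy as np
import pandas as pd
import pytest

from rohpop.ne import (generation_equivalents, ne_from_froh, ne_from_ld,
                       ne_from_regression, pairwise_r2_binned)

from conftest import make_genotypes


def naive_r2_bins(calls, pos, max_dist_mb, bin_width_mb):
    """Loop over all pairs with plain Pearson correlations."""
    n_bins = int(np.ceil(max_dist_mb / bin_width_mb))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    m = calls.shape[1]
    for i in range(m):
        for j in range(i + 1, m):
            d = pos[j] - pos[i]
            if d > max_dist_mb * 1e6:
                continue
            xi, xj = calls[:, i].astype(float), calls[:, j].astype(float)
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            b = min(int(np.ceil(d / (bin_width_mb * 1e6))) - 1, n_bins - 1)
            sums[b] += r ** 2
            counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


class TestPairwiseR2:
    def test_duplicated_snp_gives_r2_one_in_first_bin(self, rng):
        col = rng.integers(0, 3, size=50)
        calls = np.stack([col, col], axis=1)
        g = make_genotypes(calls, {1: [1000, 2000]})
        bins = pairwise_r2_binned(g, max_dist_mb=1.0, bin_width_mb=0.1)
        assert bins.loc[0, "mean_r2"] == pytest.approx(1.0)
        assert bins.loc[0, "n_pairs"] == 1

    def test_matches_naive_loop_oracle(self, rng):
        calls = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=20, replace=False))
        g = make_genotypes(calls, {1: pos.tolist()})
        bins = pairwise_r2_binned(g, max_dist_mb=3.0, bin_width_mb=0.1)
        exp_mean, exp_counts = naive_r2_bins(calls, pos, 3.0, 0.1)
        assert np.array_equal(bins["n_pairs"].to_numpy(), exp_counts)
        ok = exp_counts > 0
        assert np.allclose(bins["mean_r2"].to_numpy()[ok], exp_mean[ok])

    def test_independent_snps_have_r2_near_one_over_n(self, rng):
        n = 100
        calls = rng.binomial(2, 0.5, size=(n, 60)).astype(np.int8)
        g = make_genotypes(calls, spacing_bp=10_000)
        bins = pairwise_r2_binned(g, max_dist_mb=1.0, bin_width_mb=1.0)
        total_pairs = int(bins["n_pairs"].sum())
        mean_r2 = float((bins["mean_r2"] * bins["n_pairs"]).sum() / total_pairs)
        # E[r2] ~ 1/n for independent loci; allow 3 SE of the mean over pairs
        se = np.sqrt(2.0) / n / np.sqrt(total_pairs)  # var(r2) ~ 2/n^2 for chi2_1/n
        assert abs(mean_r2 - 1.0 / n) < max(3 * se, 0.01)

    def test_cross_chromosome_pairs_excluded(self, rng):
        col = rng.integers(0, 3, size=40)
        calls = np.stack([col, col], axis=1)
        g = make_genotypes(calls, {1: [1000], 2: [2000]})
        bins = pairwise_r2_binned(g, max_dist_mb=1.0, bin_width_mb=0.1)
        assert bins["n_pairs"].sum() == 0


class TestNeFromLd:
    def test_closed_forms(self):
        bins = pd.DataFrame({"bin_mid_mb": [1.0, 5.0], "bin_left_mb": [0.9, 4.9],
                             "mean_r2": [0.1, 0.05], "n_pairs": [10, 10]})
        out = ne_from_ld(bins)  # c = 0.01 and 0.05 Morgan
        row50 = out.set_index("t").loc[50]
        assert row50["Ne"] == pytest.approx(0.9 / 0.004)  # 225
        assert row50["delta_F"] == pytest.approx(1 / 450)
        row10 = out.set_index("t").loc[10]
        assert row10["Ne"] == pytest.approx(0.95 / (4 * 0.05 * 0.05))  # 95

    def test_degenerate_r2_one_gives_ne_zero(self):
        bins = pd.DataFrame({"bin_mid_mb": [1.0], "bin_left_mb": [0.9],
                             "mean_r2": [1.0], "n_pairs": [5]})
        out = ne_from_ld(bins)
        assert out["Ne"].iloc[0] == 0.0

    def test_bins_sharing_a_generation_are_averaged(self):
        # mids 24.0 and 26.0 Mb -> t = round(1/(2c)) = 2 for both
        bins = pd.DataFrame({"bin_mid_mb": [24.0, 26.0], "bin_left_mb": [23.9, 25.9],
                             "mean_r2": [0.2, 0.4], "n_pairs": [3, 5]})
        out = ne_from_ld(bins)
        assert len(out) == 1 and out["t"].iloc[0] == 2
        ne1 = (1 - 0.2) / (4 * 0.24 * 0.2)
        ne2 = (1 - 0.4) / (4 * 0.26 * 0.4)
        assert out["Ne"].iloc[0] == pytest.approx((ne1 + ne2) / 2)


def test_generation_equivalents_match_study_values():
    for L, ge in [(3.191, 15.6691), (4, 12.5), (8, 6.25), (16, 3.125), (32, 1.5625)]:
        assert generation_equivalents(L) == pytest.approx(ge, abs=5e-5)


class TestNeFromFroh:
    @pytest.mark.parametrize("f,ge,expected", [
        (0.074, 6.25, 34.394), (0.031, 3.125, 33.991), (0.006, 1.5625, 46.985)])
    def test_study_closed_forms(self, f, ge, expected):
        assert ne_from_froh(f, ge).ne == pytest.approx(expected, abs=0.01)

    def test_small_f_linearisation(self):
        est = ne_from_froh(1e-6, 6.25)
        assert est.delta_f == pytest.approx(1e-6 / 5.25, rel=1e-3)

    def test_zero_f_flagged_infinite(self):
        assert np.isinf(ne_from_froh(0.0, 6.25).ne)


class TestNeFromRegression:
    def test_constant_froh_flagged_infinite(self):
        est = ne_from_regression(np.full(20, 0.1), np.repeat([2000, 2001], 10))
        assert est.slope == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(est.ne)

    def test_exact_slope_recovered_to_machine_precision(self):
        years = np.arange(1990, 2015)
        b_true = -0.001
        froh = 1.0 - np.exp(b_true * (years - years[0]) + np.log(0.9))
        est = ne_from_regression(froh, years, generation_interval_years=6.5)
        assert est.slope == pytest.approx(b_true, abs=1e-12)
        assert est.delta_f_yr == pytest.approx(1 - np.exp(-0.001), rel=1e-9)
        assert est.ne == pytest.approx(1 / (2 * 6.5 * (1 - np.exp(-0.001))), rel=1e-9)
        assert est.ci_low <= est.ne <= est.ci_high

    def test_noisy_slope_recovered_within_3se(self, rng):
        years = np.tile(np.arange(1990, 2010), 10)
        b_true = -0.002
        hits = 0
        for _ in range(50):
            y = b_true * years + rng.normal(0, 0.01, size=years.size)
            froh = 1 - np.exp(y - y.max() - 0.01)
            est = ne_from_regression(froh, years)
            if abs(est.slope - b_true) <= 3 * est.slope_se:
                hits += 1
        assert hits >= 47  # ~99.7% nominal; allow a little slack
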