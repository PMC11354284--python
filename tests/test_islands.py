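"""Incidence track, percentile ROH islands, consensus ROH, stratification."""

import numpy as np
import pandas as pd
import pytest

from rohpop.io import CohortTable
from rohpop.islands import (IncidenceTrack, call_consensus, call_islands,
                            incidence_track, stratified_islands)
from rohpop.stats import assign_cohorts

from conftest import make_genotypes


def seg(ind, chrom, start, end):
    return (ind, chrom, start, end, 10, (end - start + 1) / 1000)


SEG_COLS = ["individual", "chrom", "start_bp", "end_bp", "n_snp", "length_kb"]


def track_from_values(values, spacing_bp=50_000, n_individuals=10):
    pos = [1 + k * spacing_bp for k in range(len(values))]
    return IncidenceTrack(pd.DataFrame({"chrom": 1, "pos": pos,
                                        "incidence": values}), n_individuals)


def _member_snps(track, regions):
    """SNP indices of the track covered by any region."""
    t = track.table
    out = set()
    for r in regions.itertuples():
        mask = ((t["chrom"] == r.chrom) & (t["pos"] >= r.start_bp)
                & (t["pos"] <= r.end_bp))
        out |= set(np.flatnonzero(mask.to_numpy()).tolist())
    return out


class TestIncidence:
    def test_single_individual_block(self):
        g = make_genotypes(np.zeros((1, 30)), spacing_bp=1000)
        pos = g.marker_map.table["pos"]
        segments = pd.DataFrame([seg("ind0", 1, int(pos[10]), int(pos[20]))],
                                columns=SEG_COLS)
        track = incidence_track(segments, g)
        inc = track.table["incidence"].to_numpy()
        assert (inc[10:21] == 1.0).all()
        assert (inc[:10] == 0).all() and (inc[21:] == 0).all()

    def test_two_individuals_disjoint_roh(self):
        g = make_genotypes(np.zeros((2, 30)), spacing_bp=1000)
        pos = g.marker_map.table["pos"]
        segments = pd.DataFrame([seg("ind0", 1, int(pos[0]), int(pos[5])),
                                 seg("ind1", 1, int(pos[10]), int(pos[15]))],
                                columns=SEG_COLS)
        inc = incidence_track(segments, g).table["incidence"].to_numpy()
        assert (inc[0:6] == 0.5).all() and (inc[10:16] == 0.5).all()
        assert inc[8] == 0

    def test_matches_brute_force_membership(self, rng):
        g = make_genotypes(np.zeros((5, 80)), spacing_bp=1000)
        pos = g.marker_map.table["pos"].to_numpy()
        rows = []
        for i in range(5):
            for _ in range(rng.integers(1, 4)):
                a, b = np.sort(rng.choice(pos, size=2, replace=False))
                rows.append(seg(f"ind{i}", 1, int(a), int(b)))
        segments = pd.DataFrame(rows, columns=SEG_COLS)
        inc = incidence_track(segments, g).table["incidence"].to_numpy()
        brute = np.zeros(len(pos))
        for k, p in enumerate(pos):
            covered = {r.individual for r in segments.itertuples()
                       if r.start_bp <= p <= r.end_bp}
            brute[k] = len(covered) / 5
        assert np.allclose(inc, brute)


class TestIslands:
    def test_uniform_incidence_gives_zero_islands(self):
        track = track_from_values(np.full(100, 0.4))
        assert len(call_islands(track, 99)) == 0

    def test_single_block_is_one_island(self):
        # the high block must occupy <1% of SNPs to exceed the 99th
        # percentile under strict exceedance: 50 of 10,000 SNPs
        vals = np.full(10_000, 0.1)
        vals[3000:3050] = 0.9
        track = track_from_values(vals, spacing_bp=5000)
        islands = call_islands(track, 99)
        assert islands.attrs["threshold"] == pytest.approx(0.1)
        assert len(islands) == 1
        row = islands.iloc[0]
        assert row["n_snp"] == 50
        assert row["peak_incidence"] == pytest.approx(0.9)

    def test_95th_percentile_islands_contain_99th(self, rng):
        for _ in range(10):
            track = track_from_values(rng.random(500))
            i99 = call_islands(track, 99)
            i95 = call_islands(track, 95)
            cover95 = _member_snps(track, i95)
            assert _member_snps(track, i99) <= cover95


class TestConsensus:
    def test_single_individual_footprint(self):
        g = make_genotypes(np.zeros((1, 40)), spacing_bp=1000)
        pos = g.marker_map.table["pos"]
        segments = pd.DataFrame([seg("ind0", 1, int(pos[5]), int(pos[12]))],
                                columns=SEG_COLS)
        track = incidence_track(segments, g)
        cons = call_consensus(track, 0.5)
        assert len(cons) == 1
        assert cons.iloc[0]["start_bp"] == pos[5] and cons.iloc[0]["end_bp"] == pos[12]

    def test_nestedness_across_sharing_levels(self, rng):
        for _ in range(10):
            track = track_from_values(rng.random(300))
            spans = {sh: _member_snps(track, call_consensus(track, sh))
                     for sh in (0.3, 0.4, 0.5)}
            assert spans[0.5] <= spans[0.4] <= spans[0.3]

    def test_matches_brute_force_thresholding(self, rng):
        vals = rng.choice([0.1, 0.35, 0.6], size=200)
        track = track_from_values(vals)
        cons = call_consensus(track, 0.35, max_gap_kb=50)
        member = vals >= 0.35
        # brute force: runs of member SNPs on the 50-kb grid never split
        brute_runs = []
        k = 0
        while k < len(member):
            if member[k]:
                j = k
                while j + 1 < len(member) and member[j + 1]:
                    j += 1
                brute_runs.append((k, j))
                k = j + 1
            else:
                k += 1
        assert len(cons) == len(brute_runs)
        pos = track.table["pos"].to_numpy()
        for row, (a, b) in zip(cons.itertuples(), brute_runs):
            assert row.start_bp == pos[a] and row.end_bp == pos[b]


class TestStratified:
    def _cohorts(self, ids, props):
        meta = pd.DataFrame({"id": ids, "us_bs_proportion": props,
                             "n_calvings": 5, "culled": True})
        return assign_cohorts(meta)

    def test_stratum_equal_to_cohort_matches_unstratified(self):
        g = make_genotypes(np.zeros((6, 1000)), spacing_bp=1000)
        pos = g.marker_map.table["pos"].to_numpy()
        rows = [seg(f"ind{i}", 1, int(pos[200]), int(pos[220])) for i in range(4)]
        segments = pd.DataFrame(rows, columns=SEG_COLS)
        cohorts = self._cohorts(g.individuals, [95] * 6)
        strat = stratified_islands(segments, g, cohorts, "bs_class",
                                   percentile=95, min_stratum_size=1)
        full = call_islands(incidence_track(segments, g), 95)
        assert list(strat) == ["90-99"]
        assert len(full) == 1  # non-vacuous comparison
        pd.testing.assert_frame_equal(strat["90-99"], full)

    def test_stratum_specific_block_appears_only_there(self):
        g = make_genotypes(np.zeros((8, 1000)), spacing_bp=1000)
        pos = g.marker_map.table["pos"].to_numpy()
        rows = []
        # low-BS stratum (4 animals) shares a block; high-BS does not
        for i in range(4):
            rows.append(seg(f"ind{i}", 1, int(pos[100]), int(pos[120])))
        rows.append(seg("ind4", 1, int(pos[700]), int(pos[705])))
        segments = pd.DataFrame(rows, columns=SEG_COLS)
        cohorts = self._cohorts(g.individuals, [50] * 4 + [95] * 4)
        strat = stratified_islands(segments, g, cohorts, "bs_class",
                                   percentile=95, min_stratum_size=1)
        low = strat["<60"]
        assert len(low) == 1 and low.iloc[0]["start_bp"] == pos[100]
        high = strat["90-99"]
        assert (high["start_bp"] != pos[100]).all()
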