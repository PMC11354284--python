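"""Effective population size by the three routes.

LD decay per ancestral generation, Ne-ROH from the cohort mean F_ROH
variants with their generation equivalents, and the regression of
ln(1 - F_ROH) on birth year.  Also re-evaluates the Ne-ROH closed form at
the cattle study's printed cohort means as a cross-check of the formula.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import get_cohort, outdir

from rohpop.inbreeding import FROH_LABELS, FROH_THRESHOLDS_MB, froh_profile
from rohpop.io import autosome_length
from rohpop.ne import (generation_equivalents, ne_from_froh, ne_from_ld,
                       ne_from_regression, pairwise_r2_binned)
from rohpop.roh import calibrate_params, detect_roh

sim = get_cohort()
out = outdir()
g = sim.genotypes

bins = pairwise_r2_binned(g, max_dist_mb=33.3, bin_width_mb=0.1)
bins.to_csv(out / "ld_bins.tsv", sep="\t", index=False, float_format="%.6g")
curve = ne_from_ld(bins)
curve.to_csv(out / "ne_by_generation.tsv", sep="\t", index=False,
             float_format="%.6g")
recent = curve[curve["t"] <= 20]
print(f"LD-based Ne: {len(curve)} generation bins; "
      f"t<=20 range {recent['Ne'].min():.0f}-{recent['Ne'].max():.0f}")

params = calibrate_params(g)
seg = detect_roh(g, params)
froh = froh_profile(seg, g.individuals, autosome_length(g.marker_map))
rows = []
for label, thr in zip(FROH_LABELS, FROH_THRESHOLDS_MB):
    min_len = thr if thr > 0 else params.min_length_kb / 1000.0
    ge = generation_equivalents(min_len)
    f = float(froh[label].mean())
    if 0 < f < 1:
        est = ne_from_froh(f, ge, label)
        rows.append((label, f, ge, est.delta_f, est.ne))
    else:
        rows.append((label, f, ge, np.nan, np.nan))
tab = pd.DataFrame(rows, columns=["source", "mean_F", "GE", "delta_F", "Ne"])
tab.to_csv(out / "ne_roh.tsv", sep="\t", index=False, float_format="%.6g")
print(tab.round(4).to_string(index=False))

years = sim.pedigree.table.set_index("id")["birth_year"]
yr = years.reindex(froh["individual"]).astype(float).to_numpy()
est = ne_from_regression(froh["F_ROH"].to_numpy(), yr, 6.5)
print(f"regression: b = {est.slope:.5f} +/- {est.slope_se:.5f}, "
      f"dF_yr = {est.delta_f_yr:.5f}, Ne_reg = {est.ne:.1f} "
      f"(95% CI {est.ci_low:.1f}-{est.ci_high:.1f})")

# formula cross-check at the cattle study's printed cohort means
for f, L in [(0.074, 8), (0.031, 16), (0.006, 32)]:
    ge = generation_equivalents(L)
    print(f"  check: F={f}, GE={ge} -> Ne = {ne_from_froh(f, ge).ne:.3f}")
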