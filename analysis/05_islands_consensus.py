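"""ROH islands and consensus regions, overall and per cohort stratum.

Islands are runs of SNPs whose ROH incidence strictly exceeds the 99th
(and 95th) percentile of the genome-wide incidence distribution; consensus
ROH are runs covered in at least 30/40/50% of the animals.  Stratified
island calls recompute incidence and threshold within each breed-proportion
class.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import get_cohort, outdir

from rohpop.islands import (call_consensus, call_islands, incidence_track,
                            stratified_islands, track_to_bedgraph)
from rohpop.roh import calibrate_params, detect_roh

sim = get_cohort()
out = outdir()
g = sim.genotypes

seg = detect_roh(g, calibrate_params(g))
track = incidence_track(seg, g)
track_to_bedgraph(track, out / "roh_incidence.bedgraph")

frames = []
for pct in (99, 95):
    isl = call_islands(track, pct)
    print(f"{len(isl)} island(s) above the {pct}th percentile "
          f"(threshold {isl.attrs['threshold']:.3f})")
    isl.insert(0, "percentile", pct)
    frames.append(isl)
nonempty = [f for f in frames if len(f)]
(pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]).to_csv(
    out / "roh_islands.tsv", sep="\t", index=False, float_format="%.6g")

frames = []
for sh in (0.30, 0.40, 0.50):
    cons = call_consensus(track, sh)
    print(f"{len(cons)} consensus region(s) shared by >= {sh:.0%} of animals")
    cons.insert(0, "sharing", sh)
    frames.append(cons)
nonempty = [f for f in frames if len(f)]
(pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]).to_csv(
    out / "consensus_roh.tsv", sep="\t", index=False, float_format="%.6g")

strat = stratified_islands(seg, g, sim.cohorts, "bs_class", percentile=95)
for level, isl in strat.items():
    print(f"  BS class {level}: {len(isl)} island(s) at the 95th percentile")
rows = []
for level, isl in strat.items():
    isl = isl.copy()
    isl.insert(0, "bs_class", level)
    rows.append(isl)
nonempty = [f for f in rows if len(f)]
if nonempty:
    pd.concat(nonempty, ignore_index=True).to_csv(
        out / "roh_islands_by_bs_class.tsv", sep="\t", index=False,
        float_format="%.6g")
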