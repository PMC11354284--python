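# Methods

This note records the models implemented in `rohpop`, the conventions and
defaults they use, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates, coding and map conventions

All positions are 1-based inclusive base pairs; a segment's length is
`end − start + 1`, reported in kb or Mb. Genotype calls count copies of a
*designated* allele per marker — the alphabetically second of the two
observed alleles for PED input, the ALT allele for VCF — with a dedicated
missing sentinel distinct from {0,1,2} (PED `0 0` and VCF `./.` both map to
it). Homozygosity, and therefore every ROH result, is invariant to the
designation; it is recorded in the marker map for reproducibility. Only
autosomes are analysed: markers with non-numeric chromosome labels or
chromosome 0 are dropped with a warning, never recoded.

The SNP-covered autosome length `L_AUTO` is the sum over chromosomes of
(last SNP position − first SNP position): the span-sum convention. The mean
SNP density is `L_AUTO / n_markers`. On the 49,693-SNP cattle map these give
2,477,795,166 bp and 49.86 kb/SNP, which is how the convention was fixed;
whether a "length covered by SNPs" should instead use full chromosome
lengths is not decidable from the source material, so the span-sum is
documented as the single convention throughout.

One PED caveat: a text PED file cannot say which allele is counted at a
marker where only one allele is observed, so object → write → read identity
holds for the homozygosity pattern but not necessarily for the dosage
orientation of monomorphic markers. Read → write → read is an exact
identity, and the binary and VCF dialects (which carry both alleles)
round-trip exactly.

## ROH detection

The scanner follows the PLINK 1.9 `--homozyg` sliding-window design:

1. every window of `window_snp` consecutive SNPs on a chromosome is a hit
   iff it has ≤ `window_het` heterozygous and ≤ `window_missing` missing
   calls;
2. a SNP's hit rate is hits-containing-it / windows-containing-it (only
   windows fully inside the chromosome exist); the SNP is run-eligible when
   the rate reaches `hit_threshold`;
3. maximal runs of consecutive eligible SNPs are split where adjacent SNPs
   lie more than `max_gap_kb` apart;
4. runs failing `min_snp`, `min_length_kb` or the `max_kb_per_snp` density
   bound are discarded. Segment boundaries are the outermost eligible SNP
   positions, not window edges.

Defaults (all configurable): 15-SNP windows, ≤1 heterozygote, 0 missing,
hit threshold 0.05 (the PLINK default — the source parameterisation omits
it), 64-SNP minimum, 3191-kb minimum length, 500-kb gap, 100 kb/SNP
density bound. Segments may contain heterozygous calls admitted by window
smoothing; no per-segment heterozygote cap is applied by default
(`segment_het` adds one if wanted). No MAF/HWE/LD pruning is applied —
pruning biases homozygosity on medium-density panels — and none is needed
for the calibration below.

**False-positive calibration.** The minimum SNP count is
`l = ln(α/(n_s n_i)) / ln(1 − het)` (ceiling), the expected-count bound on
chance runs of homozygous calls across `n_s` SNPs and `n_i` individuals at
mean heterozygosity `het`; the minimum length is `floor(l × density)` kb.
`calibrate_params` applies this to the cohort at hand (α = 0.05 by
default). The 64-SNP / 3191-kb defaults are this formula evaluated at the
cattle cohort's scale; the mean heterozygosity implied by that choice is
0.286 (the closed form `1 − exp(ln(α/(n_s n_i))/64)`).

Length classes are ≤4, >4–8, >8–16, >16–32 and >32 Mb, upper edge
inclusive (an exactly-8-Mb segment is in >4–8).

## Genomic inbreeding

`F_ROH = Σ L_ROH / L_AUTO`; the thresholded variants use a strict ">" on
length in Mb. `F_IS = (O_i − E_i)/(n_i − E_i)` with
`E_i = Σ_j (1 − 2 p_j (1 − p_j))` over the markers genotyped in individual
i; allele frequencies default to sample frequencies of the analysed cohort
from non-missing calls (a reference panel's frequencies can be supplied
instead). Markers missing in an individual are excluded from O, E and n
alike. The cumulative F_ROH curve accumulates segment length by segment
length ≤ cutoff; its right endpoint equals the unthresholded F_ROH.

## Pedigree inbreeding and gene dropping

`F_PED` is exact, via the tabular kinship recursion
(`phi(i,j) = (phi(s,j)+phi(d,j))/2`, `F = phi(sire, dam)`); the test suite
checks it against an independent Wright path-counting oracle.

The ancestral coefficients are estimated by gene dropping one abstract
locus per replicate: every founder (and every unknown parent, treated as a
unique unrelated founder) contributes two uniquely labelled alleles, which
are transmitted with fair Mendelian sampling in one vectorised pass per
animal across all replicates. Per replicate and animal:

* autozygous (both gametes carry the same founder allele) → F_PED-hat;
* autozygous and the allele was autozygous in an ancestor → F_a_Kal;
  otherwise → F_New, so `F_New + F_a_Kal = F_PED-hat` holds exactly by
  construction and only F_PED-hat itself carries Monte-Carlo error;
* each allele carries a flag "has been autozygous in an ancestor" (set when
  transmitted by an autozygous parent) → F_a_Bal is the mean flag;
* and a count of ancestral generations spent autozygous → Ahc is the mean
  count (it can in principle exceed 1 in extremely inbred lines).

Standard errors are binomial (`sqrt(p(1−p)/R)`) for the proportions and the
replicate-mean standard error for Ahc. The default 10^5 replicates put the
SE below 0.0016 everywhere, well under 0.001 for the coefficient magnitudes
typical of livestock pedigrees; a seed is mandatory and results are
bit-reproducible. Memory is ~15 bytes × replicates × animals, i.e. ~1.5 GB
at 10^5 replicates for a 1,000-animal pedigree — reduce replicates for very
large pedigrees.

## Effective population size

*LD route.* r² is the squared Pearson correlation of genotype dosages
(composite LD — the data are unphased), computed within chromosomes for all
pairs up to 33.3 Mb and averaged in 0.1-Mb bins. Monomorphic pairs are
skipped and counted; markers with missing calls are mean-imputed for this
computation only (the intended input is imputed array data without missing
calls). Each bin's representative distance is its midpoint (configurable to
the left edge); `c` converts at 100 Mb = 1 Morgan;
`Ne = (1−r²)/(4 c r²)`; the probed generation is `t = 1/(2c)` rounded
half-up, bins sharing a `t` have their Ne averaged, and `ΔF = 1/(2Ne)`.
Bins with r² = 0 are flagged and dropped; r² = 1 yields the degenerate
Ne = 0.

*Generation-equivalents route.* `GE = 100/(2L)` for minimum length L Mb
under 1 cM = 1 Mb (15.6691 at the calibrated 3.191 Mb; 12.5, 6.25, 3.125,
1.5625 at 4/8/16/32 Mb), `ΔF = 1 − (1−F)^(1/(GE−1))`, `Ne = 1/(2ΔF)`;
F = 0 is reported as infinite Ne rather than an error.

*Regression route.* OLS of `ln(1 − F_ROH)` on birth year;
`ΔF_yr = 1 − exp(b)`; `Ne = 1/(2 L ΔF_yr)` with generation interval
L = 6.5 years by default; the 95% CI transforms `b ± 1.96 SE_b` through the
same chain. A non-negative slope gives ΔF ≤ 0 and an infinite Ne flag. The
full-precision slope is used throughout — rounding ΔF_yr before inverting
visibly distorts Ne at this scale.

## Islands and consensus ROH

Incidence is the fraction of individuals with ≥1 ROH covering the SNP,
defined for every map SNP. The island threshold is the 99th (or 95th)
percentile of the genome-wide incidence distribution with linear
interpolation, and membership is *strict* exceedance — a degenerate
all-equal track therefore has no islands, and a high-incidence block must
occupy less than (100 − percentile)% of SNPs to stand out. Consensus uses
an inclusive ≥ sharing threshold (30/40/50%). Member runs are never merged
across chromosomes and are split at gaps above `max_gap_kb` (default the
ROH gap, 500 kb); island coordinates are the first/last member-SNP
positions. Stratified calls recompute both incidence and threshold within
each stratum; strata below a configurable minimum size trigger a warning,
not an error.

## Cohort statistics

Breed-proportion classes are <60, [60,70), [70,80), [80,90), [90,100);
survival traits Surv1/3/5/7/9 are 1 when the cow reached calving k+1, 0
when culled before it, and missing when censored (still in the herd).
Last-lactation groups are 1 / 2–3 / 4–5 / 6–8 / 9–12 / 13–17 — the source
grouping lists labels without boundaries; these bins are the package's
reading and are stated here because they affect only the descriptive
grouping, not any coefficient.

With a single fixed factor and no covariates the least-squares mean is the
class mean; SEs use the pooled residual variance and pairwise differences
are unadjusted t-tests on the residual df (no multiple-testing correction,
matching the letter-grouping convention at p < 0.05). The two-way
breed × survival model is realised as a cell-means one-way fit on the
crossed factor, which is equivalent for the contrasts of interest. The
bootstrap CI for mean differences is the standard bias-corrected (BC)
percentile construction with independent resampling of the two samples;
degenerate bootstrap distributions collapse to a point interval. Cronbach's
α is `k/(k−1) (1 − Σ var_item / var_sum)`. A Shapiro–Wilk check is provided
as an optional diagnostic, not a gate.

## Synthetic data

The generator produces discrete, non-overlapping generations (founders plus
`n_generations` cohorts) under random, circular or full-sib-line mating,
with alternating sexes and birth years advancing by the generation interval
(6.5 years by default, rounded to whole years). Founder chromosomes are
unique labelled haplotypes with per-SNP allele frequencies drawn uniformly
from [0.05, 0.5]; meiosis places a Poisson number of crossovers uniformly
(Haldane model, no interference) at 1 cM = 1 Mb. Because every transmitted
chromosome is a mosaic of founder haplotypes, the true IBD segments of each
individual (equal founder haplotype on both gametes) and the exact F_PED
are known. Genotyping error (a call resampled away from truth) and
missingness are applied after the truth is recorded.

Defaults describe a small closed nucleus population at the study's marker
density: 40 founders, 5 generations × 200, 29 × 100 Mb, one SNP per 50 kb,
no error or missingness. Survival outcomes follow a per-lactation
continuation probability `expit(logit(0.8) + effect × F)`; effect 0
decouples survival from inbreeding, negative effects make inbred cows leave
earlier; 15% of cows are censored; breed proportions are drawn
N(73.8, 10.4²) clipped to [19, 98] to mimic the study cohort's marginal
distribution (independent of inbreeding — the generator does not emulate
the breed-proportion/inbreeding correlation of the real population).

What the generator does *not* emulate, and hence what passing tests do not
show about real data: coalescent founder LD (founder sites are independent,
so background LD decays faster than in real cattle), overlapping
generations and non-random mate selection, array ascertainment beyond the
uniform MAF band, genotyping error structure, and selection during the
simulated breeding. Parameter-recovery results (IBD recall, F_ROH ≈ F_PED)
therefore validate the algorithms, not the biology of any particular breed.

## Problem sizes used in the checks

The scanner-equivalence check runs 1,000 random single-chromosome instances
of ≤300 SNPs against a naive window-enumeration oracle. The
parameter-recovery check simulates the default cohort (200 genotyped
animals, 58,000 SNPs) once: true IBD segments > 4 Mb must be ≥80%-covered by
a detected ROH in ≥95% of cases at 1-Mb detection thresholds, and the mean
F_ROH under the cohort's own calibration must agree with the exact mean
F_PED within 3 SE of the paired per-individual difference. The Kalinowski
identity is checked at 10^5 gene-dropping replicates on 20 random
pedigrees. The analysis scripts use a 630-animal, 10-chromosome cohort —
large enough for stable LD bins and survival contrasts while keeping each
script in seconds.

## Known limitations

* PLINK's `--homozyg` has additional rarely-used behaviours (e.g.
  `--homozyg-window-threshold` interactions at chromosome ends are
  approximated by using only fully-contained windows); agreement is exact
  for the windowing semantics stated above, which is also what the oracle
  enforces.
* LD r² uses mean imputation under missingness rather than pairwise
  deletion; with the intended fully-imputed inputs the two coincide.
* The LD-based Ne carries no sample-size or mutation correction and no CI.
* Ahc's [0,1] range is nominal; deeply inbred pedigrees can exceed 1.
* Gene-dropping memory grows linearly in animals × replicates (all states
  are kept for transmission); see the figure above.
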