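# Methods

`redprev` estimates how common repeat expansion disorders (REDs) are in a
genotyped population, and how many people would be expected to be affected,
from four linked computations: carrier counting under the correct inheritance
model, binomial frequency estimation with Wilson score intervals, an
age-structured prevalence model, and sequence-level decomposition of the HTT
exon-1 repeat structure. This note records the models, their assumptions, the
defaults that matter, and the numerical choices made where the design was
genuinely open.

## Locus registry and allele classification

Each RED locus is defined by its repeat motif (1–6 bp), inheritance mode and
a four-band threshold scheme on allele size in repeat units:
normal `[0, intermediate_min)`, intermediate `[intermediate_min,
premutation_min)`, premutation/reduced-penetrance `[premutation_min,
full_min)` and full mutation `[full_min, ∞)`. All bands are half-open and
lower-inclusive, applied uniformly at every locus; the premutation and
reduced-penetrance ranges are treated as a single band. Loci without a
defined intermediate range extend the normal band to `premutation_min`.

The packaged default registry covers the 16 loci at which 150 bp short-read
WGS can separate premutation from full-mutation alleles (13 autosomal
dominant, FXN and RFC1 recessive, AR X-linked). Threshold values were
compiled from standard clinical references (GeneReviews chapters, diagnostic
guidelines); each entry in `src/redprev/data/loci.yaml` carries a source
annotation, and every field can be overridden from a user config. Sizes are
integers; base-pair lengths convert by truncating division by motif length.
`max_reliable_size` records the sizing ceiling (read-length-bound, or a
larger value where orthogonal PCR/Southern validation applies) and must be at
least `full_min` for a locus to be admitted — the inclusion criterion for
frequency estimation.

## Carrier counting

An individual's carrier status at a locus is derived from their two (or, for
hemizygous males, one) classified alleles:

* dominant and X-linked: status of the larger allele; a person with one
  premutation and one full allele counts once, as a full carrier, because
  frequencies are reported per individual, not per allele;
* recessive: biallelic iff both alleles ≥ `full_min`, monoallelic iff
  exactly one;
* X-linked males are evaluated on the single allele; rows of unknown sex at
  X-linked loci are skipped with a warning (no hemizygosity model can be
  chosen), and male-only denominators are available via a sex filter.

The `qc_pass` flag models the manual read-pileup inspection applied to
putative expansions in the source workflow; failing rows leave the per-locus
denominator, so N may differ between loci.

## Carrier frequency and Wilson intervals

For `count` carriers among `n` individuals the point estimate is reported as
"1 in x" with `x = round(n / count)` (half away from zero, zero digits — so
82,176/290 = 283.4 → 283), plus a per-100,000 transform `100000 / x`. The
95% confidence interval is the Wilson score interval without continuity
correction,

    (p + z²/2n ± z·√(pq/n + z²/4n²)) / (1 + z²/n),  z = 1.96 by default,

with per-100k bounds emitted in ascending order. With zero carriers the
point estimate is undefined (reported absent) while the interval is still
computed at p = 0, whose lower bound is exactly 0. The touching bound at
p = 0 or 1 is clamped onto p to absorb last-bit rounding. Exact
(Clopper–Pearson) intervals are deliberately not offered; the Wilson form is
the method's specification.

## Age-structured prevalence model

Expected new cases in 5-year age bin k are

    M_k = f · N_k · p_k · pen(k)

with `f` the mutation (carrier) frequency, `N_k` the population pyramid
count, `p_k` the normalized age-at-onset proportion, and `pen` an optional
cumulative age-related penetrance curve (tabulated age → fraction, linearly
interpolated, evaluated at bin midpoints, default constant 1). The model is
linear in `f`, which the tests exploit for parameter recovery.

Prevalence accounts for survival with a *trailing* window: people counted in
bin k are survivors of onsets in the preceding `n` years (the disease's
median survival). On 5-year bins the window is a rolling sum over
`n // 5` full bins plus a fractional weight `(n mod 5)/5` on the oldest,
partially covered bin. This is exactly equivalent to spreading each bin's
incidence uniformly over its five years, cumulating over the trailing `n`
years, and reading the result at each bin's last year — the property the
per-year brute-force oracle in the tests checks for n ∈ {3, 10, 15}. A
trailing rather than centred window was chosen because prevalent cases at
age k arose from past, not future, incidence. With no survival limit cases
persist for life and prevalence is the running cumulative sum.

Myotonic dystrophy type 1 gets onset-dependent rules: onset at ≥31 years
carries normal life expectancy; childhood-onset (<10 y, the complement of the
stated 10–30 y early-adult range) and early-adult-onset cases survive fully
for 10 years, are 80% alive at exactly 10 years post-onset, and then decline
linearly to zero at a mean age at death of 45 y (childhood) or 52 y
(early-adult). These are implemented on the same per-year snapshot grid, so a
cohort with exclusively late onset reproduces the lifelong-survival result
identically.

The literature-comparison derivations are closed forms with the printed
rounding conventions (1 decimal for range bounds, 2 for means): the
C9orf72-FTD range is the mutation-positive fraction of FTD times median FTD
prevalence; C9orf72-ALS weights the familial (0.4 × 0.1) and sporadic
(0.07 × 0.9) expansion fractions over the reported ALS prevalence range; the
40-CAG HD figure is the 7.4% case fraction times overall HD prevalence.

The packaged epidemiological inputs are synthetic (see below); the model is
validated by its algebraic identities (linearity, conservation,
oracle-equivalent survival windows, parameter recovery), not by reproducing
country-specific case counts, which require national statistics and registry
onset tables that cannot ship with the package.

## HTT exon-1 structure

The repeat region is modelled as an ordered grammar
Q1 = (CAG)≥1, Q2 = (CAACAG)*, P1 = (CCGCCA)0..1, P2 = (CCG)*, P3 = (CCT)*,
between two 12 bp flank anchors modelled on the GRCh38 exon-1 context
(configurable; the packaged anchors are used consistently by the simulator
and the decomposer). Decomposition is greedy left-to-right maximal matching
with zero mismatch tolerance; the grammar is unambiguous under greedy
matching because consecutive motifs differ at their first discriminating
base, a claim guarded in the tests by an anchored regular-expression oracle
with counting groups. Residue between the parsed elements and the 3' anchor
yields the label `other` with the offset logged. A read is *spanning* when
both anchors of the analyzed region are present and the enclosed sequence is
clean A/C/G/T (an N anywhere in the region disqualifies the read).

Structure labels follow (q2, p1): canonical (1,1), Q2 duplication (2,1),
Q2 loss (0,1), P1 loss (1,0), Q2–P1 loss (0,0). `partial_Q2_loss` — a
dangling CAA trimer without its CAG — is this package's encoding of a state
the literature names but never sequence-defines; it should not be read as
ground truth.

Phasing uses two runs. Run 1 decomposes reads spanning the whole region
(Q1 included) and types the smaller allele by majority vote over supporting
reads, preferring groups whose CAG count matches the upstream caller's
smaller allele size. Run 2 decomposes reads spanning only Q2..P3 (anchored
by ≥2 trailing CAG copies inside the tract); the structure *not* matching
run 1's assignment goes to the larger allele, which at 150 bp typically
cannot be spanned in full. Ties break by higher read support, then
canonical-first; a majority below 80% of informative reads (or support below
2 reads) flags the call low-confidence. When run 1 also contains a group at
the larger caller size, both alleles are typed directly from spanning reads.

The population table reports per-population structure proportions (rows sum
to 1) and CAG-size-by-structure comparisons via Kruskal–Wallis plus pairwise
Dunn z-tests with Holm adjustment; Dunn's test is implemented in-package
(standard rank statistics with tie correction) as no installed library
provides it.

## Population summaries and the intermediate/pathogenic correlation

Summaries are allele-level: median, quartiles and the 99.9th percentile
(numpy's linear-interpolation convention by default; the convention is
configurable since published percentile tables rarely state one), plus
intermediate and pathogenic allele fractions. The two fractions are kept
disjoint: loci with a literature intermediate cutoff use intermediate =
`[intermediate_min, premutation_min)` and pathogenic = `[premutation_min,
∞)`; loci whose intermediate range *is* the premutation band use
`[premutation_min, full_min)` and `[full_min, ∞)`. The correlation between
the two fractions over population × gene points uses Spearman rank
correlation (average ranks on ties) with a two-tailed p; loci where either
fraction is zero across all populations are excluded, and a constant vector
reports the correlation as absent rather than NaN.

## Synthetic data

The generator replaces access-controlled cohort data and defines the
conditions under which the package is tested:

* **Cohort.** 82,176 individuals split EUR 59,568 / AFR 12,786 / AMR 5,674 /
  SAS 2,882 / EAS 1,266, 41.5% male. Each locus × population allele
  distribution is a discretized log-normal core (median at a typical normal
  allele size, σ_log = 0.2, truncated below the tail start) plus a geometric
  upper tail crossing all thresholds. Tail weights are calibrated so the
  expected full-mutation carrier frequency per locus equals the frequency
  observed in the study cohort (e.g. C9orf72 1/839, DMPK 1/1786, HTT 1/4109;
  monoallelic 1/101 for FXN and biallelic 1/712 for RFC1 via Hardy–Weinberg
  allele frequencies), with mean-preserving log-normal per-population
  multipliers (σ = 0.4, drawn once from a fixed condition seed so they are
  invariant across simulation seeds) that couple intermediate and pathogenic
  tail mass within a population — the mechanism by which the correlation
  analysis has signal to recover. Tail weights are capped at 0.05.
* **HTT reads.** Reads of 150 bp sampled uniformly over padded haplotypes;
  read counts are set so the expected number of fully spanning reads equals
  the requested spanning depth (default 30×), or plain coverage for alleles
  too long to span. The cohort variant draws a short allele (CAG ≈ 17,
  capped at 24 so it is always spannable) and a long allele (CAG ≈ 38,
  floored at 26), with structure labels at configurable per-population
  frequencies and label-dependent CAG shifts.
* **Epidemiological inputs.** A smooth flat-then-declining pyramid with ±5%
  seeded jitter (default 67 million people), a normal onset distribution
  discretized onto 5-year bins, and a logistic penetrance curve. These have
  plausible shapes only; none is a biological estimate.

What the generator does *not* model: sequencing error and mappability,
somatic instability, repeat interruptions outside HTT, linkage between loci,
within-population substructure, and non-random ascertainment. Passing tests
therefore demonstrate correctness of the computations under known
generating conditions, not calibration against real cohorts.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full 82,176-sample cohort
simulation once, 2,000 binomial replicates for interval coverage, 200
diploid HTT samples at 30× for phasing, 500 fuzzed reads for the decomposer
round-trip, 200 random incidence vectors per survival window, and a
10⁶-person cohort for mutation-frequency recovery (expected relative error
≈ 0.8% at f = 1/64). These sizes keep every stochastic check's Monte-Carlo
error well inside its tolerance while completing in seconds.

## Known limitations

* Thresholds not printed in running text ship as literature-compiled
  defaults; users with locus-specific conventions should override them.
* The prevalence model's survival window operates on attained-age bins;
  onset-age stratification is implemented only where the method defines it
  (DM1). Sensitivity to this choice is untested against external data.
* The HTT decomposer is exact-match only by design; a mismatch-tolerant mode
  would require an error model the method does not define.
* FMR1 (premutation/full discrimination unreliable at 150 bp) is outside the
  registry's default scope, as are loci caused by non-reference motif
  insertions (except RFC1, which has a dedicated calling convention).
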