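# redprev

Carrier frequencies and genetic prevalence of repeat expansion disorders
(REDs) from population-scale genotype data.

REDs — Huntington disease, myotonic dystrophy type 1, C9orf72-ALS/FTD, the
spinocerebellar ataxias, Friedreich ataxia, CANVAS, SBMA and relatives — are
caused by expansion of short (1–6 bp) tandem repeats. Because they present
heterogeneously and are ascertained clinically, their prevalence is easy to
underestimate. Given a cohort's per-sample repeat-length calls (e.g.
ExpansionHunter output after QC), this package answers two questions: *how
many people carry a premutation or full-mutation allele*, and *how many
people would be expected to be affected, given age at onset, penetrance and
survival*.

The core computations:

* **Carrier frequency.** At locus ℓ with `count` carriers among `n`
  genotyped individuals, the frequency is reported as "1 in x" with
  `x = round(n / count)`, a per-100k transform `100000/x`, and a 95% Wilson
  score interval on p = count/n:
  `(p + z²/2n ± z√(pq/n + z²/4n²)) / (1 + z²/n)`, z = 1.96.
  Carriers are counted per individual under the correct inheritance model
  (dominant / recessive mono- and biallelic / X-linked hemizygous).
* **Expected cases by age.** `M_k = f · N_k · p_k · pen(k)` on 5-year age
  bins (f mutation frequency, N_k population pyramid, p_k normalized onset
  proportions, pen optional age-related penetrance), converted to prevalence
  by a trailing median-survival window (onset-dependent rules for DM1), and
  totalled to a per-100,000 rate.
* **HTT exon-1 structure.** Spanning reads are decomposed into the ordered
  elements Q1 (CAG), Q2 (CAACAG), P1 (CCGCCA), P2 (CCG), P3 (CCT) by greedy
  maximal matching, labelled (canonical, Q2 duplication/loss, P1 loss, …),
  and phased size-to-structure with a two-run scheme for alleles too long to
  span at 150 bp.
* **Population summaries.** Allele-length percentiles (incl. the 99.9th) per
  locus × population, and the Spearman correlation between intermediate and
  pathogenic allele fractions.
* **Synthetic data.** Cohorts, HTT reads and epidemiological inputs with
  known ground truth, calibrated to the study conditions, so the whole chain
  is testable without restricted data.

See `docs/methods.md` for models, defaults and assumptions.

## Worked example

```python
>>> import redprev as rp
>>> f = rp.carrier_frequency(290, 82176)   # full-mutation carriers in a cohort
>>> print(f)
1 in 283
>>> round(f.per_100k_low, 1), round(f.per_100k_high, 1)
(314.6, 395.8)
>>> rp.reported_prevalence_c9ftd((0.04, 0.29), 83.5)
{'low': 3.3, 'high': 24.2, 'mean': 13.78}
```

290 full-mutation carriers among 82,176 genomes is 1 person in 283, with a
95% Wilson interval of roughly 315–396 carriers per 100,000. The second call
derives the literature prevalence of C9orf72-FTD: 4–29% of FTD patients
carry the expansion, so at a median FTD prevalence of 83.5 per 100,000 the
expected range is 3.3–24.2 per 100,000 (mean 13.78).

The repository is organised as an analysis project: the numbered scripts
under `analysis/` (simulate cohort → carrier frequencies → prevalence model
→ population distributions → HTT structure) are thin drivers over the
library in `src/redprev` and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_carrier_frequencies.py
python analysis/03_prevalence_model.py
python analysis/04_population_distributions.py
python analysis/05_htt_structure.py
```

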