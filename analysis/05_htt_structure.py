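"""HTT exon-1 repeat-structure decomposition and phasing across populations.

Simulates diploid HTT repeat regions (150 bp reads, 30x spanning depth) with
population-specific structure-label frequencies (non-canonical alleles
enriched in AFR/EAS), phases CAG size to structure with the two-run scheme,
and tabulates structure proportions per population plus the CAG-size-by-
structure comparison (Kruskal-Wallis with Dunn post-hoc z-tests).
"""

import argparse
from pathlib import Path

import pandas as pd

from redprev import phase_genotype
from redprev.httstruct import q1_by_structure_tests, structure_population_table
from redprev.simulate import simulate_htt_cohort

ROOT = Path(__file__).resolve().parents[1]

LABEL_FREQS = {
    "EUR": {"canonical": 0.93, "Q2_duplication": 0.03, "Q2_loss": 0.01,
            "P1_loss": 0.02, "Q2_P1_loss": 0.01},
    "AFR": {"canonical": 0.80, "Q2_duplication": 0.04, "Q2_loss": 0.04,
            "P1_loss": 0.09, "Q2_P1_loss": 0.03},
    "EAS": {"canonical": 0.85, "Q2_duplication": 0.03, "Q2_loss": 0.03,
            "P1_loss": 0.07, "Q2_P1_loss": 0.02},
}
N_PER_POP = {"EUR": 300, "AFR": 150, "EAS": 100}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    allele_rows = []
    n_agree = n_alleles = 0
    for i, (pop, n) in enumerate(N_PER_POP.items()):
        samples = simulate_htt_cohort(
            n, label_freqs=LABEL_FREQS[pop], population=pop, seed=args.seed + i
        )
        for s in samples:
            geno = phase_genotype(s["reads"], s["sizes"])
            for allele, truth in (
                (geno.smaller, s["truth_smaller"]),
                (geno.larger, s["truth_larger"]),
            ):
                if allele is None:
                    continue
                n_alleles += 1
                n_agree += allele.post_q1 == truth.post_q1 and allele.q1 == truth.q1
                allele_rows.append(
                    {"population": pop, "label": allele.label, "q1": allele.q1}
                )

    alleles = pd.DataFrame(allele_rows)
    props = structure_population_table(alleles)
    tests = q1_by_structure_tests(alleles)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    props.to_csv(results / "htt_structure_by_population.tsv", sep="\t", index=False)
    tests["pairwise"].to_csv(results / "htt_q1_by_structure_tests.tsv", sep="\t", index=False)

    print(props.to_string(index=False))
    print(f"\nphasing agreement with simulation truth: {n_agree}/{n_alleles} "
          f"({100 * n_agree / n_alleles:.1f}%)")
    print(f"CAG size differs across structures: Kruskal-Wallis H = "
          f"{tests['kruskal_h']:.1f}, P = {tests['kruskal_p']:.2e}")
    print(f"structure table -> {results / 'htt_structure_by_population.tsv'}")


if __name__ == "__main__":
    main()
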