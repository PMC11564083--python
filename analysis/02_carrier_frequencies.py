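"""Carrier counts and "1 in x" frequencies with Wilson intervals.

Reads the simulated allele table (resimulating if 01 has not been run),
counts premutation/full-mutation carriers per locus under the correct
inheritance model, and writes the forest-plot table of carrier frequencies
overall and per population.  Also reports the cohort-wide dominant + X-linked
carrier frequency in the "1 in x" form.
"""

import argparse
from pathlib import Path

from redprev import (
    carrier_frequency,
    count_carriers,
    frequency_table,
    load_registry,
    read_allele_table,
)
from redprev.plotting import forest_plot
from redprev.registry import Inheritance
from redprev.simulate import default_cohort_spec, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    registry = load_registry()
    table_path = ROOT / "scratch" / "cohort_alleles.tsv"
    if table_path.exists():
        table = read_allele_table(table_path)
    else:
        print("no simulated table found; drawing one now")
        table, _ = simulate_cohort(default_cohort_spec(registry, seed=args.seed), registry)

    counts_all = count_carriers(table, registry)
    counts_pop = count_carriers(table, registry, stratify_by_population=True)
    freq = frequency_table(counts_all + counts_pop)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    freq.to_csv(results / "carrier_frequencies.tsv", sep="\t", index=False)
    forest_plot(
        freq[(freq["population"] == "ALL")],
        results / "forest_carriers.png",
        title="Carrier frequencies, synthetic cohort",
    )

    # cohort-wide dominant + X-linked carrier individuals
    dom = [c for c in counts_all
           if c.inheritance is not Inheritance.AUTOSOMAL_RECESSIVE]
    n = max(c.n_genotyped for c in dom)
    full = sum(c.n_full_carriers for c in dom)
    pre = sum(c.n_premutation_carriers for c in dom)
    print(f"dominant/X-linked loci: {full} full-mutation carriers "
          f"-> {carrier_frequency(full, n)}")
    print(f"dominant/X-linked loci: {pre} premutation carriers "
          f"-> {carrier_frequency(pre, n)}")
    print(f"frequency table ({len(freq)} rows) -> {results / 'carrier_frequencies.tsv'}")


if __name__ == "__main__":
    main()
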