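"""Synthetic cohorts, HTT reads and epidemiological inputs with known truth.

The real study cohorts (access-controlled medical WGS programs) cannot ship
with a package, so every pipeline stage is exercised on synthetic data whose
generating parameters are recorded alongside the output:

* ``simulate_cohort`` draws a per-sample allele table in the exact dialect the
  cohort classifier reads.  Each locus x population allele distribution is a
  discretized log-normal core (the normal-allele bulk) plus a geometric upper
  tail that crosses the intermediate, premutation and full-mutation
  thresholds — the simplest long-tail shape that reproduces the qualitative
  look of real repeat-length distributions.  Default tail weights are
  calibrated so the expected full-mutation carrier frequency per locus equals
  the frequency observed in the 82,176-genome study cohort, and population
  sizes default to that cohort's ancestry split.
* ``simulate_htt_reads`` emits 150 bp reads over a diploid HTT exon-1 repeat
  region with known element structure per allele, at a chosen expected
  spanning depth, driving the decomposer and two-run phasing tests.
* ``simulate_epi_inputs`` builds a plausibly shaped population pyramid, a
  discretized-normal age-at-onset distribution and a logistic penetrance
  curve (synthetic, not biological) for the prevalence model.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .httstruct import (
    HttStructure,
    RepeatGrammar,
    default_grammar,
    sequence_from_structure,
)
from .registry import AlleleClass, Inheritance, LocusRegistry, classify_allele, load_registry

__all__ = [
    "PopulationAlleleModel",
    "CohortSpec",
    "ReadSimSpec",
    "PAPER_POPULATION_SIZES",
    "PAPER_FULL_CARRIER_FREQS",
    "default_cohort_spec",
    "sample_allele_sizes",
    "simulate_cohort",
    "simulate_htt_reads",
    "simulate_htt_cohort",
    "simulate_epi_inputs",
    "write_fasta",
    "read_fasta",
]

# Ancestry split of the study cohort (unrelated, non-neurological genomes).
PAPER_POPULATION_SIZES = {
    "EUR": 59_568,
    "AFR": 12_786,
    "AMR": 5_674,
    "SAS": 2_882,
    "EAS": 1_266,
}

# Published full-mutation carrier frequencies ("1 in x" -> frequency); zero
# for loci with no full-mutation carriers observed.  AR is a male frequency;
# FXN is the monoallelic carrier frequency; RFC1 the biallelic frequency.
PAPER_FULL_CARRIER_FREQS = {
    "C9orf72": 1 / 839,
    "DMPK": 1 / 1786,
    "AR": 1 / 2561,
    "HTT": 1 / 4109,
    "ATXN2": 1 / 5136,
    "CACNA1A": 1 / 5136,
    "ATXN1": 1 / 6321,
    "ATXN7": 1 / 41_077,
    "TBP": 1 / 41_077,
    "JPH3": 1 / 82_176,
    "ATN1": 1 / 82_176,
    "ATXN3": 0.0,
    "PPP2R2B": 0.0,
    "NOTCH2NLC": 0.0,
    "FXN": 1 / 101,
    "RFC1": 1 / 712,
}

# Typical normal-allele medians (repeat units) for the log-normal core.
_CORE_MEDIANS = {
    "HTT": 17, "JPH3": 13, "DMPK": 12, "C9orf72": 5, "ATXN1": 29, "ATXN2": 22,
    "ATXN3": 21, "CACNA1A": 11, "ATXN7": 10, "PPP2R2B": 10, "TBP": 32,
    "ATN1": 15, "NOTCH2NLC": 15, "FXN": 8, "RFC1": 11, "AR": 21,
}

# Fixed seed for condition-building randomness (population multipliers):
# part of the study conditions, invariant across simulation seeds.
_CONDITION_SEED = 20_240_301


@dataclass(frozen=True)
class PopulationAlleleModel:
    """Allele-length model for one locus in one population.

    Core: ``round(exp(Normal(meanlog, sdlog)))`` truncated to
    ``[1, tail_start - 1]``.  With probability ``tail_weight`` the allele is
    instead drawn from the tail: ``tail_start + (Geometric(tail_decay) - 1)``.
    """

    meanlog: float
    sdlog: float
    tail_start: int
    tail_weight: float
    tail_decay: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tail_weight <= 0.05:
            raise ValueError(f"tail weight must lie in [0, 0.05], got {self.tail_weight}")
        if not 0.0 < self.tail_decay < 1.0:
            raise ValueError("tail decay must lie in (0, 1)")
        if self.tail_start < 2:
            raise ValueError("tail start must be >= 2")

    def prob_at_least(self, size: int) -> float:
        """Expected fraction of alleles at or above ``size`` (tail only)."""
        if size <= self.tail_start:
            return self.tail_weight
        return self.tail_weight * (1.0 - self.tail_decay) ** (size - self.tail_start)


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic genotyped cohort."""

    n_samples: dict[str, int]
    loci: dict[str, dict[str, PopulationAlleleModel]]
    sex_ratio: float = 0.415  # fraction male, matching the study cohort
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples:
            raise ValueError("cohort spec: no populations")
        if any(n < 0 for n in self.n_samples.values()):
            raise ValueError("cohort spec: negative sample count")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("cohort spec: sex ratio must lie in [0, 1]")
        for gene, models in self.loci.items():
            missing = set(self.n_samples) - set(models)
            if missing:
                raise ValueError(f"cohort spec: locus {gene} missing populations {sorted(missing)}")


def _calibrate_tail(
    target_full_freq: float, tail_start: int, full_min: int
) -> tuple[float, float]:
    """Choose (tail_weight, tail_decay) so that P(size >= full_min) equals the
    target allele frequency, with tail weight within its allowed range."""
    span = full_min - tail_start
    for decay in (0.12, 0.05, 0.02, 0.005):
        if target_full_freq == 0.0:
            return 0.0, decay
        weight = target_full_freq / (1.0 - decay) ** span
        if weight <= 0.05:
            return weight, decay
    raise ValueError("cannot calibrate tail within the allowed weight range")


def _allele_freq_from_carrier_freq(gene: str, inheritance: Inheritance, f: float) -> float:
    """Convert the published carrier frequency into a per-allele frequency."""
    if f == 0.0:
        return 0.0
    if inheritance is Inheritance.X_LINKED:
        return f  # male (hemizygous) frequency
    if gene == "FXN":  # monoallelic carrier frequency: 2a(1-a) = f
        return (1.0 - math.sqrt(1.0 - 2.0 * f)) / 2.0
    if gene == "RFC1":  # biallelic frequency: a^2 = f
        return math.sqrt(f)
    return 1.0 - math.sqrt(1.0 - f)  # dominant carriers: 1-(1-a)^2 = f


def default_cohort_spec(
    registry: LocusRegistry | None = None,
    n_samples: dict[str, int] | None = None,
    seed: int = 0,
    population_variation: float = 0.4,
) -> CohortSpec:
    """The packaged study conditions: paper-split population sizes and tail
    weights calibrated to the published per-locus carrier frequencies.

    ``population_variation`` is the log-scale spread of per-population tail
    multipliers (mean-preserving across the cohort); it couples intermediate
    and pathogenic frequencies within each population, the signature the
    correlation analysis looks for.
    """
    registry = registry or load_registry()
    n_samples = dict(n_samples or PAPER_POPULATION_SIZES)
    pops = sorted(n_samples)
    weights = np.array([n_samples[p] for p in pops], dtype=float)
    weights = weights / weights.sum() if weights.sum() > 0 else weights

    cond_rng = np.random.default_rng(_CONDITION_SEED)
    loci: dict[str, dict[str, PopulationAlleleModel]] = {}
    for locus in registry:
        gene = locus.gene_symbol
        target_carrier = PAPER_FULL_CARRIER_FREQS.get(gene, 0.0)
        a_full = _allele_freq_from_carrier_freq(gene, locus.inheritance, target_carrier)
        tail_start = (
            locus.intermediate_min
            if locus.intermediate_min is not None
            else max(2, locus.premutation_min - 5)
        )
        weight, decay = _calibrate_tail(a_full, tail_start, locus.full_min)

        # mean-preserving per-population tail multipliers and location shifts
        mult = np.exp(cond_rng.normal(0.0, population_variation, len(pops)))
        mult = mult / float(weights @ mult) if weight > 0 else np.ones(len(pops))
        shifts = cond_rng.normal(0.0, 0.05, len(pops))

        meanlog = math.log(_CORE_MEDIANS.get(gene, 12))
        models = {}
        for i, pop in enumerate(pops):
            models[pop] = PopulationAlleleModel(
                meanlog=meanlog + float(shifts[i]),
                sdlog=0.2,
                tail_start=tail_start,
                tail_weight=min(0.05, weight * float(mult[i])),
                tail_decay=decay,
            )
        loci[gene] = models
    return CohortSpec(n_samples=n_samples, loci=loci, seed=seed)


def sample_allele_sizes(
    model: PopulationAlleleModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` allele sizes (repeat units) from a population model."""
    core = np.rint(np.exp(rng.normal(model.meanlog, model.sdlog, n))).astype(int)
    core = np.clip(core, 1, model.tail_start - 1)
    in_tail = rng.random(n) < model.tail_weight
    n_tail = int(in_tail.sum())
    if n_tail:
        core[in_tail] = model.tail_start + rng.geometric(model.tail_decay, n_tail) - 1
    return core


def _truth_counts(
    gene: str,
    pop: str,
    inheritance: Inheritance,
    a1: np.ndarray,
    a2: np.ndarray,
    classes1: np.ndarray,
    classes2: np.ndarray,
    hemizygous: np.ndarray,
    full_min: int,
) -> dict:
    alleles = np.concatenate([classes1, classes2[~hemizygous]])
    n_alleles = len(alleles)
    row = {
        "locus": gene,
        "population": pop,
        "n_samples": len(a1),
        "n_alleles": n_alleles,
        "n_intermediate_alleles": int(np.sum(alleles == AlleleClass.INTERMEDIATE)),
        "n_premutation_alleles": int(np.sum(alleles == AlleleClass.PREMUTATION)),
        "n_full_alleles": int(np.sum(alleles == AlleleClass.FULL)),
    }
    if inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        exp1 = a1 >= full_min
        exp2 = a2 >= full_min
        row["n_biallelic"] = int(np.sum(exp1 & exp2))
        row["n_monoallelic"] = int(np.sum(exp1 ^ exp2))
        row["n_premutation_carriers"] = 0
        row["n_full_carriers"] = 0
    else:
        top = np.where(hemizygous, classes1, np.maximum(classes1, classes2))
        row["n_full_carriers"] = int(np.sum(top == AlleleClass.FULL))
        row["n_premutation_carriers"] = int(np.sum(top == AlleleClass.PREMUTATION))
        row["n_biallelic"] = 0
        row["n_monoallelic"] = 0
    return row


def simulate_cohort(
    spec: CohortSpec, registry: LocusRegistry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort allele table plus its ground-truth count table.

    Returns ``(table, truth)``: the table is in the cohort classifier's TSV
    dialect; the truth frame records realized allele-class and carrier counts
    per locus x population.
    """
    registry = registry or load_registry()
    rng = np.random.default_rng(spec.seed)
    pops = sorted(spec.n_samples)

    table_parts: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for pop in pops:
        n = spec.n_samples[pop]
        if n == 0:
            continue
        sample_ids = np.array([f"{pop}_{i:06d}" for i in range(n)])
        is_male = rng.random(n) < spec.sex_ratio
        sex = np.where(is_male, "male", "female")
        for gene in sorted(spec.loci):
            locus = registry[gene]
            model = spec.loci[gene][pop]
            a1 = sample_allele_sizes(model, n, rng)
            a2 = sample_allele_sizes(model, n, rng)
            hemi = (
                is_male.copy()
                if locus.inheritance is Inheritance.X_LINKED
                else np.zeros(n, dtype=bool)
            )
            lo = np.where(hemi, a1, np.minimum(a1, a2))
            hi = np.maximum(a1, a2)

            bands = np.array(
                [0, locus.intermediate_min or locus.premutation_min,
                 locus.premutation_min, locus.full_min]
            )
            classes1 = np.searchsorted(bands, lo, side="right") - 1
            classes2 = np.searchsorted(bands, hi, side="right") - 1

            table_parts.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_ids,
                        "locus": gene,
                        "allele1": lo.astype(float),
                        "allele2": np.where(hemi, np.nan, hi.astype(float)),
                        "sex": sex,
                        "population": pop,
                        "qc_pass": True,
                    }
                )
            )
            truth_rows.append(
                _truth_counts(
                    gene, pop, locus.inheritance, lo, hi, classes1, classes2,
                    hemi, locus.full_min,
                )
            )
    table = pd.concat(table_parts, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return table, truth


# --- HTT read simulation ----------------------------------------------------


@dataclass(frozen=True)
class ReadSimSpec:
    """Read-simulation settings for one diploid HTT repeat region."""

    structures: tuple[HttStructure, HttStructure]
    read_length: int = 150
    spanning_depth: float = 30.0
    grammar: RepeatGrammar = field(default_factory=default_grammar)
    seed: int = 0

    def __post_init__(self) -> None:
        longest_motif = max(len(m) for _, m, _, _ in self.grammar.elements)
        needed = longest_motif + len(self.grammar.flank5) + len(self.grammar.flank3)
        if self.read_length < needed:
            raise ValueError(
                f"read length {self.read_length} shorter than longest motif plus anchors"
            )


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def simulate_htt_reads(spec: ReadSimSpec) -> tuple[list[str], dict]:
    """Sample reads uniformly over a padded diploid haplotype pair.

    The number of reads per allele is set so the *expected* number of reads
    spanning the anchored region (all elements, Q1 included) equals
    ``spanning_depth``; when the region plus anchors exceeds the read length
    no read can span it and plain sequence coverage is matched instead (these
    alleles drive the two-run phasing path).

    Returns ``(reads, truth)`` where truth records each allele's generating
    structure and whether it was spannable with Q1 included.
    """
    rng = np.random.default_rng(spec.seed)
    grammar = spec.grammar
    reads: list[str] = []
    truth: dict = {"alleles": [], "read_length": spec.read_length}
    pad = spec.read_length
    for allele_idx, structure in enumerate(spec.structures):
        region = sequence_from_structure(structure, grammar, with_flanks=True)
        hap = _random_dna(rng, pad) + region + _random_dna(rng, pad)
        total_positions = len(hap) - spec.read_length + 1
        span_positions = spec.read_length - len(region) + 1
        spannable = span_positions > 0
        if spannable:
            n_reads = max(1, round(spec.spanning_depth * total_positions / span_positions))
        else:
            n_reads = max(1, round(spec.spanning_depth * total_positions / spec.read_length))
        starts = rng.integers(0, total_positions, n_reads)
        reads.extend(hap[s : s + spec.read_length] for s in starts)
        truth["alleles"].append(
            {
                "allele_index": allele_idx,
                "structure": structure,
                "spannable_with_q1": spannable,
                "region_length": len(region),
                "n_reads": int(n_reads),
            }
        )
    return reads, truth


# Default per-structure q1 shifts for the HTT cohort simulator: shorter CAG
# tracts travel with Q2 duplication, longer ones with Q2 / Q2-P1 loss.
_DEFAULT_LABEL_FREQS = {
    "canonical": 0.90,
    "Q2_duplication": 0.03,
    "Q2_loss": 0.02,
    "P1_loss": 0.04,
    "Q2_P1_loss": 0.01,
}
_LABEL_PARAMS = {
    "canonical": dict(q2=1, p1=1, shift=0),
    "Q2_duplication": dict(q2=2, p1=1, shift=-3),
    "Q2_loss": dict(q2=0, p1=1, shift=4),
    "P1_loss": dict(q2=1, p1=0, shift=1),
    "Q2_P1_loss": dict(q2=0, p1=0, shift=5),
}


def _draw_structure(
    rng: np.random.Generator, q1: int, label: str, q1_lo: int = 5, q1_hi: int = 60
) -> HttStructure:
    params = _LABEL_PARAMS[label]
    return HttStructure(
        q1=int(np.clip(q1 + params["shift"], q1_lo, q1_hi)),
        q2=params["q2"],
        p1=params["p1"],
        p2=int(rng.integers(6, 9)),
        p3=int(rng.integers(1, 4)),
    )


def simulate_htt_cohort(
    n_samples: int,
    label_freqs: dict[str, float] | None = None,
    population: str = "EUR",
    spanning_depth: float = 30.0,
    seed: int = 0,
    large_allele_mean: float = 38.0,
) -> list[dict]:
    """Simulate per-sample HTT reads with known diploid structure truth.

    Each sample gets a smaller allele (CAG around 17, spannable with Q1) and
    a larger allele (CAG around ``large_allele_mean``, typically only
    spannable without Q1), with structure labels drawn from ``label_freqs``.
    Returns one dict per sample: ``reads``, ``sizes`` (the upstream caller's
    allele sizes), ``truth_smaller``, ``truth_larger``, ``population``.
    """
    label_freqs = label_freqs or _DEFAULT_LABEL_FREQS
    labels = sorted(label_freqs)
    probs = np.array([label_freqs[lab] for lab in labels], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    samples = []
    for i in range(n_samples):
        small_q1 = int(np.clip(np.rint(rng.normal(17, 2)), 10, 22))
        large_q1 = int(np.clip(np.rint(rng.normal(large_allele_mean, 6)), 26, 60))
        lab_small, lab_large = rng.choice(labels, 2, p=probs)
        # cap the smaller allele so spanning reads (Q1 included) exist at 150 bp
        s_small = _draw_structure(rng, small_q1, str(lab_small), q1_lo=5, q1_hi=24)
        s_large = _draw_structure(rng, large_q1, str(lab_large), q1_lo=26, q1_hi=65)
        reads, _ = simulate_htt_reads(
            ReadSimSpec(
                structures=(s_small, s_large),
                spanning_depth=spanning_depth,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        samples.append(
            {
                "sample_id": f"{population}_HTT_{i:05d}",
                "population": population,
                "reads": reads,
                "sizes": (s_small.q1, s_large.q1),
                "truth_smaller": s_small,
                "truth_larger": s_large,
            }
        )
    return samples


# --- epidemiological inputs -------------------------------------------------


def simulate_epi_inputs(
    seed: int = 0,
    total_population: float = 67_000_000,
    onset_mean: float = 60.0,
    onset_sd: float = 12.0,
    n_onset_cases: int = 1000,
    penetrance_midpoint: float = 50.0,
    penetrance_scale: float = 8.0,
    max_age: int = 90,
):
    """Synthetic pyramid, onset distribution and penetrance curve.

    The pyramid follows a smooth, roughly constant-then-declining shape with
    mild seeded jitter; onset is a normal distribution discretized onto
    5-year bins; penetrance is a logistic curve in age (synthetic shape for
    testing, not a biological estimate).
    """
    from scipy import stats as _st

    from .prevalence import OnsetDistribution, PenetranceCurve, PopulationPyramid

    rng = np.random.default_rng(seed)
    starts = np.arange(0, max_age + 1, 5)

    mids = starts + 2.5
    base = np.where(mids < 50, 1.0, np.exp(-(mids - 50) / 20.0))
    base = base * (1.0 + rng.uniform(-0.05, 0.05, len(base)))
    pyramid = PopulationPyramid(starts, total_population * base / base.sum())

    edges = np.append(starts, starts[-1] + 5).astype(float)
    mass = np.diff(_st.norm.cdf(edges, loc=onset_mean, scale=onset_sd))
    onset = OnsetDistribution(starts, np.round(n_onset_cases * mass / mass.sum(), 6))

    ages = np.arange(0.0, max_age + 6.0, 1.0)
    fractions = 1.0 / (1.0 + np.exp(-(ages - penetrance_midpoint) / penetrance_scale))
    penetrance = PenetranceCurve(ages, fractions)
    return pyramid, onset, penetrance


# --- text-format helpers ----------------------------------------------------


def write_fasta(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    """Write reads as uncompressed FASTA (one record per read)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(r), id=f"{prefix}_{i:06d}", description="") for i, r in enumerate(reads)
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[str]:
    """Read sequences (one per record) from FASTA."""
    from Bio.SeqIO import parse

    return [str(rec.seq).upper() for rec in parse(str(path), "fasta")]
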