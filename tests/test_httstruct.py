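"""HTT exon-1 read decomposition, phasing and structure tables."""

import re

import numpy as np
import pandas as pd
import pytest

from redprev.httstruct import (
    DEFAULT_FLANK3,
    DEFAULT_FLANK5,
    HttStructure,
    NonSpanningReadError,
    decompose,
    default_grammar,
    is_spanning,
    phase_genotype,
    q1_by_structure_tests,
    sequence_from_structure,
    structure_label,
    structure_population_table,
)
from redprev.simulate import ReadSimSpec, simulate_htt_reads

_ORACLE = re.compile(
    rf"^{DEFAULT_FLANK5}((?:CAG)+)((?:CAACAG)*)(CAA)?(CCGCCA)?((?:CCG)*)((?:CCT)*){DEFAULT_FLANK3}$"
)


def regex_oracle(read):
    """Anchored regular-expression decomposition with counting groups."""
    m = _ORACLE.match(read)
    if m is None:
        return None
    g = m.groups()
    return (
        len(g[0]) // 3,
        len(g[1]) // 6,
        1 if g[3] else 0,
        len(g[4]) // 3,
        len(g[5]) // 3,
        g[2] is not None,
    )


def random_structure(rng):
    q2 = int(rng.integers(0, 3))
    return HttStructure(
        q1=int(rng.integers(5, 46)),
        q2=q2,
        p1=int(rng.integers(0, 2)),
        p2=int(rng.integers(0, 11)),
        p3=int(rng.integers(0, 4)),
        partial_q2=bool(q2 == 0 and rng.random() < 0.2),
    )


class TestDecompose:
    def test_canonical_read(self):
        s = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        out = decompose(sequence_from_structure(s))
        assert (out.q1, out.q2, out.p1, out.p2, out.p3) == (19, 1, 1, 7, 2)
        assert out.label == "canonical"

    @pytest.mark.parametrize(
        "q2,p1,partial,label",
        [
            (1, 1, False, "canonical"),
            (2, 1, False, "Q2_duplication"),
            (0, 1, False, "Q2_loss"),
            (0, 1, True, "partial_Q2_loss"),
            (1, 0, False, "P1_loss"),
            (0, 0, False, "Q2_P1_loss"),
            (3, 1, False, "other"),
        ],
    )
    def test_structure_labels(self, q2, p1, partial, label):
        s = HttStructure(q1=21, q2=q2, p1=p1, p2=7, p3=2, partial_q2=partial)
        assert s.label == label
        assert decompose(sequence_from_structure(s)).label == label

    def test_round_trip_and_regex_oracle_on_fuzzed_reads(self, rng):
        for _ in range(200):
            truth = random_structure(rng)
            read = sequence_from_structure(truth)
            out = decompose(read)
            assert (out.q1, out.q2, out.p1, out.p2, out.p3, out.partial_q2) == (
                truth.q1, truth.q2, truth.p1, truth.p2, truth.p3, truth.partial_q2
            )
            assert regex_oracle(read) == (
                truth.q1, truth.q2, truth.p1, truth.p2, truth.p3, truth.partial_q2
            )

    def test_decompose_without_q1_types_post_q1_elements(self):
        s = HttStructure(q1=45, q2=2, p1=1, p2=8, p3=2)
        read = "CAG" * 6 + sequence_from_structure(s, with_flanks=False)[45 * 3:] + DEFAULT_FLANK3
        out = decompose(read, include_q1=False)
        assert out.q1 == -1  # unknown in this mode
        assert (out.q2, out.p1, out.p2, out.p3) == (2, 1, 8, 2)

    def test_non_spanning_read_raises(self):
        s = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        truncated = sequence_from_structure(s)[:-15]
        with pytest.raises(NonSpanningReadError):
            decompose(truncated)

    def test_unparsed_residue_labels_other(self):
        read = DEFAULT_FLANK5 + "CAG" * 10 + "TTTTT" + DEFAULT_FLANK3
        assert decompose(read).label == "other"

    def test_deterministic_and_order_free(self, rng):
        reads = [sequence_from_structure(random_structure(rng)) for _ in range(20)]
        first = [decompose(r) for r in reads]
        again = [decompose(r) for r in reversed(reads)]
        assert first == list(reversed(again))


class TestIsSpanning:
    def test_full_span_detected(self):
        s = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        assert is_spanning(sequence_from_structure(s), include_q1=True)

    def test_truncated_read_not_spanning(self):
        s = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        assert not is_spanning(sequence_from_structure(s)[:-15])

    def test_ambiguous_base_in_region_rejected(self):
        s = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        read = sequence_from_structure(s)
        pos = len(DEFAULT_FLANK5) + 5
        assert not is_spanning(read[:pos] + "N" + read[pos + 1:])

    def test_q1_excluded_mode_requires_cag_anchor(self):
        tail = "CAACAG" + "CCGCCA" + "CCG" * 7 + "CCT" * 2 + DEFAULT_FLANK3
        assert is_spanning("CAGCAG" + tail, include_q1=False)
        assert not is_spanning("TTT" + tail, include_q1=False)


class TestPhasing:
    def test_homozygous_canonical_sample(self):
        s = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        reads, _ = simulate_htt_reads(ReadSimSpec(structures=(s, s), seed=5))
        geno = phase_genotype(reads, (19, 19))
        assert geno.smaller.label == geno.larger.label == "canonical"

    def test_two_run_assignment_with_unspannable_larger_allele(self):
        smaller = HttStructure(q1=19, q2=1, p1=1, p2=7, p3=2)
        larger = HttStructure(q1=45, q2=1, p1=0, p2=9, p3=2)  # P1 loss
        reads, truth = simulate_htt_reads(
            ReadSimSpec(structures=(smaller, larger), seed=11)
        )
        assert not truth["alleles"][1]["spannable_with_q1"]
        geno = phase_genotype(reads, (19, 45))
        assert geno.phasing_method == "two_run"
        assert geno.smaller.label == "canonical" and geno.smaller.q1 == 19
        assert geno.larger.label == "P1_loss" and geno.larger.q1 == 45

    def test_read_order_does_not_change_phasing(self, rng):
        smaller = HttStructure(q1=17, q2=2, p1=1, p2=6, p3=1)
        larger = HttStructure(q1=40, q2=0, p1=1, p2=7, p3=2)
        reads, _ = simulate_htt_reads(ReadSimSpec(structures=(smaller, larger), seed=2))
        g1 = phase_genotype(reads, (17, 40))
        shuffled = list(reads)
        rng.shuffle(shuffled)
        g2 = phase_genotype(shuffled, (17, 40))
        assert g1 == g2

    def test_no_reads_raises(self):
        with pytest.raises(ValueError, match="no reads"):
            phase_genotype([], (17, 40))


class TestPopulationTable:
    def test_all_canonical_single_population(self):
        alleles = pd.DataFrame({"population": ["EUR"] * 5, "label": ["canonical"] * 5})
        out = structure_population_table(alleles)
        assert out.loc[0, "canonical"] == 1.0
        assert out.loc[0, "n_alleles"] == 5

    def test_even_split_yields_half_half(self):
        alleles = pd.DataFrame(
            {"population": ["AFR"] * 10, "label": ["canonical"] * 5 + ["P1_loss"] * 5}
        )
        out = structure_population_table(alleles)
        assert out.loc[0, "canonical"] == 0.5
        assert out.loc[0, "P1_loss"] == 0.5

    def test_rows_sum_to_one_and_conserve_alleles(self, rng):
        labels = np.array(["canonical", "Q2_loss", "P1_loss"])
        alleles = pd.DataFrame(
            {
                "population": rng.choice(["EUR", "AFR"], 200),
                "label": rng.choice(labels, 200),
            }
        )
        out = structure_population_table(alleles)
        props = out[[c for c in out.columns if c not in ("population", "n_alleles")]]
        assert np.allclose(props.sum(axis=1), 1.0)
        assert out["n_alleles"].sum() == 200

    def test_q1_differs_across_structures_detected(self, rng):
        alleles = pd.DataFrame(
            {
                "label": ["canonical"] * 50 + ["Q2_loss"] * 50,
                "q1": np.concatenate(
                    [rng.normal(18, 2, 50), rng.normal(30, 2, 50)]
                ).round(),
            }
        )
        tests = q1_by_structure_tests(alleles)
        assert tests["kruskal_p"] < 1e-6
        assert tests["pairwise"]["p_holm"].iloc[0] < 1e-6
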