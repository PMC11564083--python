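"""Genotype classification, carrier counting and the sample exclusion filter."""

import numpy as np
import pandas as pd
import pytest

from redprev.cohort import (
    CarrierStatus,
    classify_genotype,
    count_carriers,
    exclusion_filter,
    read_allele_table,
    write_allele_table,
)
from redprev.registry import Inheritance

from conftest import make_allele_table


class TestClassifyGenotype:
    def test_dominant_full_from_larger_allele(self, registry):
        assert classify_genotype(17, 42, "female", registry["HTT"]) is CarrierStatus.FULL_CARRIER

    def test_dominant_normal_genotype(self, registry):
        assert classify_genotype(17, 19, "male", registry["HTT"]) is CarrierStatus.NONE

    def test_full_dominates_premutation(self, registry):
        # one premutation plus one full allele counts once, as a full carrier
        assert classify_genotype(37, 41, "female", registry["HTT"]) is CarrierStatus.FULL_CARRIER

    def test_recessive_biallelic_and_monoallelic(self, registry):
        fxn = registry["FXN"]
        assert classify_genotype(70, 90, "female", fxn) is CarrierStatus.BIALLELIC
        assert classify_genotype(20, 90, "female", fxn) is CarrierStatus.MONOALLELIC
        assert classify_genotype(8, 20, "female", fxn) is CarrierStatus.NONE

    def test_x_linked_male_single_allele(self, registry):
        ar = registry["AR"]
        assert classify_genotype(40, None, "male", ar) is CarrierStatus.FULL_CARRIER
        assert classify_genotype(20, None, "male", ar) is CarrierStatus.NONE

    def test_x_linked_unknown_sex_skipped(self, registry):
        assert classify_genotype(40, 20, "unknown", registry["AR"]) is None

    def test_missing_required_allele_skipped(self, registry):
        assert classify_genotype(42, np.nan, "female", registry["HTT"]) is None


class TestCountCarriers:
    def test_constructed_full_carriers(self, registry):
        table = make_allele_table(
            [("s1", "HTT", 17, 42), ("s2", "HTT", 15, 40), ("s3", "HTT", 20, 55),
             ("s4", "HTT", 17, 19)]
        )
        (counts,) = count_carriers(table, registry)
        assert counts.n_full_carriers == 3
        assert counts.n_genotyped == 4

    def test_constructed_recessive_counts(self, registry):
        table = make_allele_table([("s1", "FXN", 70, 90), ("s2", "FXN", 8, 9)])
        (counts,) = count_carriers(table, registry)
        assert counts.n_biallelic == 1
        assert counts.n_monoallelic == 0

    def test_qc_fail_rows_leave_denominator(self, registry):
        table = make_allele_table(
            [("s1", "HTT", 17, 42), ("s2", "HTT", 17, 42, "female", "EUR", False)]
        )
        (counts,) = count_carriers(table, registry)
        assert counts.n_genotyped == 1
        assert counts.n_full_carriers == 1

    def test_male_denominator_for_x_linked(self, registry):
        table = make_allele_table(
            [("m1", "AR", 40, None, "male"), ("m2", "AR", 20, None, "male"),
             ("f1", "AR", 20, 40, "female")]
        )
        (counts,) = count_carriers(table, registry, sexes=("male",))
        assert counts.n_genotyped == 2
        assert counts.n_full_carriers == 1

    def test_empty_table_errors(self, registry):
        with pytest.raises(ValueError, match="empty"):
            count_carriers(make_allele_table([]).reindex(
                columns=["sample_id", "locus", "allele1", "allele2", "sex",
                         "population", "qc_pass"]), registry)

    def test_unknown_locus_errors(self, registry):
        with pytest.raises(ValueError, match="NOPE"):
            count_carriers(make_allele_table([("s1", "NOPE", 1, 2)]), registry)


def _naive_recount(table, registry):
    """Independent row-scan oracle for carrier counts."""
    out = {}
    for _, row in table.iterrows():
        if not row.qc_pass:
            continue
        locus = registry[row.locus]
        status = classify_genotype(row.allele1, row.allele2, row.sex, locus)
        if status is None:
            continue
        key = (row.locus, row.population)
        rec = out.setdefault(key, {"n": 0, "pre": 0, "full": 0, "mono": 0, "bi": 0})
        rec["n"] += 1
        rec["pre"] += status is CarrierStatus.PREMUTATION_CARRIER
        rec["full"] += status is CarrierStatus.FULL_CARRIER
        rec["mono"] += status is CarrierStatus.MONOALLELIC
        rec["bi"] += status is CarrierStatus.BIALLELIC
    return out


@pytest.fixture()
def random_table(registry, rng):
    loci = ["HTT", "FXN", "AR", "DMPK"]
    rows = []
    for i in range(1000):
        gene = loci[int(rng.integers(len(loci)))]
        sex = ["male", "female"][int(rng.integers(2))]
        a = np.sort(rng.integers(5, 80, 2))
        hemi = gene == "AR" and sex == "male"
        rows.append(
            (f"s{i:04d}", gene, int(a[0]), None if hemi else int(a[1]), sex,
             ["EUR", "AFR", "EAS"][int(rng.integers(3))], bool(rng.random() > 0.05))
        )
    return make_allele_table(rows)


class TestCountingInvariants:
    def test_counts_match_naive_row_scan_oracle(self, registry, random_table):
        oracle = _naive_recount(random_table, registry)
        for c in count_carriers(random_table, registry, stratify_by_population=True):
            rec = oracle[(c.locus, c.population)]
            assert (c.n_genotyped, c.n_premutation_carriers, c.n_full_carriers,
                    c.n_monoallelic, c.n_biallelic) == (
                rec["n"], rec["pre"], rec["full"], rec["mono"], rec["bi"])

    def test_stratified_counts_sum_to_overall(self, registry, random_table):
        overall = {c.locus: c for c in count_carriers(random_table, registry)}
        sums = {}
        for c in count_carriers(random_table, registry, stratify_by_population=True):
            agg = sums.setdefault(c.locus, [0, 0, 0, 0, 0])
            for i, v in enumerate(
                (c.n_genotyped, c.n_premutation_carriers, c.n_full_carriers,
                 c.n_monoallelic, c.n_biallelic)
            ):
                agg[i] += v
        for gene, c in overall.items():
            assert sums[gene] == [c.n_genotyped, c.n_premutation_carriers,
                                  c.n_full_carriers, c.n_monoallelic, c.n_biallelic]

    def test_row_permutation_does_not_change_counts(self, registry, random_table, rng):
        shuffled = random_table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert count_carriers(random_table, registry) == count_carriers(shuffled, registry)

    def test_dominant_carriers_bounded_by_denominator(self, registry, random_table):
        for c in count_carriers(random_table, registry):
            if c.inheritance is not Inheritance.AUTOSOMAL_RECESSIVE:
                assert c.n_full_carriers + c.n_premutation_carriers <= c.n_genotyped


class TestExclusionFilter:
    def test_removes_listed_samples(self, registry):
        table = make_allele_table([(f"s{i}", "HTT", 17, 19) for i in range(10)])
        out = exclusion_filter(table, ["s0", "s5"])
        assert len(out) == 8
        assert not {"s0", "s5"} & set(out["sample_id"])

    def test_empty_exclusion_is_identity(self):
        table = make_allele_table([("s1", "HTT", 17, 19)])
        pd.testing.assert_frame_equal(exclusion_filter(table, []), table)

    def test_excluding_everyone_breaks_downstream_counting(self, registry):
        table = make_allele_table([("s1", "HTT", 17, 19), ("s2", "HTT", 17, 19)])
        empty = exclusion_filter(table, ["s1", "s2"])
        assert len(empty) == 0
        with pytest.raises(ValueError):
            count_carriers(empty, registry)

    def test_unknown_ids_ignored(self):
        table = make_allele_table([("s1", "HTT", 17, 19)])
        assert len(exclusion_filter(table, ["ghost"])) == 1


class TestTableIO:
    def test_tsv_round_trip_preserves_hemizygous_calls(self, tmp_path):
        table = make_allele_table(
            [("s1", "AR", 22, None, "male"), ("s2", "HTT", 17, 42)]
        )
        path = tmp_path / "alleles.tsv"
        write_allele_table(table, path)
        back = read_allele_table(path)
        assert np.isnan(back["allele2"].iloc[0])
        assert back["allele2"].iloc[1] == 42.0

    def test_allele_order_violation_rejected(self, tmp_path):
        table = make_allele_table([("s1", "HTT", 42, 17)])
        path = tmp_path / "bad.tsv"
        write_allele_table(table, path)
        with pytest.raises(ValueError, match="allele1 > allele2"):
            read_allele_table(path)
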