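"""Per-sample genotype classification and cohort carrier counting.

Consumes a per-sample allele table (the post-QC output dialect of a
short-tandem-repeat genotyper such as ExpansionHunter) and produces per-locus,
optionally per-population, carrier counts under the correct inheritance model:

* autosomal dominant and X-linked loci: an individual is a *full carrier* if
  their larger classified allele is in the full-mutation range, a *premutation
  carrier* if it is in the premutation/reduced-penetrance range (full status
  dominates — individuals are counted once);
* autosomal recessive loci: *biallelic* if both alleles are at or above the
  full-mutation cutoff, *monoallelic* if exactly one is;
* males at X-linked loci are evaluated on their single (hemizygous) allele;
  rows of unknown sex at X-linked loci are excluded with a warning.

The allele-table dialect is TSV with columns
``sample_id  locus  allele1  allele2  sex  population  qc_pass``;
``allele2`` may be empty for hemizygous calls, and ``qc_pass`` models the
study's manual visual inspection of read pileups (rows failing it are dropped
from the per-locus denominator, so N may vary between loci).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import AlleleClass, Inheritance, LocusDefinition, LocusRegistry, classify_allele

__all__ = [
    "CarrierStatus",
    "CarrierCounts",
    "ALLELE_TABLE_COLUMNS",
    "read_allele_table",
    "write_allele_table",
    "validate_allele_table",
    "classify_genotype",
    "count_carriers",
    "exclusion_filter",
]

logger = logging.getLogger(__name__)

ALLELE_TABLE_COLUMNS = [
    "sample_id",
    "locus",
    "allele1",
    "allele2",
    "sex",
    "population",
    "qc_pass",
]

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


class CarrierStatus(str, enum.Enum):
    """Carrier status of one individual at one locus."""

    NONE = "none"
    PREMUTATION_CARRIER = "premutation_carrier"
    FULL_CARRIER = "full_carrier"
    MONOALLELIC = "monoallelic"  # recessive loci only
    BIALLELIC = "biallelic"  # recessive loci only


@dataclass(frozen=True)
class CarrierCounts:
    """Carrier counts for one locus in one population stratum (or ``ALL``).

    ``n_genotyped`` counts QC-passing individuals genotyped at this locus;
    full carriers are never double-counted as premutation carriers.
    """

    locus: str
    population: str  # one of POPULATIONS or "ALL"
    inheritance: Inheritance
    n_genotyped: int
    n_premutation_carriers: int = 0
    n_full_carriers: int = 0
    n_monoallelic: int = 0
    n_biallelic: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_premutation_carriers",
            "n_full_carriers",
            "n_monoallelic",
            "n_biallelic",
        ):
            if getattr(self, name) > self.n_genotyped:
                raise ValueError(
                    f"{self.locus}/{self.population}: {name} exceeds n_genotyped"
                )


def read_allele_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort allele table from TSV, tolerating missing ``allele2``."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "locus": str, "sex": str, "population": str},
    )
    missing = [c for c in ALLELE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele table {path} missing columns: {missing}")
    table["allele1"] = table["allele1"].astype(float)
    table["allele2"] = pd.to_numeric(table["allele2"], errors="coerce")
    table["qc_pass"] = table["qc_pass"].astype(bool)
    validate_allele_table(table)
    return table


def write_allele_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def validate_allele_table(table: pd.DataFrame) -> None:
    """Check structural invariants: allele ordering and sample x locus keys."""
    both = table["allele2"].notna()
    bad = both & (table["allele1"] > table["allele2"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"allele1 > allele2 at row {i} "
            f"(sample {table['sample_id'].iloc[i]}, locus {table['locus'].iloc[i]})"
        )
    if table.duplicated(subset=["sample_id", "locus"]).any():
        raise ValueError("duplicate sample_id x locus rows in allele table")


def classify_genotype(
    allele1: float,
    allele2: float | None,
    sex: str,
    locus: LocusDefinition,
) -> CarrierStatus | None:
    """Classify one individual's genotype at one locus.

    Returns ``None`` when the row cannot be evaluated (missing required
    allele, or unknown sex at an X-linked locus); callers log and skip.
    """
    a2_missing = allele2 is None or (isinstance(allele2, float) and np.isnan(allele2))

    if locus.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        if a2_missing:
            return None
        n_exp = int(allele1 >= locus.full_min) + int(allele2 >= locus.full_min)
        if n_exp == 2:
            return CarrierStatus.BIALLELIC
        if n_exp == 1:
            return CarrierStatus.MONOALLELIC
        return CarrierStatus.NONE

    if locus.inheritance is Inheritance.X_LINKED:
        if sex == "male":
            alleles = [allele1]
        elif sex == "female":
            if a2_missing:
                return None
            alleles = [allele1, allele2]
        else:
            return None  # unknown sex: cannot pick the hemizygous model
    else:  # autosomal dominant
        if a2_missing:
            return None
        alleles = [allele1, allele2]

    top = max(classify_allele(int(a), locus) for a in alleles)
    if top is AlleleClass.FULL:
        return CarrierStatus.FULL_CARRIER
    if top is AlleleClass.PREMUTATION:
        return CarrierStatus.PREMUTATION_CARRIER
    return CarrierStatus.NONE


def _count_block(
    block: pd.DataFrame, locus: LocusDefinition, population: str
) -> CarrierCounts:
    statuses = []
    n_skipped = 0
    for allele1, allele2, sex in zip(
        block["allele1"].to_numpy(),
        block["allele2"].to_numpy(),
        block["sex"].to_numpy(),
    ):
        status = classify_genotype(float(allele1), allele2, str(sex), locus)
        if status is None:
            n_skipped += 1
        else:
            statuses.append(status)
    if n_skipped:
        logger.warning(
            "%s/%s: skipped %d records with missing allele or unknown sex",
            locus.gene_symbol,
            population,
            n_skipped,
        )
    counts = {s: statuses.count(s) for s in CarrierStatus}
    return CarrierCounts(
        locus=locus.gene_symbol,
        population=population,
        inheritance=locus.inheritance,
        n_genotyped=len(statuses),
        n_premutation_carriers=counts[CarrierStatus.PREMUTATION_CARRIER],
        n_full_carriers=counts[CarrierStatus.FULL_CARRIER],
        n_monoallelic=counts[CarrierStatus.MONOALLELIC],
        n_biallelic=counts[CarrierStatus.BIALLELIC],
    )


def count_carriers(
    table: pd.DataFrame,
    registry: LocusRegistry,
    stratify_by_population: bool = False,
    sexes: tuple[str, ...] | None = None,
) -> list[CarrierCounts]:
    """Count carriers per locus (and optionally per population).

    Only ``qc_pass`` rows enter the per-locus denominator, so ``n_genotyped``
    may differ between loci.  ``sexes`` restricts the denominator (for
    example ``("male",)`` for a male-only X-linked frequency).

    Raises
    ------
    ValueError
        On an empty table or a locus absent from the registry.
    """
    if len(table) == 0:
        raise ValueError("empty allele table")
    unknown = set(table["locus"]) - set(registry.gene_symbols)
    if unknown:
        raise ValueError(f"loci not in registry: {sorted(unknown)}")

    table = table[table["qc_pass"]]
    if sexes is not None:
        table = table[table["sex"].isin(sexes)]

    results: list[CarrierCounts] = []
    for gene, locus_block in table.groupby("locus", sort=True):
        locus = registry[str(gene)]
        if stratify_by_population:
            for pop, block in locus_block.groupby("population", sort=True):
                results.append(_count_block(block, locus, str(pop)))
        else:
            results.append(_count_block(locus_block, locus, "ALL"))
    return results


def exclusion_filter(
    table: pd.DataFrame, excluded_sample_ids: "set[str] | list[str]"
) -> pd.DataFrame:
    """Drop listed samples (e.g. individuals ascertained for neurological
    disease, excluded to avoid inflating carrier frequencies).

    Unknown ids are ignored with a log message; the returned table is new.
    """
    excluded = set(excluded_sample_ids)
    present = set(table["sample_id"])
    missing = excluded - present
    if missing:
        logger.info("exclusion list: %d ids not present in table", len(missing))
    return table[~table["sample_id"].isin(excluded)].reset_index(drop=True)
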