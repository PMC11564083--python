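"""Per-population allele-length distribution summaries and the
intermediate-vs-pathogenic frequency correlation.

Summaries are allele-level (every called allele counts once): median,
quartiles, the 99.9th percentile that marks the upper tail of each
population's distribution, and the fractions of alleles in the intermediate
and pathogenic ranges.  To keep the two fractions disjoint, loci with a
defined intermediate cutoff use intermediate = [intermediate_min,
premutation_min) and pathogenic = [premutation_min, inf); loci whose
intermediate range is the premutation band itself use intermediate =
[premutation_min, full_min) and pathogenic = [full_min, inf).

The correlation analysis asks whether populations and genes with more
intermediate (large-normal) alleles also carry more pathogenic alleles — the
expected signature when expansions arise gradually from the large-normal
pool.  It is a Spearman rank correlation over one point per population x
gene, with two-tailed p; loci where either fraction is zero across all
populations are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import LocusDefinition, LocusRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleDistributionSummary",
    "intermediate_band",
    "summarize_distribution",
    "intermediate_pathogenic_correlation",
]


@dataclass(frozen=True)
class AlleleDistributionSummary:
    """Distribution summary for one locus in one population."""

    locus: str
    population: str
    n_alleles: int
    median: float
    q1: float
    q3: float
    p99_9: float
    frac_intermediate: float
    frac_pathogenic: float

    def __post_init__(self) -> None:
        if not (0 <= self.frac_intermediate <= 1 and 0 <= self.frac_pathogenic <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_intermediate + self.frac_pathogenic > 1 + 1e-12:
            raise ValueError("intermediate and pathogenic fractions overlap")
        if self.p99_9 < self.median:
            raise ValueError("99.9th percentile below the median")


def intermediate_band(locus: LocusDefinition) -> tuple[int, int]:
    """(low, high) bounds of the disjoint intermediate band, half-open."""
    if locus.intermediate_min is not None:
        return locus.intermediate_min, locus.premutation_min
    return locus.premutation_min, locus.full_min


def _pathogenic_min(locus: LocusDefinition) -> int:
    return (
        locus.premutation_min if locus.intermediate_min is not None else locus.full_min
    )


def summarize_distribution(
    alleles: pd.DataFrame,
    registry: LocusRegistry,
    percentile_method: str = "linear",
) -> pd.DataFrame:
    """Summarize allele sizes per locus x population.

    ``alleles`` needs columns ``locus``, ``population``, ``size`` with one row
    per called allele.  Percentiles use numpy's ``percentile`` with the given
    interpolation convention (default ``linear``); empty cells are omitted
    with a warning.
    """
    required = {"locus", "population", "size"}
    if not required <= set(alleles.columns):
        raise ValueError(f"allele table needs columns {sorted(required)}")
    rows = []
    for (gene, pop), cell in alleles.groupby(["locus", "population"], sort=True):
        sizes = cell["size"].to_numpy(dtype=float)
        if len(sizes) == 0:
            logger.warning("no alleles for %s/%s; omitted", gene, pop)
            continue
        locus = registry[str(gene)]
        int_lo, int_hi = intermediate_band(locus)
        path_min = _pathogenic_min(locus)
        q1, med, q3, p999 = np.percentile(
            sizes, [25, 50, 75, 99.9], method=percentile_method
        )
        summary = AlleleDistributionSummary(
            locus=str(gene),
            population=str(pop),
            n_alleles=len(sizes),
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            p99_9=float(p999),
            frac_intermediate=float(np.mean((sizes >= int_lo) & (sizes < int_hi))),
            frac_pathogenic=float(np.mean(sizes >= path_min)),
        )
        rows.append(summary.__dict__)
    return pd.DataFrame(rows)


def intermediate_pathogenic_correlation(
    summaries: pd.DataFrame,
) -> tuple[float | None, float | None, pd.DataFrame]:
    """Spearman correlation between intermediate and pathogenic allele
    fractions over population x gene points.

    Loci where either fraction is zero across *all* populations are excluded.
    Returns (rho, two-tailed p, scatter table); rho is ``None`` when either
    vector is constant (correlation undefined).

    Raises
    ------
    ValueError
        With fewer than 3 usable points.
    """
    required = {"locus", "population", "frac_intermediate", "frac_pathogenic"}
    if not required <= set(summaries.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")

    keep = []
    for gene, sub in summaries.groupby("locus"):
        if (sub["frac_intermediate"] > 0).any() and (sub["frac_pathogenic"] > 0).any():
            keep.append(sub)
        else:
            logger.info("excluding %s: intermediate or pathogenic absent everywhere", gene)
    if not keep:
        raise ValueError("no loci with both intermediate and pathogenic alleles")
    points = pd.concat(keep, ignore_index=True)
    if len(points) < 3:
        raise ValueError("need at least 3 population x gene points")

    scatter = points[
        ["locus", "population", "frac_intermediate", "frac_pathogenic"]
    ].copy()
    if "n_intermediate" in points.columns:
        scatter["n_intermediate"] = points["n_intermediate"]
    elif "n_alleles" in points.columns:
        scatter["n_intermediate"] = (
            points["frac_intermediate"] * points["n_alleles"]
        ).round().astype(int)

    x = points["frac_intermediate"].to_numpy()
    y = points["frac_pathogenic"].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None, scatter
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), scatter
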