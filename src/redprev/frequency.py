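"""Carrier frequencies: "1 in x" estimates, Wilson score intervals, per-100k.

The carrier frequency of a category (e.g. full-mutation carriers at a locus)
is reported the way clinical epidemiology prints it:

* ``1 in x`` with ``x = round(n / count)`` (half away from zero, 0 digits),
* a 95% Wilson score confidence interval on the carrier proportion
  ``p = count / n``::

      ci = (p + z^2/(2n) +- z * sqrt(p*q/n + z^2/(4n^2))) / (1 + z^2/n)

  with ``q = 1 - p`` and ``z = 1.96`` by default,
* a per-100,000 transform ``100000 / x`` with interval bounds
  ``100000 * ci_min`` and ``100000 * ci_max`` (ascending order).

With ``count = 0`` the "1 in x" and per-100k point estimates are undefined
(reported as ``None``); the Wilson interval is still computed at ``p = 0``,
whose lower bound is exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import CarrierCounts
from .registry import Inheritance

__all__ = ["CarrierFrequency", "carrier_frequency", "wilson_interval", "frequency_table"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def wilson_interval(count: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, no continuity correction.

    Returns ``(ci_min, ci_max)``, both clipped to [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, n], got count={count}, n={n}")
    p = count / n
    q = 1.0 - p
    denom = 1.0 + z * z / n
    centre = p + z * z / (2 * n)
    half = z * math.sqrt(p * q / n + z * z / (4 * n * n))
    ci_min = (centre - half) / denom
    ci_max = (centre + half) / denom
    # mathematically ci_min <= p <= ci_max always holds; at p = 0 or 1 the
    # touching bound can drift past p by rounding, so clamp onto [0, p], [p, 1]
    return min(max(0.0, ci_min), p), max(min(1.0, ci_max), p)


@dataclass(frozen=True)
class CarrierFrequency:
    """Carrier-frequency estimate for one locus x category x stratum."""

    locus: str
    category: str
    population: str
    count: int
    n: int
    p: float
    q: float
    one_in_x: int | None
    ci_min: float
    ci_max: float
    per_100k: float | None
    per_100k_low: float
    per_100k_high: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_min <= self.p <= self.ci_max <= 1.0):
            raise ValueError(
                f"{self.locus}/{self.category}: interval does not bracket p "
                f"({self.ci_min}, {self.p}, {self.ci_max})"
            )

    def __str__(self) -> str:
        prefix = " ".join(x for x in (self.locus, self.category) if x)
        prefix = f"{prefix}: " if prefix else ""
        if self.one_in_x is None:
            return f"{prefix}0 of {self.n:,}"
        return f"{prefix}1 in {self.one_in_x:,}"


def carrier_frequency(
    count: int,
    n: int,
    z: float = 1.96,
    locus: str = "",
    category: str = "",
    population: str = "ALL",
) -> CarrierFrequency:
    """Estimate a carrier frequency from ``count`` carriers among ``n`` people.

    Examples
    --------
    >>> carrier_frequency(290, 82176).one_in_x
    283
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, n], got count={count}, n={n}")
    p = count / n
    ci_min, ci_max = wilson_interval(count, n, z)
    if count > 0:
        one_in_x: int | None = _round_half_away(n / count)
        per_100k: float | None = 100_000.0 / one_in_x
    else:
        one_in_x = None
        per_100k = None
    return CarrierFrequency(
        locus=locus,
        category=category,
        population=population,
        count=int(count),
        n=int(n),
        p=p,
        q=1.0 - p,
        one_in_x=one_in_x,
        ci_min=ci_min,
        ci_max=ci_max,
        per_100k=per_100k,
        per_100k_low=100_000.0 * ci_min,
        per_100k_high=100_000.0 * ci_max,
        z=z,
    )


def _categories(c: CarrierCounts) -> list[tuple[str, int]]:
    if c.inheritance is Inheritance.AUTOSOMAL_RECESSIVE:
        return [("monoallelic", c.n_monoallelic), ("biallelic", c.n_biallelic)]
    return [
        ("premutation", c.n_premutation_carriers),
        ("full", c.n_full_carriers),
    ]


def frequency_table(counts: list[CarrierCounts], z: float = 1.96) -> pd.DataFrame:
    """Expand carrier counts into a forest-plot-ready frequency table.

    One row per locus x category x population stratum, with count, n,
    "1 in x", Wilson CI bounds and per-100k columns.
    """
    rows = []
    for c in counts:
        for category, k in _categories(c):
            if c.n_genotyped == 0:
                continue
            f = carrier_frequency(
                k, c.n_genotyped, z=z, locus=c.locus, category=category,
                population=c.population,
            )
            rows.append(
                {
                    "locus": f.locus,
                    "category": f.category,
                    "population": f.population,
                    "count": f.count,
                    "n": f.n,
                    "p": f.p,
                    "one_in_x": f.one_in_x,
                    "ci_min": f.ci_min,
                    "ci_max": f.ci_max,
                    "per_100k": f.per_100k,
                    "per_100k_low": f.per_100k_low,
                    "per_100k_high": f.per_100k_high,
                }
            )
    return pd.DataFrame(rows)
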