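"""Age-structured genetic-prevalence model.

Given a mutation frequency ``f`` estimated from population genomes, the
expected number of new disease cases in age bin ``k`` is

    M_k = f * N_k * p_k * pen(k)

where ``N_k`` is the population count in the bin (population pyramid),
``p_k`` the proportion of all disease onsets occurring in the bin (an age-at-
onset distribution normalized to sum to 1), and ``pen(k)`` an optional
age-related cumulative penetrance.  Prevalence then accounts for survival:
people counted in bin ``k`` are those whose onset fell in the trailing window
of ``n`` years (the disease's median survival) ending at bin ``k``; with no
survival limit cases persist for life and prevalence is the running cumulative
sum of incidence.

All bins are 5-year, half-open ``[a, a+5)``.  When ``n`` is not a multiple of
the bin width the oldest, partially covered bin contributes the fraction
``(n mod 5)/5`` — equivalent to spreading each bin's incidence uniformly over
its 5 years, cumulating over the trailing ``n`` years, and reading the result
at the last year of each bin.

Myotonic dystrophy type 1 (DM1) gets onset-dependent survival rules: onset at
31 years or later carries normal life expectancy; childhood (<10 y) and
early-adult (10-30 y) onset cases survive fully for 10 years, 80% at 10 years
post-onset, then decline linearly to zero at a mean age at death of 45 y
(childhood onset) or 52 y (early-adult onset).

The module also carries the closed-form literature-prevalence derivations
used to benchmark the model (C9orf72-FTD, C9orf72-ALS and 40-CAG Huntington
disease), reproducing the printed rounding conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BIN_WIDTH",
    "PopulationPyramid",
    "OnsetDistribution",
    "PenetranceCurve",
    "Dm1SurvivalRules",
    "normalize_onset",
    "expected_new_cases",
    "apply_survival",
    "dm1_survival_fraction",
    "apply_dm1_survival",
    "total_prevalence",
    "aggregate_bins",
    "reported_prevalence_c9ftd",
    "reported_prevalence_c9als",
    "reported_prevalence_hd40",
]

BIN_WIDTH = 5


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def _check_starts(starts: np.ndarray, what: str) -> None:
    if len(starts) == 0:
        raise ValueError(f"{what}: no age bins")
    diffs = np.diff(starts)
    if np.any(diffs != BIN_WIDTH):
        k = int(np.flatnonzero(diffs != BIN_WIDTH)[0])
        raise ValueError(
            f"{what}: bins must be contiguous {BIN_WIDTH}-year intervals; "
            f"gap between bin starting {starts[k]} and bin starting {starts[k + 1]}"
        )


@dataclass(frozen=True)
class PopulationPyramid:
    """Population counts per 5-year age bin ``[start, start+5)``."""

    bin_starts: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_starts", np.asarray(self.bin_starts, dtype=int))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        _check_starts(self.bin_starts, "population pyramid")
        if len(self.counts) != len(self.bin_starts):
            raise ValueError("population pyramid: counts/bins length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("population pyramid: negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class OnsetDistribution:
    """Age-at-onset counts per 5-year bin; ``proportions`` normalizes to 1."""

    bin_starts: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_starts", np.asarray(self.bin_starts, dtype=int))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        _check_starts(self.bin_starts, "onset distribution")
        if len(self.counts) != len(self.bin_starts):
            raise ValueError("onset distribution: counts/bins length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("onset distribution: negative counts")

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("onset distribution: zero total count")
        return self.counts / total


def normalize_onset(dist: OnsetDistribution) -> OnsetDistribution:
    """Return the distribution with counts replaced by proportions p_k."""
    return OnsetDistribution(dist.bin_starts, dist.proportions)


@dataclass(frozen=True)
class PenetranceCurve:
    """Cumulative age-related penetrance: fraction of carriers manifest by age.

    Tabulated (age, fraction) pairs, linearly interpolated and clamped at the
    ends; must be non-decreasing and within [0, 1].  ``constant(1.0)`` is the
    default full-penetrance curve.
    """

    ages: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))
        if len(self.ages) != len(self.fractions) or len(self.ages) == 0:
            raise ValueError("penetrance curve: need matching non-empty age/fraction arrays")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("penetrance curve: ages must be strictly increasing")
        if np.any(np.diff(self.fractions) < 0):
            raise ValueError("penetrance curve: must be non-decreasing in age")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("penetrance curve: fractions must lie in [0, 1]")

    @classmethod
    def constant(cls, value: float = 1.0) -> "PenetranceCurve":
        return cls(np.array([0.0, 120.0]), np.array([value, value]))

    def at(self, ages) -> np.ndarray:
        return np.interp(np.asarray(ages, dtype=float), self.ages, self.fractions)


@dataclass(frozen=True)
class Dm1SurvivalRules:
    """Onset-dependent DM1 survival: mean ages at death and 10-year survival."""

    death_age_childhood: float = 45.0
    death_age_early_adult: float = 52.0
    early_adult_onset_range: tuple[float, float] = (10.0, 30.0)
    ten_year_survival: float = 0.80


def _align(a_starts: np.ndarray, b_starts: np.ndarray, what: str) -> None:
    if len(a_starts) != len(b_starts) or np.any(a_starts != b_starts):
        for i in range(min(len(a_starts), len(b_starts))):
            if a_starts[i] != b_starts[i]:
                raise ValueError(
                    f"{what}: bin mismatch at index {i} "
                    f"({a_starts[i]} vs {b_starts[i]})"
                )
        raise ValueError(f"{what}: differing number of bins "
                         f"({len(a_starts)} vs {len(b_starts)})")


def expected_new_cases(
    f: float,
    pyramid: PopulationPyramid,
    onset: OnsetDistribution,
    penetrance: PenetranceCurve | None = None,
) -> np.ndarray:
    """Per-bin expected new cases ``M_k = f * N_k * p_k * pen(k)``.

    ``pen`` is evaluated at bin midpoints; omit it for full penetrance.
    The result is linear in ``f``.
    """
    if f < 0:
        raise ValueError("mutation frequency must be non-negative")
    _align(pyramid.bin_starts, onset.bin_starts, "pyramid vs onset")
    p_k = onset.proportions
    m = f * pyramid.counts * p_k
    if penetrance is not None:
        midpoints = pyramid.bin_starts + BIN_WIDTH / 2
        m = m * penetrance.at(midpoints)
    return m


def apply_survival(
    new_cases: np.ndarray, median_survival_years: int | None
) -> np.ndarray:
    """Convert per-bin incidence to prevalence via a trailing survival window.

    ``median_survival_years=None`` means normal life expectancy within the
    modelled age span: cases persist, and prevalence is the cumulative sum.
    Otherwise bin ``k`` sums incidence over the trailing window of ``n``
    years; the oldest partially covered bin is weighted ``(n mod 5)/5``.
    """
    m = np.asarray(new_cases, dtype=float)
    if median_survival_years is None:
        return np.cumsum(m)
    n = int(median_survival_years)
    if n < 1:
        raise ValueError("median survival must be >= 1 year")
    n_full, rem = divmod(n, BIN_WIDTH)
    prev = np.zeros_like(m)
    for j in range(n_full):
        prev[j:] += m[: len(m) - j] if j == 0 else m[:-j]
    if rem:
        frac = rem / BIN_WIDTH
        if n_full == 0:
            prev += frac * m
        elif n_full < len(m):
            prev[n_full:] += frac * m[:-n_full]
    return prev


def dm1_survival_fraction(
    onset_age: float, attained_age: float, rules: Dm1SurvivalRules = Dm1SurvivalRules()
) -> float:
    """Fraction of a DM1 onset cohort still alive at an attained age.

    Survival is 100% for the first 10 years after onset, 80% at exactly
    10 years, then declines linearly to 0 at the mean age at death for the
    onset group.  Onset at or after 31 years carries no excess mortality.
    """
    if attained_age < onset_age:
        return 0.0
    early_lo, early_hi = rules.early_adult_onset_range
    if onset_age > early_hi:
        return 1.0
    death_age = (
        rules.death_age_childhood if onset_age < early_lo else rules.death_age_early_adult
    )
    years_since_onset = attained_age - onset_age
    if years_since_onset < 10:
        return 1.0
    if attained_age >= death_age:
        return 0.0
    decline_span = death_age - (onset_age + 10)
    if decline_span <= 0:
        return 0.0
    return rules.ten_year_survival * (death_age - attained_age) / decline_span


def apply_dm1_survival(
    new_cases: np.ndarray,
    bin_starts: np.ndarray,
    rules: Dm1SurvivalRules = Dm1SurvivalRules(),
) -> np.ndarray:
    """Onset-stratified DM1 prevalence by attained-age bin.

    Each bin's incidence is spread uniformly over its 5 onset years; the
    prevalence in attained-age bin ``k`` is the sum of surviving fractions of
    all earlier onset-year cohorts, read at the bin's last year (the same
    snapshot convention as :func:`apply_survival`).
    """
    m = np.asarray(new_cases, dtype=float)
    starts = np.asarray(bin_starts, dtype=int)
    _check_starts(starts, "DM1 incidence")
    if len(m) != len(starts):
        raise ValueError("DM1 incidence: counts/bins length mismatch")

    onset_years = np.concatenate(
        [np.arange(s, s + BIN_WIDTH) for s in starts]
    )  # one cohort per onset year
    inc_per_year = np.repeat(m / BIN_WIDTH, BIN_WIDTH)

    prev = np.zeros_like(m)
    for k, s in enumerate(starts):
        snapshot_age = s + BIN_WIDTH - 1  # last year of the bin
        alive = np.array(
            [
                dm1_survival_fraction(float(o), float(snapshot_age), rules)
                for o in onset_years
            ]
        )
        prev[k] = float(np.sum(inc_per_year * alive * (onset_years <= snapshot_age)))
    return prev


def total_prevalence(
    prevalence_by_age: np.ndarray, pyramid: PopulationPyramid
) -> tuple[float, float]:
    """Total expected affected ``M`` and the per-100,000 rate."""
    prev = np.asarray(prevalence_by_age, dtype=float)
    if len(prev) != len(pyramid.bin_starts):
        raise ValueError("prevalence vector does not align with pyramid bins")
    if pyramid.total <= 0:
        raise ValueError("empty population pyramid")
    m_total = float(prev.sum())
    return m_total, 100_000.0 * m_total / pyramid.total


def aggregate_bins(
    starts: np.ndarray, values: np.ndarray, width: int = BIN_WIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate finer (e.g. 1-year) bins onto the model's 5-year grid."""
    starts = np.asarray(starts)
    values = np.asarray(values, dtype=float)
    coarse = (starts // width) * width
    uniq = np.unique(coarse)
    agg = np.array([values[coarse == u].sum() for u in uniq])
    return uniq.astype(int), agg


# --- literature-prevalence derivations used for comparison -----------------


def reported_prevalence_c9ftd(
    mutation_fraction_range: tuple[float, float], median_ftd_prevalence: float
) -> dict[str, float]:
    """C9orf72-FTD prevalence from the fraction of FTD cases carrying the
    expansion times the median FTD prevalence.

    Returns per-100k ``low``/``high`` (1 decimal) and the midpoint ``mean``
    of the unrounded bounds (2 decimals).
    """
    lo, hi = mutation_fraction_range
    if not 0 <= lo <= hi <= 1:
        raise ValueError("mutation fraction range must satisfy 0 <= low <= high <= 1")
    raw_lo = lo * median_ftd_prevalence
    raw_hi = hi * median_ftd_prevalence
    return {
        "low": _round_half_away(raw_lo, 1),
        "high": _round_half_away(raw_hi, 1),
        "mean": _round_half_away((raw_lo + raw_hi) / 2, 2),
    }


def reported_prevalence_c9als(
    als_prevalence_range: tuple[float, float] = (5.0, 12.0),
    familial_fraction: float = 0.1,
    sporadic_fraction: float = 0.9,
    familial_mut_fraction: float = 0.4,
    sporadic_mut_fraction: float = 0.07,
) -> dict[str, float]:
    """C9orf72-ALS prevalence: the familial/sporadic-weighted expansion
    fraction applied to the reported ALS prevalence range (per 100k,
    1 decimal)."""
    for x in (familial_fraction, sporadic_fraction, familial_mut_fraction,
              sporadic_mut_fraction):
        if not 0 <= x <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    if not math.isclose(familial_fraction + sporadic_fraction, 1.0):
        raise ValueError("familial and sporadic fractions must sum to 1")
    weight = (
        familial_mut_fraction * familial_fraction
        + sporadic_mut_fraction * sporadic_fraction
    )
    lo, hi = als_prevalence_range
    return {
        "weight": weight,
        "low": _round_half_away(weight * lo, 1),
        "high": _round_half_away(weight * hi, 1),
    }


def reported_prevalence_hd40(
    carrier_fraction_of_cases: float, hd_prevalence: float
) -> float:
    """Prevalence of symptomatic 40-CAG Huntington disease: the fraction of
    clinically affected HD patients carrying exactly 40 repeats times overall
    HD prevalence (per 100k, 2 decimals)."""
    if not 0 <= carrier_fraction_of_cases <= 1:
        raise ValueError("carrier fraction must lie in [0, 1]")
    return _round_half_away(carrier_fraction_of_cases * hd_prevalence, 2)
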