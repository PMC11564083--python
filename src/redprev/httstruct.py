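"""HTT exon-1 repeat-structure decomposition and phasing from spanning reads.

A typical HTT exon-1 repeat region is an ordered run of five elements: the
pure CAG tract (Q1), a CAACAG interruption (Q2), a CCGCCA element (P1), a CCG
tract (P2) and a CCT tract (P3).  Atypical alleles duplicate or lose Q2, lose
P1, or both; these structures travel with different CAG tract sizes and vary
in frequency between populations.

This module decomposes individual sequencing reads that *span* the repeat
region (both flank anchors visible) into exact element copy numbers by greedy
left-to-right maximal matching — unambiguous for this grammar because each
element's motif differs from the next at the first discriminating base — and
phases CAG size to structure with a two-run scheme: a first run over reads
spanning the whole region (including Q1) types the smaller allele, and a
second run over reads spanning only Q2..P3 (anchored in the CAG tract) types
the larger allele that no read can span in full at 150 bp.

Structure labels follow the element copy numbers::

    canonical        q2 == 1 and p1 == 1
    Q2_duplication   q2 == 2 and p1 == 1
    Q2_loss          q2 == 0 and p1 == 1
    partial_Q2_loss  q2 == 0, p1 == 1, with a dangling CAA trimer
    P1_loss          q2 == 1 and p1 == 0
    Q2_P1_loss       q2 == 0 and p1 == 0
    other            anything else (incl. unparsed residue)

``partial_Q2_loss`` (a CAA trimer present without its CAG) is a detectable
intermediate state encoded here for completeness; the literature does not
define its sequence, so the encoding is this package's convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatGrammar",
    "HttStructure",
    "PhasedHttGenotype",
    "NonSpanningReadError",
    "default_grammar",
    "is_spanning",
    "decompose",
    "sequence_from_structure",
    "phase_genotype",
    "structure_population_table",
    "q1_by_structure_tests",
]

Q1, Q2, P1, P2, P3 = "CAG", "CAACAG", "CCGCCA", "CCG", "CCT"

# 12 bp anchors adjacent to the repeat, modelled on the GRCh38 exon-1 context.
DEFAULT_FLANK5 = "CTCAAGTCCTTC"
DEFAULT_FLANK3 = "CAGCTTCCTCAG"

STRUCTURE_LABELS = (
    "canonical",
    "Q2_duplication",
    "Q2_loss",
    "partial_Q2_loss",
    "P1_loss",
    "Q2_P1_loss",
    "other",
)


class NonSpanningReadError(ValueError):
    """Raised when a read does not span the element region being analyzed."""


@dataclass(frozen=True)
class RepeatGrammar:
    """Ordered element grammar with flank anchors.

    ``elements`` is a tuple of (name, motif, min_copies, max_copies); the
    order is fixed (Q1, Q2, P1, P2, P3 by default).  ``min_q1_anchor_copies``
    is the number of trailing CAG copies required to anchor a second-run
    (Q1-excluded) read inside the CAG tract.
    """

    elements: tuple[tuple[str, str, int, int | None], ...] = (
        ("Q1", Q1, 1, None),
        ("Q2", Q2, 0, None),
        ("P1", P1, 0, 1),
        ("P2", P2, 0, None),
        ("P3", P3, 0, None),
    )
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    min_q1_anchor_copies: int = 2

    def __post_init__(self) -> None:
        for name, motif, lo, hi in self.elements:
            if not motif:
                raise ValueError(f"element {name}: empty motif")
            if hi is not None and hi < lo:
                raise ValueError(f"element {name}: max_copies < min_copies")
        if not self.flank5 or not self.flank3:
            raise ValueError("both flank anchors are required")


def default_grammar() -> RepeatGrammar:
    return RepeatGrammar()


@dataclass(frozen=True)
class HttStructure:
    """Phased element copy numbers for one HTT allele."""

    q1: int
    q2: int
    p1: int
    p2: int
    p3: int
    label: str = ""
    partial_q2: bool = False
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.label == "":
            object.__setattr__(
                self, "label", structure_label(self.q2, self.p1, self.partial_q2)
            )

    @property
    def post_q1(self) -> tuple[int, int, int, int, bool]:
        """The Q1-independent part of the structure (used by run-2 phasing)."""
        return (self.q2, self.p1, self.p2, self.p3, self.partial_q2)


def structure_label(q2: int, p1: int, partial_q2: bool = False) -> str:
    if partial_q2:
        return "partial_Q2_loss" if (q2 == 0 and p1 == 1) else "other"
    if q2 == 1 and p1 == 1:
        return "canonical"
    if q2 == 2 and p1 == 1:
        return "Q2_duplication"
    if q2 == 0 and p1 == 1:
        return "Q2_loss"
    if q2 == 1 and p1 == 0:
        return "P1_loss"
    if q2 == 0 and p1 == 0:
        return "Q2_P1_loss"
    return "other"


@dataclass(frozen=True)
class PhasedHttGenotype:
    """Both alleles of one individual, phased size-to-structure."""

    smaller: HttStructure | None
    larger: HttStructure
    phasing_method: str  # "spanning_both" | "two_run" | "unphased_smaller"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.smaller is not None and self.smaller.q1 > self.larger.q1:
            raise ValueError("smaller allele has larger q1 than larger allele")


# --- read-level operations --------------------------------------------------

_ACGT = set("ACGT")


def _count_leading(seq: str, pos: int, motif: str, max_copies: int | None) -> tuple[int, int]:
    n = 0
    step = len(motif)
    while seq.startswith(motif, pos) and (max_copies is None or n < max_copies):
        n += 1
        pos += step
    return n, pos


def _locate_region(read: str, grammar: RepeatGrammar, include_q1: bool):
    """Return (region, q1_anchor_copies) or None if the read does not span."""
    if include_q1:
        a = read.find(grammar.flank5)
        if a < 0:
            return None
        start = a + len(grammar.flank5)
        e = read.find(grammar.flank3, start)
        if e < 0:
            return None
        return read[start:e], None
    e = read.find(grammar.flank3)
    if e < 0:
        return None
    region = read[:e]
    anchor = Q1 * grammar.min_q1_anchor_copies
    idx = region.find(anchor)
    if idx < 0:
        return None
    j = idx
    while region.startswith(Q1, j):
        j += len(Q1)
    return region[j:], (j - idx) // len(Q1)


def is_spanning(read: str, grammar: RepeatGrammar | None = None, include_q1: bool = True) -> bool:
    """True iff both anchors flank the analyzed element region (all elements
    when ``include_q1``, Q2..P3 otherwise) and the region is clean A/C/G/T."""
    grammar = grammar or default_grammar()
    located = _locate_region(read.upper(), grammar, include_q1)
    if located is None:
        return False
    region, _ = located
    return set(region) <= _ACGT


def _parse_post_q1(region: str, pos: int) -> tuple[dict, bool, int]:
    """Greedy match of Q2, optional dangling CAA, P1, P2, P3 from ``pos``."""
    counts: dict[str, int] = {}
    counts["q2"], pos = _count_leading(region, pos, Q2, None)
    partial = False
    if region.startswith("CAA", pos) and not region.startswith(Q2, pos):
        partial = True
        pos += 3
    counts["p1"], pos = _count_leading(region, pos, P1, 1)
    counts["p2"], pos = _count_leading(region, pos, P2, None)
    counts["p3"], pos = _count_leading(region, pos, P3, None)
    return counts, partial, pos


def decompose(
    read: str, grammar: RepeatGrammar | None = None, include_q1: bool = True
) -> HttStructure:
    """Decompose one spanning read into exact element copy numbers.

    Greedy left-to-right maximal matching in fixed element order; copy counts
    are exact for grammar-conforming reads.  Residue between the parsed
    elements and the 3' anchor yields label ``other`` with the offset logged.

    Raises
    ------
    NonSpanningReadError
        If the read does not span the chosen element region.
    """
    grammar = grammar or default_grammar()
    read = read.upper()
    located = _locate_region(read, grammar, include_q1)
    if located is None or not (set(located[0]) <= _ACGT):
        raise NonSpanningReadError(
            f"read does not span the {'full' if include_q1 else 'post-Q1'} "
            "element region"
        )
    region, _anchor_copies = located

    pos = 0
    if include_q1:
        q1, pos = _count_leading(region, pos, Q1, None)
        if q1 < 1:
            logger.info("no CAG tract at expected position; labelling other")
            return HttStructure(0, 0, 0, 0, 0, label="other")
    else:
        q1 = -1  # unknown: read anchored inside the tract

    counts, partial, pos = _parse_post_q1(region, pos)
    label = ""
    if pos != len(region):
        logger.info("unparsed residue at offset %d of element region", pos)
        label = "other"
    return HttStructure(
        q1=q1,
        q2=counts["q2"],
        p1=counts["p1"],
        p2=counts["p2"],
        p3=counts["p3"],
        partial_q2=partial,
        label=label,
        supporting_reads=1,
    )


def sequence_from_structure(
    structure: HttStructure,
    grammar: RepeatGrammar | None = None,
    with_flanks: bool = True,
) -> str:
    """Reconstruct the repeat-region sequence encoding a structure
    (inverse of :func:`decompose` on grammar-conforming reads)."""
    grammar = grammar or default_grammar()
    core = (
        Q1 * max(structure.q1, 0)
        + Q2 * structure.q2
        + ("CAA" if structure.partial_q2 else "")
        + P1 * structure.p1
        + P2 * structure.p2
        + P3 * structure.p3
    )
    if with_flanks:
        return grammar.flank5 + core + grammar.flank3
    return core


# --- phasing ----------------------------------------------------------------


def _majority(groups: dict, canonical_key=None) -> tuple:
    """Pick (key, support) with most support; ties prefer canonical, then
    lexicographically smallest key for determinism."""
    best = None
    for key, support in groups.items():
        cand = (support, key == canonical_key, tuple(str(x) for x in key))
        if best is None:
            best = (cand, key, support)
        else:
            (b_support, b_canon, b_key), _, _ = best
            if (cand[0], cand[1]) > (b_support, b_canon) or (
                cand[0] == b_support and cand[1] == b_canon and cand[2] < b_key
            ):
                best = (cand, key, support)
    return best[1], best[2]


def phase_genotype(
    reads: list[str],
    sizes: tuple[int, int],
    grammar: RepeatGrammar | None = None,
    min_support: int = 2,
    confidence_threshold: float = 0.8,
) -> PhasedHttGenotype:
    """Phase CAG size to repeat structure using the two-run scheme.

    Run 1 decomposes reads spanning the full region (Q1 included); the
    majority structure — preferring groups whose q1 matches the upstream
    caller's smaller allele size — is assigned to the smaller allele.  Run 2
    decomposes reads spanning only Q2..P3; the structure not matching run 1's
    assignment is given to the larger allele (with its caller CAG size).  If
    run 1 also contains the larger allele's size the genotype is phased
    directly from spanning reads (``spanning_both``).

    Ties break by higher read support, then canonical-first.  A majority
    below ``confidence_threshold`` of informative reads sets
    ``low_confidence``.
    """
    grammar = grammar or default_grammar()
    if not reads:
        raise ValueError("no reads supplied")
    small_size, large_size = sorted(int(s) for s in sizes)

    run1: dict[tuple, int] = {}
    for read in reads:
        if is_spanning(read, grammar, include_q1=True):
            s = decompose(read, grammar, include_q1=True)
            key = (s.q1, s.q2, s.p1, s.p2, s.p3, s.partial_q2)
            run1[key] = run1.get(key, 0) + 1

    run2: dict[tuple, int] = {}
    for read in reads:
        if is_spanning(read, grammar, include_q1=False):
            s = decompose(read, grammar, include_q1=False)
            key = (s.q2, s.p1, s.p2, s.p3, s.partial_q2)
            run2[key] = run2.get(key, 0) + 1

    low_confidence = False

    # run 1: type the smaller allele
    smaller: HttStructure | None = None
    small_key = None
    small_groups = {k: v for k, v in run1.items() if k[0] == small_size} or run1
    if small_groups:
        small_key, support = _majority(small_groups)
        if support < min_support or support / sum(small_groups.values()) < confidence_threshold:
            low_confidence = True
        smaller = HttStructure(
            q1=small_key[0], q2=small_key[1], p1=small_key[2], p2=small_key[3],
            p3=small_key[4], partial_q2=small_key[5], supporting_reads=support,
        )

    # both alleles visible in run 1?
    large_groups_run1 = {k: v for k, v in run1.items() if k[0] == large_size and k != small_key}
    if large_groups_run1 and not (small_size == large_size and len(run1) == 1):
        key, support = _majority(large_groups_run1)
        larger = HttStructure(
            q1=key[0], q2=key[1], p1=key[2], p2=key[3], p3=key[4],
            partial_q2=key[5], supporting_reads=support,
        )
        return PhasedHttGenotype(smaller, larger, "spanning_both", low_confidence)
    if small_size == large_size and smaller is not None:
        larger = replace(smaller, q1=large_size)
        return PhasedHttGenotype(smaller, larger, "spanning_both", low_confidence)

    # run 2: the "second structure" goes to the larger allele
    small_post = None if smaller is None else smaller.post_q1
    second = {k: v for k, v in run2.items() if k != small_post}
    if second:
        key, support = _majority(second, canonical_key=(1, 1, 0, 0, False))
    elif run2:  # homozygous post-Q1 structure
        key, support = _majority(run2)
    elif smaller is not None:  # no run-2 reads at all: assume shared structure
        key, support = small_post, 0
        low_confidence = True
    else:
        raise ValueError("no spanning reads in either run; genotype unphasable")

    larger = HttStructure(
        q1=large_size, q2=key[0], p1=key[1], p2=key[2], p3=key[3],
        partial_q2=key[4], supporting_reads=support,
    )
    method = "two_run" if smaller is not None else "unphased_smaller"
    return PhasedHttGenotype(smaller, larger, method, low_confidence)


# --- population summaries ---------------------------------------------------


def structure_population_table(alleles: pd.DataFrame) -> pd.DataFrame:
    """Per-population structure proportions from a per-allele table.

    ``alleles`` needs columns ``population``, ``label`` (and optionally
    ``q1``).  Rows sum to 1 within each population; populations with no
    alleles are omitted with a warning.
    """
    required = {"population", "label"}
    if not required <= set(alleles.columns):
        raise ValueError(f"allele table needs columns {sorted(required)}")
    if len(alleles) == 0:
        raise ValueError("empty allele table")
    counts = (
        alleles.groupby(["population", "label"]).size().unstack(fill_value=0)
    )
    for lab in STRUCTURE_LABELS:
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[[c for c in STRUCTURE_LABELS if c in counts.columns]]
    props = counts.div(counts.sum(axis=1), axis=0)
    props["n_alleles"] = counts.sum(axis=1)
    return props.reset_index()


def q1_by_structure_tests(alleles: pd.DataFrame, min_group: int = 3) -> dict:
    """Rank-based comparison of CAG size across structures: Kruskal-Wallis
    followed by pairwise Dunn z-tests with Holm adjustment.

    Groups with fewer than ``min_group`` alleles are dropped with a warning.
    """
    if not {"label", "q1"} <= set(alleles.columns):
        raise ValueError("allele table needs columns label and q1")
    groups = {
        lab: sub["q1"].to_numpy(dtype=float)
        for lab, sub in alleles.groupby("label")
        if len(sub) >= min_group
    }
    dropped = set(alleles["label"]) - set(groups)
    if dropped:
        logger.warning("q1_by_structure_tests: dropping small groups %s", sorted(dropped))
    if len(groups) < 2:
        raise ValueError("need at least two structure groups for comparison")

    labels = sorted(groups)
    h_stat, kw_p = stats.kruskal(*[groups[lab] for lab in labels])

    pooled = np.concatenate([groups[lab] for lab in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for lab in labels:
        k = len(groups[lab])
        mean_ranks[lab] = float(ranks[offset : offset + k].mean())
        sizes[lab] = k
        offset += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows).sort_values("p_raw", kind="stable").reset_index(drop=True)
    m = len(pairwise)
    # Holm step-down: cumulative max over increasing raw p
    holm = []
    running = 0.0
    for i, p in enumerate(pairwise["p_raw"]):
        running = max(running, min(1.0, p * (m - i)))
        holm.append(running)
    pairwise["p_holm"] = holm
    return {"kruskal_h": float(h_stat), "kruskal_p": float(kw_p), "pairwise": pairwise}
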