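"""Machine-readable definitions of repeat-expansion-disorder (RED) loci.

Every downstream step — genotype classification, carrier counting, allele
distribution summaries — classifies repeat sizes against the threshold scheme
held here.  A locus is described by its repeat motif, inheritance mode and
four half-open, lower-inclusive size bands::

    normal        [0, intermediate_min)
    intermediate  [intermediate_min, premutation_min)
    premutation   [premutation_min, full_min)    # includes reduced penetrance
    full          [full_min, inf)

Sizes are integer repeat units, not base pairs.  The premutation and
reduced-penetrance ranges are treated as a single band.

The packaged default registry (``data/loci.yaml``) covers the 16 loci at which
short-read WGS reliably separates premutation from full-mutation alleles.
Any field can be overridden from a user config file.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "AlleleClass",
    "Inheritance",
    "LocusDefinition",
    "LocusRegistry",
    "load_registry",
    "save_registry",
    "classify_allele",
    "repeat_units_from_bp",
]


class Inheritance(str, enum.Enum):
    """Mode of inheritance of the disorder caused by the expansion."""

    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"


class AlleleClass(enum.IntEnum):
    """Ordered repeat-size category; larger alleles never get a smaller class."""

    NORMAL = 0
    INTERMEDIATE = 1
    PREMUTATION = 2
    FULL = 3

    def __str__(self) -> str:  # friendly name for tables
        return self.name.lower()


_DNA = set("ACGT")


@dataclass(frozen=True)
class LocusDefinition:
    """One RED locus: motif, inheritance and classification thresholds.

    Parameters
    ----------
    gene_symbol : str
        HGNC symbol, the registry key.
    disease_name : str
        Disorder caused by the expansion.
    motif : str
        Repeat unit on the reference strand, 1-6 bp over {A,C,G,T}.
    inheritance : Inheritance
    intermediate_min : int or None
        Lower bound (inclusive) of the intermediate/large-normal range, in
        repeat units.  ``None`` when the locus has no defined intermediate
        range; the normal band then extends to ``premutation_min``.
    premutation_min : int
        Lower bound (inclusive) of the premutation / reduced-penetrance band.
    full_min : int
        Lower bound (inclusive) of the fully pathogenic range.
    max_reliable_size : int
        Sizing ceiling in repeat units (read-length bound, or a larger
        validated ceiling).  Must be >= ``full_min`` for the locus to be
        admitted to frequency estimation.
    reference_coordinates : tuple or None
        Optional (contig, start, end), 0-based half-open.
    source : str
        Provenance annotation for the thresholds.
    """

    gene_symbol: str
    disease_name: str
    motif: str
    inheritance: Inheritance
    premutation_min: int
    full_min: int
    max_reliable_size: int
    intermediate_min: int | None = None
    reference_coordinates: tuple[str, int, int] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.motif or not set(self.motif) <= _DNA:
            raise ValueError(
                f"{self.gene_symbol}: motif {self.motif!r} must be a non-empty "
                "string over A/C/G/T"
            )
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"{self.gene_symbol}: motif length must be 1-6 bp")
        if self.intermediate_min is not None and not (
            self.intermediate_min < self.premutation_min
        ):
            raise ValueError(
                f"{self.gene_symbol}: intermediate_min ({self.intermediate_min}) "
                f"must be < premutation_min ({self.premutation_min})"
            )
        if not self.premutation_min <= self.full_min:
            raise ValueError(
                f"{self.gene_symbol}: premutation_min ({self.premutation_min}) "
                f"must be <= full_min ({self.full_min})"
            )
        if self.max_reliable_size < self.full_min:
            raise ValueError(
                f"{self.gene_symbol}: max_reliable_size ({self.max_reliable_size}) "
                f"below full_min ({self.full_min}); locus cannot be admitted to "
                "frequency estimation"
            )


@dataclass
class LocusRegistry:
    """Ordered collection of :class:`LocusDefinition`, keyed by gene symbol."""

    loci: dict[str, LocusDefinition] = field(default_factory=dict)

    def __getitem__(self, gene_symbol: str) -> LocusDefinition:
        try:
            return self.loci[gene_symbol]
        except KeyError:
            raise KeyError(f"locus {gene_symbol!r} not in registry") from None

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self.loci

    def __iter__(self) -> Iterator[LocusDefinition]:
        return iter(self.loci.values())

    def __len__(self) -> int:
        return len(self.loci)

    def add(self, locus: LocusDefinition) -> None:
        if locus.gene_symbol in self.loci:
            raise ValueError(f"duplicate gene symbol {locus.gene_symbol!r}")
        self.loci[locus.gene_symbol] = locus

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.loci)

    def to_frame(self):
        """TSV-ready table of the registry (one row per locus)."""
        import pandas as pd

        rows = []
        for d in self:
            rows.append(
                {
                    "gene_symbol": d.gene_symbol,
                    "disease_name": d.disease_name,
                    "motif": d.motif,
                    "inheritance": d.inheritance.value,
                    "intermediate_min": d.intermediate_min,
                    "premutation_min": d.premutation_min,
                    "full_min": d.full_min,
                    "max_reliable_size": d.max_reliable_size,
                }
            )
        return pd.DataFrame(rows)


def _definition_from_mapping(gene: str, entry: Mapping) -> LocusDefinition:
    ref = entry.get("reference")
    coords = None
    if ref is not None:
        coords = (str(ref["contig"]), int(ref["start"]), int(ref["end"]))
    inter = entry.get("intermediate_min")
    return LocusDefinition(
        gene_symbol=gene,
        disease_name=str(entry.get("disease", "")),
        motif=str(entry["motif"]),
        inheritance=Inheritance(entry["inheritance"]),
        intermediate_min=None if inter is None else int(inter),
        premutation_min=int(entry["premutation_min"]),
        full_min=int(entry["full_min"]),
        max_reliable_size=int(entry["max_reliable_size"]),
        reference_coordinates=coords,
        source=str(entry.get("source", "")),
    )


def _parse_config(text: str, origin: str) -> dict[str, dict]:
    try:
        parsed = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"malformed locus config {origin}{where}: {exc}") from exc
    if not isinstance(parsed, dict):
        raise ValueError(f"malformed locus config {origin}: expected a mapping")
    return parsed


def _packaged_defaults() -> dict[str, dict]:
    text = resources.files("redprev.data").joinpath("loci.yaml").read_text()
    return _parse_config(text, "<packaged loci.yaml>")


def load_registry(path: str | Path | None = None) -> LocusRegistry:
    """Load the locus registry, optionally overriding packaged defaults.

    With ``path=None`` the packaged 16-locus default registry is returned.
    A user config file may redefine individual fields of existing loci or add
    new loci; unspecified fields fall back to the packaged values.

    Raises
    ------
    ValueError
        On a malformed config file (naming the line) or a threshold-ordering
        violation (naming the locus).
    """
    entries = _packaged_defaults()
    if path is not None:
        user = _parse_config(Path(path).read_text(), str(path))
        for gene, fields in user.items():
            if not isinstance(fields, Mapping):
                raise ValueError(f"malformed entry for locus {gene!r} in {path}")
            merged = dict(entries.get(gene, {}))
            merged.update(fields)
            entries[gene] = merged

    registry = LocusRegistry()
    for gene, entry in entries.items():
        try:
            registry.add(_definition_from_mapping(gene, entry))
        except KeyError as exc:
            raise ValueError(f"locus {gene}: missing required field {exc}") from exc
    return registry


def save_registry(registry: LocusRegistry, path: str | Path) -> None:
    """Serialize a registry to the same YAML dialect ``load_registry`` reads."""
    out: dict[str, dict] = {}
    for d in registry:
        entry: dict = {
            "disease": d.disease_name,
            "motif": d.motif,
            "inheritance": d.inheritance.value,
            "intermediate_min": d.intermediate_min,
            "premutation_min": d.premutation_min,
            "full_min": d.full_min,
            "max_reliable_size": d.max_reliable_size,
            "source": d.source,
        }
        if d.reference_coordinates is not None:
            contig, start, end = d.reference_coordinates
            entry["reference"] = {"contig": contig, "start": start, "end": end}
        out[d.gene_symbol] = entry
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def classify_allele(size: int, locus: LocusDefinition) -> AlleleClass:
    """Classify a repeat size (in repeat units) into the locus's size bands.

    Bands are half-open and lower-inclusive; when the locus has no defined
    intermediate range the normal band extends to ``premutation_min``.

    Raises
    ------
    ValueError
        If ``size`` < 1 (no allele can have fewer than one repeat unit).
    """
    size = int(size)
    if size < 1:
        raise ValueError(f"repeat size must be >= 1 repeat unit, got {size}")
    if size >= locus.full_min:
        return AlleleClass.FULL
    if size >= locus.premutation_min:
        return AlleleClass.PREMUTATION
    if locus.intermediate_min is not None and size >= locus.intermediate_min:
        return AlleleClass.INTERMEDIATE
    return AlleleClass.NORMAL


def repeat_units_from_bp(length_bp: int, motif: str) -> int:
    """Convert a tract length in bp to repeat units (truncating division)."""
    if length_bp < 0:
        raise ValueError("tract length must be non-negative")
    return int(length_bp) // len(motif)
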