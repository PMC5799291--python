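"""Reading and validation of miRNA annotation tables.

Three kinds of tables are consumed:

* host annotations — one row per intragenic pre-miRNA with its host gene,
  its location class (intronic/exonic) and its orientation relative to the
  host (sense/antisense);
* a mature ↔ precursor map linking mature miRNA identifiers to the
  pre-miRNAs they derive from (many-to-many);
* two independent tables of experimentally validated miRNA → target-gene
  interactions.  An interaction counts as *validated* only when it is
  present in both tables.

Gene identifiers are official symbols, upper-cased on input; mature miRNA
identifiers are matched case-insensitively (lower-cased on input) and
otherwise exactly — no -3p/-5p collapsing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "LocationClass",
    "Orientation",
    "ClassFilter",
    "MirnaGeneAnnotation",
    "MaturePrecursorMap",
    "TargetInteraction",
    "ValidatedTargetSet",
    "AnnotationFormatError",
    "read_host_annotations",
    "read_mature_map",
    "read_target_interactions",
    "intersect_validated_targets",
    "filter_mirna_class",
    "write_validated_targets",
    "read_validated_targets",
]


class AnnotationFormatError(ValueError):
    """A table does not declare the columns the reader requires."""


class LocationClass(str, Enum):
    INTRONIC = "intronic"
    EXONIC = "exonic"


class Orientation(str, Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"


class ClassFilter(str, Enum):
    """miRNA class restriction used when building a network."""

    ALL_INTRAGENIC = "all_intragenic"
    INTRONIC_SENSE = "intronic_sense"


@dataclass(frozen=True)
class MirnaGeneAnnotation:
    """One intragenic pre-miRNA and the gene that hosts it."""

    pre_mirna_id: str
    host_gene: str
    location_class: LocationClass
    orientation: Orientation


@dataclass(frozen=True)
class TargetInteraction:
    """One miRNA → gene interaction from a single source database."""

    mature_mirna_id: str
    target_gene: str
    source: str


#: mature miRNA id -> set of precursor ids
MaturePrecursorMap = dict[str, frozenset[str]]

#: set of validated (mature miRNA, target gene) pairs
ValidatedTargetSet = frozenset[tuple[str, str]]


def _normalize_gene(symbol: str, synonyms: Mapping[str, str] | None = None) -> str:
    symbol = symbol.strip().upper()
    if synonyms:
        symbol = synonyms.get(symbol, symbol)
    return symbol


def _normalize_mature(mirna: str) -> str:
    return mirna.strip().lower()


def _open_rows(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Read a delimited text table, sniffing tab vs comma from the header."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise AnnotationFormatError(f"{path}: empty file, no header")
        delimiter = "\t" if header_line.count("\t") >= header_line.count(",") else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        fieldnames = [f.strip() for f in reader.fieldnames or []]
        reader.fieldnames = fieldnames
        rows = [row for row in reader]
    return fieldnames, rows


def _require_columns(path: str | Path, fieldnames: Sequence[str], required: Iterable[str]) -> None:
    missing = [c for c in required if c not in fieldnames]
    if missing:
        raise AnnotationFormatError(f"{path}: missing required column(s) {missing}")


_LOCATION_ALIASES = {
    "intronic": LocationClass.INTRONIC,
    "intron": LocationClass.INTRONIC,
    "exonic": LocationClass.EXONIC,
    "exon": LocationClass.EXONIC,
}
_ORIENTATION_ALIASES = {
    "sense": Orientation.SENSE,
    "s": Orientation.SENSE,
    "antisense": Orientation.ANTISENSE,
    "as": Orientation.ANTISENSE,
}


def read_host_annotations(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[MirnaGeneAnnotation]:
    """Read the intragenic pre-miRNA / host-gene table.

    Parameters
    ----------
    path
        Tab- or comma-separated table with a header.
    columns
        Optional mapping from the logical column names
        ``{"pre_mirna_id", "host_gene", "location_class", "orientation"}``
        to the names used in the file.
    synonyms
        Optional gene-symbol synonym map applied after upper-casing.
    """
    cols = {
        "pre_mirna_id": "pre_mirna_id",
        "host_gene": "host_gene",
        "location_class": "location_class",
        "orientation": "orientation",
    }
    if columns:
        cols.update(columns)
    fieldnames, rows = _open_rows(path)
    _require_columns(path, fieldnames, cols.values())

    records: list[MirnaGeneAnnotation] = []
    host_of: dict[str, str] = {}
    for i, row in enumerate(rows, start=2):  # header is line 1
        pre = row[cols["pre_mirna_id"]].strip().lower()
        host = _normalize_gene(row[cols["host_gene"]], synonyms)
        if not pre:
            raise ValueError(f"{path}: line {i}: empty pre_mirna_id")
        if not host:
            raise ValueError(f"{path}: line {i}: empty host_gene")
        loc_raw = row[cols["location_class"]].strip().lower()
        ori_raw = row[cols["orientation"]].strip().lower()
        if loc_raw not in _LOCATION_ALIASES:
            raise ValueError(f"{path}: line {i}: unknown location class {loc_raw!r}")
        if ori_raw not in _ORIENTATION_ALIASES:
            raise ValueError(f"{path}: line {i}: unknown orientation {ori_raw!r}")
        rec = MirnaGeneAnnotation(pre, host, _LOCATION_ALIASES[loc_raw], _ORIENTATION_ALIASES[ori_raw])
        # A pre-miRNA may legitimately appear several times (e.g. one row per
        # transcript isoform) but never with two different host genes.
        if rec.pre_mirna_id in host_of and host_of[rec.pre_mirna_id] != rec.host_gene:
            raise ValueError(
                f"{path}: line {i}: pre-miRNA {pre!r} annotated with conflicting "
                f"host genes {host_of[pre]!r} and {host!r}"
            )
        host_of[rec.pre_mirna_id] = rec.host_gene
        records.append(rec)
    return records


def read_mature_map(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
) -> MaturePrecursorMap:
    """Read the mature-miRNA ↔ pre-miRNA mapping table (many-to-many)."""
    cols = {"mature_mirna_id": "mature_mirna_id", "pre_mirna_id": "pre_mirna_id"}
    if columns:
        cols.update(columns)
    fieldnames, rows = _open_rows(path)
    _require_columns(path, fieldnames, cols.values())
    mapping: dict[str, set[str]] = {}
    for i, row in enumerate(rows, start=2):
        mature = _normalize_mature(row[cols["mature_mirna_id"]])
        pre = row[cols["pre_mirna_id"]].strip().lower()
        if not mature or not pre:
            raise ValueError(f"{path}: line {i}: empty identifier")
        mapping.setdefault(mature, set()).add(pre)
    return {m: frozenset(ps) for m, ps in mapping.items()}


def read_target_interactions(
    path: str | Path,
    source: str,
    *,
    columns: Mapping[str, str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[TargetInteraction]:
    """Read one validated-target table, tagging every row with ``source``.

    Duplicate (mature, target) rows — one per supporting experiment in the
    source databases — are deduplicated silently with a log message.
    """
    cols = {"mature_mirna_id": "mature_mirna_id", "target_gene": "target_gene"}
    if columns:
        cols.update(columns)
    fieldnames, rows = _open_rows(path)
    _require_columns(path, fieldnames, cols.values())
    seen: set[tuple[str, str]] = set()
    out: list[TargetInteraction] = []
    n_dup = 0
    for i, row in enumerate(rows, start=2):
        mature = _normalize_mature(row[cols["mature_mirna_id"]])
        gene = _normalize_gene(row[cols["target_gene"]], synonyms)
        if not mature or not gene:
            raise ValueError(f"{path}: line {i}: empty identifier")
        key = (mature, gene)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(TargetInteraction(mature, gene, source))
    if n_dup:
        logger.info("%s: deduplicated %d repeated interaction rows", path, n_dup)
    return out


def intersect_validated_targets(
    a: Sequence[TargetInteraction], b: Sequence[TargetInteraction]
) -> ValidatedTargetSet:
    """Pairs present simultaneously in both source tables.

    Symmetric in its arguments; an empty intersection is a valid result.
    """
    sources_a = {t.source for t in a}
    sources_b = {t.source for t in b}
    if sources_a & sources_b and (a and b):
        raise ValueError(
            f"the two interaction lists must come from distinct sources, "
            f"got {sorted(sources_a)} and {sorted(sources_b)}"
        )
    pairs_a = {(t.mature_mirna_id, t.target_gene) for t in a}
    pairs_b = {(t.mature_mirna_id, t.target_gene) for t in b}
    return frozenset(pairs_a & pairs_b)


def filter_mirna_class(
    annotations: Sequence[MirnaGeneAnnotation],
    class_filter: ClassFilter | str,
) -> list[MirnaGeneAnnotation]:
    """Restrict host annotations to a miRNA class.

    ``all_intragenic`` is the identity; ``intronic_sense`` keeps records with
    intronic location and sense orientation.
    """
    class_filter = ClassFilter(class_filter)
    if class_filter is ClassFilter.ALL_INTRAGENIC:
        return list(annotations)
    return [
        r
        for r in annotations
        if r.location_class is LocationClass.INTRONIC and r.orientation is Orientation.SENSE
    ]


def write_validated_targets(targets: ValidatedTargetSet, path: str | Path) -> None:
    """Write the validated set as a two-column TSV (mature_mirna_id, target_gene)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("mature_mirna_id\ttarget_gene\n")
        for mature, gene in sorted(targets):
            fh.write(f"{mature}\t{gene}\n")


def read_validated_targets(path: str | Path) -> ValidatedTargetSet:
    """Read a two-column TSV written by :func:`write_validated_targets`."""
    fieldnames, rows = _open_rows(path)
    _require_columns(path, fieldnames, ["mature_mirna_id", "target_gene"])
    return frozenset(
        (_normalize_mature(r["mature_mirna_id"]), _normalize_gene(r["target_gene"])) for r in rows
    )
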