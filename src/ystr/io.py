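"""Read and write Y-STR haplotype tables in a documented CSV dialect.

One row per male sample; one column per panel locus; multi-allele cells
(DYS385 pairs, duplicated patterns) hold the alleles joined by a separator
distinct from the CSV delimiter — semicolon by default, so unquoted files
stay parseable.  A comma inside a quoted cell (the convention the printed
tables use, e.g. ``"11,14"``) is accepted on input.

Leading non-locus columns are sample metadata; ``sample_id`` is required.
Header tokens are case-insensitive and locus aliases (``YGATAH``) resolve.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from typing import IO, Iterable

from .core import (
    PANEL,
    AlleleSet,
    FounderSignature,
    Haplotype,
    Population,
    canonical_locus,
)

__all__ = [
    "TableDialect",
    "TableFormatError",
    "read_population",
    "write_population",
    "read_signature",
    "write_signature",
]


class TableFormatError(ValueError):
    """A haplotype table violates the dialect (missing column, bad token...)."""


@dataclass(frozen=True)
class TableDialect:
    """CSV dialect for haplotype tables."""

    delimiter: str = ","
    multi_allele_separator: str = ";"
    locus_header_order: tuple[str, ...] = PANEL

    def __post_init__(self) -> None:
        if self.multi_allele_separator == self.delimiter:
            raise ValueError("multi-allele separator must differ from the delimiter")


DEFAULT_DIALECT = TableDialect()


def _split_cell(cell: str, dialect: TableDialect) -> list[str]:
    tokens = [t for t in cell.split(dialect.multi_allele_separator)]
    if len(tokens) == 1 and "," in cell and dialect.delimiter != ",":
        tokens = cell.split(",")
    elif len(tokens) == 1 and "," in cell:
        # quoted "11,14" style cell under a comma delimiter
        tokens = cell.split(",")
    return [t.strip() for t in tokens if t.strip()]


def _classify_header(header: list[str]) -> tuple[dict[str, int], dict[str, int]]:
    """Split header columns into locus columns and metadata columns."""
    locus_cols: dict[str, int] = {}
    meta_cols: dict[str, int] = {}
    for idx, raw in enumerate(header):
        name = raw.strip()
        try:
            locus_cols[canonical_locus(name)] = idx
        except KeyError:
            meta_cols[name] = idx
    return locus_cols, meta_cols


def read_population(
    source: IO[str] | str,
    dialect: TableDialect = DEFAULT_DIALECT,
    name: str = "",
) -> Population:
    """Parse a haplotype table into a :class:`Population`, preserving row order.

    Raises :class:`TableFormatError` for a missing locus column, a
    non-numeric allele token (with row and column named), or a duplicate
    sample id.
    """
    if isinstance(source, str):
        source = _stdio.StringIO(source)
    reader = csv.reader(source, delimiter=dialect.delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise TableFormatError("empty input: no header row") from None

    locus_cols, meta_cols = _classify_header(header)
    missing = [loc for loc in PANEL if loc not in locus_cols]
    if missing:
        raise TableFormatError(f"missing locus column(s): {', '.join(missing)}")
    id_col = next(
        (idx for key, idx in meta_cols.items() if key.lower() == "sample_id"), None
    )
    if id_col is None:
        raise TableFormatError("missing required 'sample_id' column")
    meta_cols = {k: v for k, v in meta_cols.items() if k.lower() != "sample_id"}

    members: list[Haplotype] = []
    for row_num, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        sample_id = row[id_col].strip()
        locus_values: dict[str, AlleleSet] = {}
        for locus, idx in locus_cols.items():
            cell = row[idx] if idx < len(row) else ""
            tokens = _split_cell(cell, dialect)
            if not tokens:
                raise TableFormatError(
                    f"row {row_num} ({sample_id}): empty cell at locus {locus}"
                )
            try:
                locus_values[locus] = AlleleSet(tokens)
            except ValueError as exc:
                raise TableFormatError(
                    f"row {row_num} ({sample_id}), locus {locus}: {exc}"
                ) from None
        metadata = {
            key: row[idx].strip()
            for key, idx in meta_cols.items()
            if idx < len(row) and row[idx].strip()
        }
        members.append(Haplotype(sample_id, locus_values, metadata))

    try:
        return Population(name=name, members=members)
    except ValueError as exc:
        raise TableFormatError(str(exc)) from None


def write_population(
    pop: Population,
    dialect: TableDialect = DEFAULT_DIALECT,
    stream: IO[str] | None = None,
) -> str:
    """Serialise a population to the CSV dialect; returns the text.

    Output is deterministic: header, then one row per member in order;
    multi-allele cells are joined smallest allele first.
    ``read_population(write_population(p)) == p``.
    """
    out = stream if stream is not None else _stdio.StringIO()
    meta_keys: list[str] = []
    for h in pop.members:
        for key in h.metadata:
            if key not in meta_keys:
                meta_keys.append(key)
    writer = csv.writer(out, delimiter=dialect.delimiter, lineterminator="\n")
    writer.writerow(["sample_id", *meta_keys, *dialect.locus_header_order])
    for h in pop.members:
        row = [h.sample_id]
        row.extend(h.metadata.get(key, "") for key in meta_keys)
        row.extend(
            str(h[loc]).replace(",", dialect.multi_allele_separator)
            for loc in dialect.locus_header_order
        )
        writer.writerow(row)
    if stream is not None:
        return ""
    return out.getvalue()


def read_signature(
    source: IO[str] | str,
    dialect: TableDialect = DEFAULT_DIALECT,
    name: str = "",
) -> FounderSignature:
    """Read a one-row partial haplotype (founder signature) table.

    Unlike a full haplotype table the header may cover any subset of the
    panel; a ``name`` column, if present, names the signature.
    """
    if isinstance(source, str):
        source = _stdio.StringIO(source)
    reader = csv.reader(source, delimiter=dialect.delimiter)
    try:
        header = next(reader)
        row = next(reader)
    except StopIteration:
        raise TableFormatError("signature file needs a header and one row") from None
    locus_cols, meta_cols = _classify_header(header)
    if not locus_cols:
        raise TableFormatError("signature file has no locus columns")
    locus_values = {}
    for locus, idx in locus_cols.items():
        tokens = _split_cell(row[idx] if idx < len(row) else "", dialect)
        if tokens:
            locus_values[locus] = AlleleSet(tokens)
    for key, idx in meta_cols.items():
        if key.lower() == "name" and idx < len(row) and row[idx].strip():
            name = row[idx].strip()
    return FounderSignature(name=name, locus_values=locus_values)


def write_signature(
    sig: FounderSignature, dialect: TableDialect = DEFAULT_DIALECT
) -> str:
    """Serialise a founder signature as a one-row table over its loci."""
    out = _stdio.StringIO()
    writer = csv.writer(out, delimiter=dialect.delimiter, lineterminator="\n")
    loci = sig.loci
    writer.writerow(["name", *loci])
    writer.writerow(
        [sig.name]
        + [str(sig[loc]).replace(",", dialect.multi_allele_separator) for loc in loci]
    )
    return out.getvalue()
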