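"""Amino-acid property tables: AAindex flat-file I/O and the packaged reduced index.

The AAindex database assigns each of the 20 standard amino acids one measured
biochemical/physical value per index (hydropathy, polarity, surrounding-residue
counts, ...).  This module parses the AAindex1 flat-file dialect, assembles
complete indices into a 20 x m :class:`IndexTable`, and ships the package's
reduced 8-property table (``load_raaindex``) used for sequence encoding.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AAindexParseError, EmptyTableError

#: Canonical one-letter residue order (Ala..Val by three-letter name).
RESIDUES: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)

#: Residue order of the two numeric rows under an AAindex ``I`` line:
#: first row A R N D C Q E G H I, second row L K M F P S T W Y V.
_I_LINE_ORDER: tuple[str, ...] = RESIDUES[:10] + RESIDUES[10:]


@dataclass
class PropertyIndex:
    """One AAindex entry: a named scale over the 20 standard residues.

    ``values`` maps each residue to a float; missing measurements are
    ``math.nan``.  ``provenance`` carries the free-text citation lines.
    """

    accession: str
    description: str = ""
    values: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        missing = set(RESIDUES) - set(self.values)
        extra = set(self.values) - set(RESIDUES)
        if missing or extra:
            raise ValueError(
                f"{self.accession}: values must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def has_na(self) -> bool:
        return any(math.isnan(v) for v in self.values.values())


class IndexTable:
    """A complete 20-residue x m-property numeric matrix.

    Rows follow the canonical residue order; columns are unique AAindex-style
    accessions.  NA values are not allowed: incomplete indices must be dropped
    (see :func:`to_index_table`) before construction.
    """

    def __init__(self, values: pd.DataFrame, descriptions: Mapping[str, str] | None = None):
        if list(values.index) != list(RESIDUES):
            values = values.reindex(list(RESIDUES))
        if values.isna().any().any():
            raise ValueError("IndexTable must not contain NA values")
        if values.shape[1] == 0:
            raise EmptyTableError("IndexTable needs at least one property")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate property accessions: {dupes}")
        self._df = values.astype(float)
        self.descriptions: dict[str, str] = dict(descriptions or {})

    # -- accessors -----------------------------------------------------
    @property
    def residues(self) -> tuple[str, ...]:
        return RESIDUES

    @property
    def properties(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_properties(self) -> int:
        return self._df.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Residue-by-property DataFrame (a copy)."""
        return self._df.copy()

    def to_numpy(self) -> np.ndarray:
        return self._df.to_numpy(copy=True)

    def value(self, residue: str, accession: str) -> float:
        return float(self._df.at[residue, accession])

    def row(self, residue: str) -> np.ndarray:
        """Property vector of one residue, in column order."""
        return self._df.loc[residue].to_numpy(copy=True)

    def subset(self, accessions: Iterable[str]) -> "IndexTable":
        accessions = list(accessions)
        return IndexTable(self._df[accessions], {a: self.descriptions.get(a, "") for a in accessions})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IndexTable):
            return NotImplemented
        return self.properties == other.properties and np.array_equal(
            self._df.to_numpy(), other._df.to_numpy()
        )

    def __repr__(self) -> str:
        return f"IndexTable({self.n_properties} properties x 20 residues)"


# ---------------------------------------------------------------------------
# AAindex1 flat-file parsing

def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_aaindex(stream: IO[str] | str) -> list[PropertyIndex]:
    """Parse AAindex1 flat-file text into :class:`PropertyIndex` records.

    Records are blocks of ``H/D/R/A/T/J/C/I`` lines terminated by ``//``; the
    ``I`` line header is followed by two rows of ten values in the order
    A R N D C Q E G H I / L K M F P S T W Y V.  ``NA`` tokens become NaN.
    Pair-substitution matrices (AAindex2/3 ``M`` records) are rejected.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    records: list[PropertyIndex] = []
    for raw in text.split("//"):
        block = raw.strip("\n").strip()
        if not block:
            continue
        records.append(_parse_record(raw))
    return records


def _parse_record(raw: str) -> PropertyIndex:
    lines = [ln for ln in raw.splitlines() if ln.strip()]
    fields: dict[str, list[str]] = {}
    current: str | None = None
    for ln in lines:
        tag = ln[0] if ln[0] != " " else None
        if tag is not None and tag.isalpha() and (len(ln) == 1 or ln[1] == " " or len(ln.split()) >= 1):
            current = tag
            fields.setdefault(tag, []).append(ln[1:].strip())
        elif current is not None:
            fields[current].append(ln.strip())
        else:
            raise AAindexParseError(f"continuation line before any record tag: {ln!r}")

    accession = fields.get("H", [""])[0].split()[0] if fields.get("H") and fields["H"][0] else ""
    if not accession:
        raise AAindexParseError(
            f"record missing H (accession) line: {lines[0][:60]!r}..."
        )
    if "M" in fields:
        raise AAindexParseError(
            f"{accession}: pair-substitution matrices (AAindex2/3 'M' records) are not supported"
        )
    if "I" not in fields:
        raise AAindexParseError(f"{accession}: record missing I (index data) line")

    i_lines = fields["I"]
    # First I line is the residue header (A/L R/K ...); the numbers follow.
    tokens: list[str] = []
    for ln in i_lines[1:] if "/" in i_lines[0] else i_lines:
        tokens.extend(ln.split())
    if len(tokens) != 20:
        raise AAindexParseError(
            f"{accession}: expected 20 values under I line, found {len(tokens)}"
        )
    values: dict[str, float] = {}
    for residue, tok in zip(_I_LINE_ORDER, tokens):
        if tok.upper() == "NA":
            values[residue] = math.nan
        elif _is_number(tok):
            values[residue] = float(tok)
        else:
            raise AAindexParseError(f"{accession}: non-numeric value {tok!r} under I line")

    provenance_parts = []
    for tag in ("R", "A", "T", "J"):
        if tag in fields:
            provenance_parts.append(" ".join(fields[tag]))
    return PropertyIndex(
        accession=accession,
        description=" ".join(fields.get("D", [])),
        values=values,
        provenance="; ".join(provenance_parts),
    )


def to_index_table(
    indices: Iterable[PropertyIndex],
) -> tuple[IndexTable, list[str]]:
    """Assemble complete indices into an :class:`IndexTable`.

    Indices with a missing (NA) value for any residue are excluded, mirroring
    the preprocessing step that removes incomplete scales before selection.

    Returns the table and the list of dropped accessions.
    """
    indices = list(indices)
    seen: set[str] = set()
    for idx in indices:
        if idx.accession in seen:
            raise ValueError(f"duplicate accession in collection: {idx.accession}")
        seen.add(idx.accession)
    kept = [idx for idx in indices if not idx.has_na]
    dropped = [idx.accession for idx in indices if idx.has_na]
    if not kept:
        raise EmptyTableError(
            f"no complete indices remain ({len(dropped)} dropped for missing values)"
        )
    data = {idx.accession: [idx.values[r] for r in RESIDUES] for idx in kept}
    df = pd.DataFrame(data, index=list(RESIDUES))
    table = IndexTable(df, {idx.accession: idx.description for idx in kept})
    return table, dropped


def to_property_indices(table: IndexTable) -> list[PropertyIndex]:
    """Explode an :class:`IndexTable` back into per-property records."""
    df = table.to_frame()
    return [
        PropertyIndex(
            accession=acc,
            description=table.descriptions.get(acc, ""),
            values=dict(zip(RESIDUES, df[acc])),
        )
        for acc in table.properties
    ]


# ---------------------------------------------------------------------------
# TSV round-trip

def write_table(table: IndexTable, stream: IO[str] | None = None) -> str:
    """Serialize an :class:`IndexTable` as TSV (residue rows, accession columns)."""
    text = table.to_frame().to_csv(sep="\t", index_label="residue", lineterminator="\n")
    if stream is not None:
        stream.write(text)
    return text


def read_table(stream: IO[str] | str) -> IndexTable:
    """Read a TSV property table written by :func:`write_table`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", index_col="residue")
    return IndexTable(df)


# ---------------------------------------------------------------------------
# Packaged reduced table

#: Accessions of the packaged 8-property reduced index, in column order.
RAAINDEX_ACCESSIONS: tuple[str, ...] = (
    "JACR890101", "COWR900101", "ZIMJ680103", "MEEJ810102",
    "FAUJ880110", "WARP780101", "PONP800108", "LIFS790102",
)

_raaindex_cache: IndexTable | None = None


def load_raaindex() -> IndexTable:
    """Load the packaged reduced amino-acid index (8 properties x 20 residues).

    The table ships with the package and is identical on every call.  Two
    published description sets exist for these accessions; both are exposed
    via :func:`load_raaindex_annotations` without adjudicating between them.
    """
    global _raaindex_cache
    if _raaindex_cache is None:
        with resources.files("raaindex.data").joinpath("raaindex.tsv").open() as fh:
            table = read_table(fh)
        assert table.properties == list(RAAINDEX_ACCESSIONS)
        _raaindex_cache = table
    return _raaindex_cache


def load_raaindex_annotations() -> pd.DataFrame:
    """Both description sets published for the 8 reduced-index accessions."""
    with resources.files("raaindex.data").joinpath("raaindex_annotations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="accession")
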