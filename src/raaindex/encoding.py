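"""Numeric feature coding of aligned protein sequences.

A gapped alignment is first reduced to its homologous block (columns below a
gap-fraction cutoff; by default strictly gap-free).  Each sequence in the
block is then turned into a flat feature vector by concatenating a
per-residue code from the N- to the C-terminus:

* ``bpp`` — the residue's row from an :class:`~raaindex.aaindex.IndexTable`
  (d = number of properties, 8 for the packaged reduced index);
* ``binary8`` — the 8-bit big-endian binary expansion of the residue's
  ordinal (0-19) in the canonical residue order, the conventional
  information-free baseline.

Family labels ride along as metadata and never enter the encoding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aaindex import RESIDUES, IndexTable
from .errors import EmptyBlockError, EncodingError

GAP = "-"
_RESIDUE_ORDINAL = {r: i for i, r in enumerate(RESIDUES)}

#: Exported bit table: residue -> 8-tuple of 0/1 (big-endian ordinal).
BINARY8_TABLE: dict[str, tuple[int, ...]] = {
    r: tuple((i >> (7 - b)) & 1 for b in range(8)) for r, i in _RESIDUE_ORDINAL.items()
}
_BITS_TO_RESIDUE = {bits: r for r, bits in BINARY8_TABLE.items()}


@dataclass
class AlignedRecord:
    id: str
    sequence: str
    family: str | None = None


@dataclass
class Alignment:
    """Equal-length gapped sequences over the 20 residues plus ``-``."""

    records: list[AlignedRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")
        for rec in self.records:
            bad = set(rec.sequence) - set(RESIDUES) - {GAP}
            if bad:
                raise ValueError(f"{rec.id}: unexpected symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def families(self) -> list[str | None]:
        return [r.family for r in self.records]

    def to_char_matrix(self) -> np.ndarray:
        return np.array([list(r.sequence) for r in self.records])


def read_alignment(
    source: str | Path | IO[str], tags: dict[str, str] | None = None
) -> Alignment:
    """Read an aligned FASTA file; ``.`` gaps are normalized to ``-``.

    Family labels come from an ``id -> family`` mapping (e.g. a sidecar TSV,
    see :func:`read_family_tags`) or, failing that, from a ``family=NAME``
    token in the FASTA description line.
    """
    handle = io.StringIO(source) if isinstance(source, str) and "\n" in source else source
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        family = None
        if tags and rec.id in tags:
            family = tags[rec.id]
        else:
            for token in rec.description.split():
                if token.startswith("family="):
                    family = token.split("=", 1)[1]
        seq = str(rec.seq).upper().replace(".", GAP)
        records.append(AlignedRecord(id=rec.id, sequence=seq, family=family))
    return Alignment(records)


def read_family_tags(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a two-column (id, family) TSV into a mapping."""
    df = pd.read_csv(source, sep="\t", header=None, names=["id", "family"], dtype=str)
    return dict(zip(df["id"], df["family"]))


def write_alignment(aln: Alignment, stream: IO[str]) -> None:
    for rec in aln.records:
        header = rec.id if rec.family is None else f"{rec.id} family={rec.family}"
        stream.write(f">{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Homologous-block extraction

def extract_block(
    aln: Alignment, max_gap_fraction: float = 0.0
) -> tuple[Alignment, dict]:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_fraction``.

    With the strict default every column containing any gap is removed, so the
    result is gap-free.  If a tolerance is allowed, residual gaps in retained
    columns are imputed by the column's majority residue (ties broken by
    canonical residue order) and logged.

    Returns the block and a log with the retained column indices (0-based,
    relative to the input) and any imputations performed.
    """
    if not (0.0 <= max_gap_fraction < 1.0):
        raise ValueError("max_gap_fraction must lie in [0, 1)")
    chars = aln.to_char_matrix()
    gap_frac = (chars == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    if keep.size == 0:
        raise EmptyBlockError(
            f"no columns with gap fraction <= {max_gap_fraction} remain"
        )
    block = chars[:, keep]
    imputations: list[dict] = []
    gap_rows, gap_cols = np.nonzero(block == GAP)
    for r, c in zip(gap_rows, gap_cols):
        col = block[:, c]
        residues, counts = np.unique(col[col != GAP], return_counts=True)
        order = sorted(
            zip(residues, counts), key=lambda rc: (-rc[1], _RESIDUE_ORDINAL[rc[0]])
        )
        majority = order[0][0]
        imputations.append(
            {"id": aln.records[r].id, "column": int(keep[c]), "imputed": majority}
        )
        block[r, c] = majority
    records = [
        AlignedRecord(id=rec.id, sequence="".join(row), family=rec.family)
        for rec, row in zip(aln.records, block)
    ]
    log = {"kept_columns": keep.tolist(), "imputations": imputations}
    return Alignment(records), log


# ---------------------------------------------------------------------------
# Per-sequence coders

def _check_sequence(seq: str) -> None:
    if not seq:
        raise EncodingError("cannot encode an empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in _RESIDUE_ORDINAL:
            raise EncodingError(
                f"unencodable residue {ch!r} at position {pos} "
                "(only the 20 standard one-letter codes are supported)"
            )


def encode_bpp(seq: str, table: IndexTable) -> np.ndarray:
    """Concatenated property rows (N to C): length ``L * m`` for m properties."""
    _check_sequence(seq)
    rows = table.to_frame().to_numpy()
    return np.concatenate([rows[_RESIDUE_ORDINAL[ch]] for ch in seq])


def encode_binary8(seq: str) -> np.ndarray:
    """Concatenated 8-bit ordinal codes (N to C): length ``L * 8``, entries 0/1."""
    _check_sequence(seq)
    return np.concatenate([BINARY8_TABLE[ch] for ch in seq]).astype(float)


def decode_binary8(vector: Sequence[float]) -> str:
    """Inverse of :func:`encode_binary8`."""
    arr = np.asarray(vector)
    if arr.size % 8 != 0:
        raise EncodingError(f"binary8 vector length {arr.size} is not a multiple of 8")
    out = []
    for i in range(arr.size // 8):
        bits = tuple(int(round(b)) for b in arr[8 * i : 8 * i + 8])
        if bits not in _BITS_TO_RESIDUE:
            raise EncodingError(f"bit pattern {bits} at residue {i} decodes to no residue")
        out.append(_BITS_TO_RESIDUE[bits])
    return "".join(out)


# ---------------------------------------------------------------------------
# Whole-set encoding

@dataclass
class EncodedMatrix:
    """n_sequences x (L*d) feature lattice with scheme and family metadata."""

    ids: list[str]
    families: list[str | None]
    scheme: str  # "bpp" | "binary8"
    block_length: int
    columns: list[str]
    matrix: np.ndarray
    table_properties: list[str] | None = None

    def __post_init__(self) -> None:
        n, w = self.matrix.shape
        if n != len(self.ids) or w != len(self.columns):
            raise ValueError("matrix shape inconsistent with ids/columns")

    @property
    def d(self) -> int:
        return len(self.columns) // self.block_length

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.ids, columns=self.columns)
        df.index.name = "id"
        return df


def encode_set(
    aln: Alignment, scheme: str, table: IndexTable | None = None
) -> EncodedMatrix:
    """Encode every sequence of a gap-free alignment under one scheme."""
    if scheme not in ("bpp", "binary8"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "bpp":
        if table is None:
            raise ValueError("scheme 'bpp' requires an IndexTable")
        labels = table.properties
    else:
        labels = [f"bit{b}" for b in range(8)]
    L = aln.length
    columns = [f"pos{p:03d}_{lab}" for p in range(L) for lab in labels]
    rows = []
    for rec in aln.records:
        if GAP in rec.sequence:
            raise EncodingError(
                f"{rec.id}: sequence still contains gaps; run extract_block first"
            )
        if scheme == "bpp":
            rows.append(encode_bpp(rec.sequence, table))
        else:
            rows.append(encode_binary8(rec.sequence))
    return EncodedMatrix(
        ids=aln.ids(),
        families=aln.families(),
        scheme=scheme,
        block_length=L,
        columns=columns,
        matrix=np.vstack(rows),
        table_properties=list(labels) if scheme == "bpp" else None,
    )


def fragment_alignment(aln: Alignment, window: int, step: int = 1) -> Alignment:
    """Sliding-window fragmentation of a gap-free block.

    Each sequence yields fragments ``id:start-end`` (0-based, end exclusive)
    of length ``window`` every ``step`` columns; family tags are inherited.
    Off by default in the CLI — whole blocks are the primary unit of analysis.
    """
    if window < 1 or window > aln.length:
        raise ValueError(f"window must lie in [1, {aln.length}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    records = []
    for rec in aln.records:
        for start in range(0, aln.length - window + 1, step):
            records.append(
                AlignedRecord(
                    id=f"{rec.id}:{start}-{start + window}",
                    sequence=rec.sequence[start : start + window],
                    family=rec.family,
                )
            )
    return Alignment(records)


def write_matrix(enc: EncodedMatrix, stream: IO[str]) -> None:
    """TSV with id and family columns followed by the feature lattice."""
    df = enc.to_frame()
    df.insert(0, "family", [f if f is not None else "" for f in enc.families])
    df.to_csv(stream, sep="\t", lineterminator="\n")


def read_matrix(source: str | Path | IO[str]) -> EncodedMatrix:
    """Read a TSV written by :func:`write_matrix` (scheme metadata not recoverable)."""
    df = pd.read_csv(source, sep="\t", index_col="id")
    families = [f if isinstance(f, str) and f else None for f in df["family"]]
    feat = df.drop(columns=["family"])
    first_pos = feat.columns[0].split("_")[0]
    d = sum(1 for c in feat.columns if c.startswith(first_pos + "_"))
    return EncodedMatrix(
        ids=[str(i) for i in df.index],
        families=families,
        scheme="unknown",
        block_length=len(feat.columns) // d,
        columns=list(feat.columns),
        matrix=feat.to_numpy(dtype=float),
    )
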