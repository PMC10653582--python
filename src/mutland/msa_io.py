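"""Alignment input/output and preprocessing.

Reads FASTA / A3M / Stockholm multiple sequence alignments into a
query-anchored matrix and applies the preprocessing rules used upstream of
depth, conservation and landscape computation: removal of insertion states,
replacement of undefined residues (X/U and the ambiguity codes B/Z) by the
column-most-frequent amino acid, removal of all-gap columns under undefined
query residues, and the minimum-query-length gate.

Conventions
-----------
* Row 0 of every alignment is the query.  Columns where the query carries a
  gap are removed at read time, so ``L`` always equals the query length
  (the A3M convention, applied to every format).
* Positions are 0-based internally; user-facing mutation notation is 1-based.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNDEFINED = set("XUBZ")
_VALID = set(AMINO_ACIDS) | UNDEFINED | {GAP}

TAXA = ("human", "eukaryote", "prokaryote", "virus", "unknown")


class MsaError(ValueError):
    """Base class for alignment reading/preprocessing failures."""


class MsaParseError(MsaError):
    pass


class MsaFormatError(MsaError):
    pass


class MsaSymbolError(MsaError):
    pass


class UnresolvableColumnError(MsaError):
    """A column needs an undefined-residue replacement but holds no canonical
    amino acid in any row."""


@dataclass
class Alignment:
    """Query-anchored multiple sequence alignment.

    ``matrix`` is an ``N x L`` array of single-character symbols over the 20
    canonical amino acids, the undefined codes (before preprocessing) and the
    gap ``'-'``.  Row 0 is the query.
    """

    query_id: str
    sequence_ids: list[str]
    matrix: np.ndarray
    taxon: str = "unknown"
    source_protocol: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise MsaFormatError("alignment matrix must be 2-D")
        if self.n == 0 or self.L == 0:
            raise MsaFormatError("alignment must have N >= 1 and L >= 1")
        if len(self.sequence_ids) != self.n:
            raise MsaFormatError("sequence_ids length does not match matrix")
        if self.taxon not in TAXA:
            raise MsaError(f"unknown taxon label {self.taxon!r}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def query(self) -> str:
        return "".join(self.matrix[0])

    def row(self, s: int) -> str:
        return "".join(self.matrix[s])


@dataclass
class ChangeLogEntry:
    """One preprocessing edit: replacement or column removal."""

    row: int               # -1 for a column removal
    position: int          # 0-based position in the ORIGINAL alignment
    old: str
    new: str               # "" for a removed column

    def is_column_removal(self) -> bool:
        return self.new == ""


def _check_symbols(rows: list[str], ids: list[str]) -> None:
    for seq, sid in zip(rows, ids):
        bad = set(seq) - _VALID
        if bad:
            raise MsaSymbolError(
                f"sequence {sid!r} contains non-IUPAC symbol(s): "
                + ", ".join(sorted(bad))
            )


def _anchor_to_query(rows: list[str], ids: list[str]) -> np.ndarray:
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MsaFormatError(f"ragged alignment rows (lengths {sorted(lengths)})")
    mat = np.array([list(r) for r in rows], dtype="<U1")
    keep = mat[0] != GAP
    mat = mat[:, keep]
    if mat.shape[1] == 0:
        raise MsaFormatError("query row is entirely gaps")
    return mat


def _read_a3m_rows(path: Path) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    rows: list[str] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") and header is None:
                continue  # A3M/HHsuite preamble
            if line.startswith(">"):
                if header is not None:
                    ids.append(header)
                    rows.append("".join(chunks))
                header = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif header is not None:
                chunks.append(line.strip())
    if header is not None:
        ids.append(header)
        rows.append("".join(chunks))
    # lowercase letters are insertion states relative to the query: drop them
    rows = ["".join(c for c in r if not c.islower()).replace(".", GAP) for r in rows]
    return rows, ids


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    taxon: str = "unknown",
    source_protocol: str = "",
) -> Alignment:
    """Read an MSA from ``path`` in ``format`` (fasta, a3m or stockholm).

    The first record is taken as the query.  A3M lowercase insertion states
    are removed; Stockholm ``'.'`` is treated as a gap; columns where the
    query has a gap are removed, so ``L`` equals the query length.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "a3m":
        rows, ids = _read_a3m_rows(path)
    elif fmt in ("fasta", "stockholm"):
        try:
            if fmt == "fasta":
                records = list(SeqIO.parse(path, "fasta"))
            else:
                records = list(AlignIO.read(path, "stockholm"))
        except Exception as exc:  # Biopython raises assorted ValueError types
            raise MsaParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
        ids = [r.id for r in records]
        rows = [str(r.seq).replace(".", GAP) for r in records]
    else:
        raise MsaError(f"unsupported alignment format {format!r}")
    if not rows:
        raise MsaParseError(f"no records found in {path}")
    rows = [r.upper() if fmt != "a3m" else r for r in rows]
    _check_symbols(rows, ids)
    matrix = _anchor_to_query(rows, ids)
    return Alignment(
        query_id=ids[0],
        sequence_ids=ids,
        matrix=matrix,
        taxon=taxon,
        source_protocol=source_protocol,
    )


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write the alignment back out (fasta or stockholm)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "fasta":
        with open(path, "w") as fh:
            for sid, row in zip(aln.sequence_ids, aln.matrix):
                fh.write(f">{sid}\n{''.join(row)}\n")
    elif fmt == "stockholm":
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            width = max(len(s) for s in aln.sequence_ids) + 2
            for sid, row in zip(aln.sequence_ids, aln.matrix):
                fh.write(f"{sid:<{width}}{''.join(row)}\n")
            fh.write("//\n")
    else:
        raise MsaError(f"unsupported output format {format!r}")


def _most_frequent_canonical(column: np.ndarray) -> str | None:
    """Most frequent canonical amino acid in a column, alphabetical tie-break.

    Returns None when the column holds no canonical residue at all.
    """
    counts = collections.Counter(c for c in column if c in AMINO_ACIDS)
    if not counts:
        return None
    # max count first, then alphabetical one-letter code
    return min(counts, key=lambda aa: (-counts[aa], aa))


def preprocess_undefined(aln: Alignment) -> tuple[Alignment, list[ChangeLogEntry]]:
    """Resolve undefined residues (X/U/B/Z) in every row.

    A query position whose non-query column is entirely gaps is removed
    (these arise from undefined leading residues that nothing aligned to);
    every other undefined symbol is replaced by the most frequent canonical
    amino acid in its column, gaps excluded from the count, ties broken
    alphabetically.  Idempotent.  Returns the cleaned alignment and a change
    log with one entry per edit.
    """
    mat = aln.matrix.copy()
    n, L = mat.shape
    log: list[ChangeLogEntry] = []

    undefined_mask = np.isin(mat, list(UNDEFINED))
    drop: list[int] = []
    for j in range(L):
        if undefined_mask[0, j] and (n == 1 or np.all(mat[1:, j] == GAP)):
            drop.append(j)
            log.append(ChangeLogEntry(row=-1, position=j, old=mat[0, j], new=""))

    for j in range(L):
        if j in drop:
            continue
        col_undef = np.nonzero(undefined_mask[:, j])[0]
        if col_undef.size == 0:
            continue
        repl = _most_frequent_canonical(mat[:, j])
        if repl is None:
            raise UnresolvableColumnError(
                f"column {j + 1} holds only gaps and undefined symbols; "
                "no replacement residue available"
            )
        for s in col_undef:
            log.append(ChangeLogEntry(row=int(s), position=j, old=mat[s, j], new=repl))
            mat[s, j] = repl

    if drop:
        mat = np.delete(mat, drop, axis=1)
    cleaned = replace(aln, matrix=mat)
    return cleaned, log


def check_query_length(aln: Alignment, min_len: int = 20) -> str:
    """Return ``"skip"`` when the query is at most ``min_len`` residues long
    (too short to be treated as a protein), else ``"pass"``."""
    return "skip" if aln.L <= min_len else "pass"


def write_change_log(log: Iterable[ChangeLogEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("row\tposition\told\tnew\taction\n")
        for e in log:
            action = "remove_column" if e.is_column_removal() else "replace"
            fh.write(f"{e.row}\t{e.position + 1}\t{e.old}\t{e.new}\t{action}\n")
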