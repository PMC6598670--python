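"""Sequence and interval data model plus FASTA / expression-TSV / BED I/O.

Promoters are stored 5'->3' as given; offset 0 is the distal end of the
upstream region and the TSS sits immediately 3' of the last base, so the
distance of a position to the TSS is ``len(seq) - position``.  All
coordinates are 0-based half-open, matching BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide complement table (uppercase only; inputs are normalized).
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "X": "X",
}

#: IUPAC degenerate codes expanded to their base sets.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "X": "ACGT",
}


class FastaParseError(ValueError):
    """Structural problem in a FASTA file (reported with a line number)."""


class ExpressionTableError(ValueError):
    """Malformed or invalid expression TSV."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def gc_fraction(self) -> float:
        """GC fraction over non-N bases (nan if the sequence is all N)."""
        counted = [b for b in self.residues if b != "N"]
        if not counted:
            return float("nan")
        return sum(b in "GC" for b in counted) / len(counted)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionMatrix:
    """Transcript-by-tissue FPKM values with a transcript->gene map.

    ``values`` is a DataFrame indexed by transcript id with one column per
    tissue; ``gene_of`` maps every transcript id to exactly one gene id.
    """

    values: pd.DataFrame
    gene_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ExpressionTableError(f"duplicate transcript id {dup!r}")
        if self.values.columns.has_duplicates:
            raise ExpressionTableError("tissue ids are not unique")
        if self.values.isna().any().any():
            raise ExpressionTableError("missing expression values")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionTableError("negative FPKM values")
        missing = set(self.values.index) - set(self.gene_of)
        if missing:
            raise ExpressionTableError(
                f"transcripts without a gene mapping: {sorted(missing)[:3]}..."
                if len(missing) > 3 else
                f"transcripts without a gene mapping: {sorted(missing)}"
            )

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    def transcripts_of_gene(self) -> dict[str, list[str]]:
        by_gene: dict[str, list[str]] = {}
        for t in self.values.index:
            by_gene.setdefault(self.gene_of[t], []).append(t)
        return by_gene


def _normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase and map any symbol outside {A,C,G,T,N} to N.

    Returns the normalized string and the number of replaced symbols.
    Ensembl-style dumps contain soft-masked lowercase and IUPAC ambiguity
    codes; both are tolerated rather than rejected.
    """
    up = raw.upper()
    replaced = sum(1 for ch in up if ch not in DNA_ALPHABET)
    if replaced:
        up = "".join(ch if ch in DNA_ALPHABET else "N" for ch in up)
    return up, replaced


def _validate_fasta_structure(path: Path) -> None:
    """Cheap line scan so structural errors carry a line number."""
    seen_header = False
    have_residues = False
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if seen_header and not have_residues:
                    raise FastaParseError(
                        f"{path}: empty record at line {header_line}"
                    )
                if not stripped[1:].strip():
                    raise FastaParseError(
                        f"{path}: malformed header (no id) at line {lineno}"
                    )
                seen_header = True
                have_residues = False
                header_line = lineno
            else:
                if not seen_header:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                have_residues = True
    if seen_header and not have_residues:
        raise FastaParseError(f"{path}: empty record at line {header_line}")


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into normalized :class:`Sequence` records.

    Residues are uppercased and symbols outside {A,C,G,T,N} are replaced by
    N (a warning with the replacement count is logged).  Duplicate ids,
    empty records and malformed headers raise :class:`FastaParseError`.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records: list[Sequence] = []
    seen: set[str] = set()
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues, replaced = _normalize_residues(str(rec.seq))
        total_replaced += replaced
        records.append(Sequence(id=rec.id, residues=residues))
    if total_replaced:
        logger.warning(
            "%s: replaced %d non-ACGTN symbol(s) with N", path, total_replaced
        )
    return records


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV whose first two columns are transcript id and gene id.

    Remaining columns are tissues with nonnegative FPKM values.  Missing
    cells, ragged rows, negative values and duplicate transcript ids raise
    :class:`ExpressionTableError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str})
    except pd.errors.ParserError as exc:
        raise ExpressionTableError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.shape[1] < 3:
        raise ExpressionTableError(f"{path}: need transcript, gene and >=1 tissue column")
    transcript_col, gene_col = df.columns[:2]
    tissues = list(df.columns[2:])
    values = df[tissues].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ExpressionTableError(f"{path}: missing or non-numeric expression cells")
    values.index = pd.Index(df[transcript_col].astype(str), name="transcript_id")
    gene_of = dict(zip(df[transcript_col].astype(str), df[gene_col].astype(str)))
    return ExpressionMatrix(values=values, gene_of=gene_of)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.insert(0, "gene_id", [m.gene_of[t] for t in out.index])
    out.to_csv(path, sep="\t", index_label="transcript_id")


def write_bed(
    hits: Iterable[tuple[GenomicInterval, str, int]], path: str | Path
) -> None:
    """Write (interval, name, score) triples as sorted BED6.

    Sort order is (seq_id, start, end, name); deterministic for a given
    hit multiset.
    """
    rows = sorted(
        ((iv.seq_id, iv.start, iv.end, name, int(score), iv.strand)
         for iv, name, score in hits),
        key=lambda r: (r[0], r[1], r[2], r[3], r[5]),
    )
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA/IUPAC string (an involution)."""
    try:
        return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(s.upper()))
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide symbol {exc.args[0]!r}") from exc
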