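"""Sequence and table I/O with fixed coordinate conventions.

All external coordinates are 1-based and inclusive, matching GenBank-style
locus coordinates. Genomes are treated as linear; matches never span an
origin. Residues are uppercased on load, so soft-masked (lowercase) input is
not treated as masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GENE_TABLE_COLUMNS = ["locus", "start", "end", "strand", "product"]

#: 12-column tabular hit format (BLAST outfmt-6 dialect).
HIT_TABLE_COLUMNS = [
    "query", "subject", "pct_identity", "aln_len", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header or illegal residue)."""


class TableFormatError(ValueError):
    """Malformed tabular input (wrong column count, bad field)."""


class AlphabetError(ValueError):
    """Sequence contains a character outside the permitted alphabet."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}; always linear."""

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"genome {self.id!r}: illegal DNA residue(s) {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def length_bp(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence; function_known is explicit, never inferred."""

    id: str
    residues: str
    function_known: bool = False
    product: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with 1-based inclusive coordinates."""

    locus: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.locus!r}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus!r}: strand must be + or -")


@dataclass(frozen=True)
class HomologyHit:
    """One query->subject alignment record.

    ``aln_len`` counts alignment columns including gaps. ``pct_similarity``
    and ``evalue`` may be absent (NaN) when the producing tool did not report
    them.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    query_len: int = 0
    subject_len: int = 0
    pct_similarity: float = math.nan
    score: float = 0.0
    evalue: float = math.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if not math.isnan(self.pct_similarity):
            if not self.pct_identity <= self.pct_similarity <= 100.0:
                raise ValueError(
                    "require pct_identity <= pct_similarity <= 100"
                )
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


# ---------------------------------------------------------------------------
# FASTA

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal DNA residue(s) {sorted(bad)}")
    return dna.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, kind: str = "dna") -> list:
    """Read a multi-record FASTA file.

    Parameters
    ----------
    path
        FASTA file, wrapped or unwrapped.
    kind
        ``"dna"`` yields :class:`GenomeSequence`, ``"protein"`` yields
        :class:`ProteinRecord`. Residues are uppercased on load.

    Returns records in file order; an empty file yields an empty list.
    """
    if kind not in ("dna", "protein"):
        raise ValueError(f"kind must be 'dna' or 'protein', got {kind!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        residues = str(rec.seq).upper()
        try:
            if kind == "dna":
                records.append(GenomeSequence(id=rec.id, residues=residues))
            else:
                records.append(ProteinRecord(id=rec.id, residues=residues))
        except AlphabetError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write GenomeSequence/ProteinRecord objects as FASTA."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Tabular hit format (12-column outfmt-6 dialect)


def read_hit_table(
    path: str | Path,
    query_lens: dict[str, int] | None = None,
    subject_lens: dict[str, int] | None = None,
) -> list[HomologyHit]:
    """Read a 12-column tab-separated hit table.

    Column order follows the outfmt-6 dialect (see
    :data:`HIT_TABLE_COLUMNS`). Sequence lengths are not part of the format;
    supply them from the FASTA inputs via ``query_lens``/``subject_lens``.
    ``pct_similarity`` is absent (NaN) — the tabular dialect does not carry
    it.
    """
    query_lens = query_lens or {}
    subject_lens = subject_lens or {}
    hits: list[HomologyHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TableFormatError(
                    f"{path}: row {lineno}: expected 12 columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        query_len=query_lens.get(fields[0], 0),
                        subject_len=subject_lens.get(fields[1], 0),
                        score=float(fields[11]),
                        evalue=float(fields[10]),
                    )
                )
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: row {lineno}: {exc}"
                ) from exc
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect read by :func:`read_hit_table`.

    Fields the internal record does not track (mismatches, gap opens,
    coordinates) are written as 0 placeholders; identity, alignment length,
    e-value and score round-trip exactly.
    """
    with open(path, "w") as handle:
        for h in hits:
            evalue = "0.0" if math.isnan(h.evalue) else repr(h.evalue)
            handle.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, repr(h.pct_identity),
                        str(h.aln_len), "0", "0", "0", "0", "0", "0",
                        evalue, repr(h.score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene feature tables


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene feature TSV with header ``locus start end strand product``.

    An optional sixth column ``protein_id`` links each gene to a protein
    record; when absent the locus tag doubles as the protein id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "product": str})
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                locus=row.locus,
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                product="" if pd.isna(row.product) else str(row.product),
                protein_id=str(getattr(row, "protein_id", row.locus)),
            )
        )
    if len({g.locus for g in genes}) != len(genes):
        raise TableFormatError(f"{path}: duplicate locus tags")
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "locus": [g.locus for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "product": [g.product for g in genes],
            "protein_id": [g.protein_id or g.locus for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
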