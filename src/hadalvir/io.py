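"""Domain records and on-disk formats.

Sequences live in FASTA, tables in header-carrying TSV, and homology
evidence in the 12-column tabular alignment dialect (outfmt 6: tab-separated,
1-based inclusive coordinates, no header). Internally all coordinates are
0-based half-open; the outfmt-6 reader/writer converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("hadalvir")

VALID_BASES = frozenset("ACGTN")

SOURCE_SETS = ("assembly", "blank_control", "host_mag")


@dataclass(frozen=True)
class ContigRecord:
    """An assembled sequence; the substrate of every downstream stage."""

    contig_id: str
    sequence: str
    sample_site: str = ""
    source_set: str = "assembly"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"non-IUPAC character(s) {sorted(bad)} in contig "
                f"{self.contig_id!r} (allowed: A,C,G,T,N)"
            )
        if self.source_set not in SOURCE_SETS:
            raise ValueError(f"unknown source_set {self.source_set!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A predicted gene with its functional annotation.

    Coordinates are 0-based half-open on the contig; ``category`` may be
    absent and is then derived from ``product`` by the triage stage.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str
    category: Optional[str] = None
    bitscore: Optional[float] = None
    subject_family: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass(frozen=True)
class AlignmentRow:
    """One row of a 12-column tabular alignment (1-based inclusive ends)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gaps: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must be in [0, 100]")


# ---------------------------------------------------------------------------
# FASTA

def parse_fasta(
    path: str | Path,
    min_length: int = 0,
    sample_site: str = "",
    source_set: str = "assembly",
) -> list[ContigRecord]:
    """Read a FASTA file into contig records.

    Records with length <= ``min_length`` are dropped (strictly-greater
    admission: with the default virome cutoff of 10 kb a 10,000 nt contig is
    excluded and a 10,001 nt contig kept). Sequences are uppercased; file
    order is preserved. Duplicate ids, empty sequences and non-ACGTN
    characters are hard errors.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        contig = ContigRecord(rec.id, seq, sample_site=sample_site,
                              source_set=source_set)
        if contig.length > min_length:
            records.append(contig)
    log.debug("parsed %d contigs from %s (min_length=%d)",
              len(records), path, min_length)
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.contig_id, description="")
            for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Header-carrying TSV with a typed schema

@dataclass
class TableSchema:
    """Named, typed column specification for a TSV with a header row."""

    name: str
    columns: dict  # column name -> callable dtype (str, int, float, ...)

    def required(self) -> Sequence[str]:
        return list(self.columns)


GENE_SCHEMA = TableSchema("genes", {
    "gene_id": str, "contig_id": str, "start": int, "end": int,
    "strand": str, "product": str,
})

PREDICTOR_SCHEMA = TableSchema("predictor_calls", {"contig_id": str, "tool": str,
                                                   "call": int})
COMPLETENESS_SCHEMA = TableSchema("completeness", {"contig_id": str,
                                                   "completeness": float})
BLANK_SCHEMA = TableSchema("blank_hits", {"contig_id": str, "reads": int})
DEPTH_SCHEMA = TableSchema("depth", {
    "contig_id": str, "sample_id": str, "mean_depth": float,
    "covered_fraction": float,
})
READS_SCHEMA = TableSchema("read_summaries", {
    "contig_id": str, "sample_id": str, "identity": float,
    "aligned_length": int,
})
SAMPLE_SCHEMA = TableSchema("samples", {"sample_id": str, "gb": float,
                                        "group": str})
TRANSCRIPT_SCHEMA = TableSchema("transcript_counts", {
    "gene_id": str, "contig_id": str, "reads": int,
})
PROTEIN_HIT_SCHEMA = TableSchema("protein_hits", {
    "protein_id": str, "votu_id": str, "family": str, "score": float,
    "pass": str,
})
PC_SCHEMA = TableSchema("pc_membership", {"protein_id": str, "genome_id": str,
                                          "pc_id": str})
AMG_SCHEMA = TableSchema("amg_candidates", {
    "gene_id": str, "contig_id": str, "function_id": str, "description": str,
    "source": str, "auxiliary_score": str, "flags": str, "category": str,
})


def parse_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV with a header against a schema (order-insensitive).

    Missing required columns and unparseable cells are hard errors; extra
    columns are preserved as opaque strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema.required() if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing} for schema "
            f"{schema.name!r}"
        )
    for col, caster in schema.columns.items():
        if caster is str:
            continue
        converted = []
        for i, raw in enumerate(df[col]):
            try:
                converted.append(caster(raw))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: cannot parse cell {raw!r} in column {col!r} "
                    f"at data row {i + 1}"
                ) from exc
        df[col] = converted
    log.debug("parsed %d rows from %s (schema %s)", len(df), path, schema.name)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 12-column tabular alignment (outfmt-6 dialect; no header)

OUTFMT6_COLUMNS = (
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gaps", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
)


def parse_outfmt6(path: str | Path) -> list[AlignmentRow]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[AlignmentRow] = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 12:
            raise ValueError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
        try:
            rows.append(AlignmentRow(
                parts[0], parts[1], float(parts[2]), int(parts[3]),
                int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                int(parts[8]), int(parts[9]), float(parts[10]),
                float(parts[11]),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: unparseable alignment row") from exc
    return rows


def write_outfmt6(rows: Iterable[AlignmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(getattr(r, c)) for c in OUTFMT6_COLUMNS) + "\n")


def alignments_to_frame(rows: Iterable[AlignmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) | {} for r in rows], columns=OUTFMT6_COLUMNS)
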