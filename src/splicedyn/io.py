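"""Readers and writers for the formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals on the
forward genomic strand. Conversion to the 1-based inclusive convention of
GTF happens only at the read/write boundary; BED shares the internal
convention. Keeping a single internal convention confines off-by-one
arithmetic to this module.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "RepeatInterval",
    "ExpressionMatrix",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_bed_repeats",
    "write_bed_repeats",
    "read_tpm",
    "write_tpm",
    "transcript_sequence",
    "reverse_complement",
]

#: transcript × sample TPM table: rows indexed by transcript_id, columns are
#: sample identifiers, values are non-negative TPM.
ExpressionMatrix = pd.DataFrame

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """An exon-structured transcript on a scaffold.

    ``exons`` are (start, end) pairs, 0-based half-open, sorted by start and
    non-overlapping. Introns are the gaps between consecutive exons.
    ``smrt_supported`` marks structures corroborated by long-read data; it is
    an input property carried through, never recomputed.
    """

    transcript_id: str
    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    smrt_supported: bool = False
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: exon end {e} <= start {s}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def junctions(self) -> frozenset[tuple[int, int]]:
        """Intron coordinates as a set, for splicing-form compatibility tests."""
        return frozenset(self.introns)


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing scaffold and strand."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transcripts:
            sc = {t.scaffold for t in self.transcripts}
            st = {t.strand for t in self.transcripts}
            if len(sc) > 1 or len(st) > 1:
                raise ValueError(
                    f"{self.gene_id}: transcripts must share scaffold and strand"
                )

    @property
    def scaffold(self) -> str:
        return self.transcripts[0].scaffold

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> tuple[str, int, int]:
        return (
            self.scaffold,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat-element annotation interval (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    family: str
    repeat_class: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"repeat {self.family}: end {self.end} <= start {self.start}")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GTF file into gene models.

    Exon features are grouped by transcript_id, transcripts by gene_id; all
    other feature types are ignored. GTF's 1-based inclusive coordinates are
    converted to 0-based half-open. The optional ``smrt_supported`` attribute
    ("true"/"false") is read per transcript and defaults to False.
    """
    path = os.fspath(path)
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str, bool]] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype != "exon":
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        smrt = feat.attributes.get("smrt_supported", ["false"])[0].lower() == "true"
        if tid not in tx_meta:
            tx_meta[tid] = (gid, feat.seqid, feat.strand, smrt)
            order.append(tid)
        # GTF 1-based inclusive -> 0-based half-open
        tx_exons.setdefault(tid, []).append((feat.start - 1, feat.end))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in order:
        gid, scaffold, strand, smrt = tx_meta[tid]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            scaffold=scaffold,
            strand=strand,
            exons=tx_exons[tid],
            smrt_supported=smrt,
        )
        if gid not in genes:
            genes[gid] = GeneModel(gene_id=gid, transcripts=[])
            gene_order.append(gid)
        genes[gid].transcripts.append(model)
    out = [genes[g] for g in gene_order]
    for g in out:
        GeneModel(gene_id=g.gene_id, transcripts=g.transcripts)  # re-validate
    return out


def _prevalidate_gtf(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            start, end = int(fields[3]), int(fields[4])
            if end < start:
                raise GtfParseError(f"{path}:{lineno}: exon end {end} < start {start}")
            if "transcript_id" not in fields[8]:
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id attribute")


def write_gtf(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GTF (exon features only, 1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for s, e in tx.exons:
                    attrs = (
                        f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'smrt_supported "{"true" if tx.smrt_supported else "false"}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                tx.scaffold,
                                "splicedyn",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                tx.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a scaffold -> sequence map.

    Soft-masked (lowercase) bases are uppercased; N is preserved, as the
    N-flank transposon filter depends on it.
    """
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(str(seq)), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# BED repeats
# ---------------------------------------------------------------------------

def read_bed_repeats(path: str | os.PathLike) -> list[RepeatInterval]:
    """Read a BED6 repeat annotation; the name column carries the family."""
    out: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED start {start} >= end {end}")
            out.append(
                RepeatInterval(
                    scaffold=fields[0],
                    start=start,
                    end=end,
                    family=fields[3],
                    repeat_class=fields[6] if len(fields) > 6 else "",
                )
            )
    return out


def write_bed_repeats(repeats: Iterable[RepeatInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.family}\t0\t+\n")


# ---------------------------------------------------------------------------
# TPM matrix
# ---------------------------------------------------------------------------

def read_tpm(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a transcript × sample TPM table (TSV, first column transcript_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_tpm(df)


def validate_tpm(df: pd.DataFrame) -> ExpressionMatrix:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids in TPM table: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in TPM table")
    if (df.values < 0).any():
        raise ValueError("negative TPM values are not allowed")
    return df.astype(float)


def write_tpm(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    validate_tpm(matrix)
    matrix.to_csv(path, sep="\t", index_label="transcript_id")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def transcript_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in 5'→3' transcript orientation."""
    chrom = genome[tx.scaffold]
    parts = []
    for s, e in tx.exons:
        chunk = chrom[s:e]
        if isinstance(chunk, (bytes, bytearray)):
            chunk = chunk.decode()
        parts.append(chunk)
    seq = "".join(parts)
    return reverse_complement(seq) if tx.strand == "-" else seq
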