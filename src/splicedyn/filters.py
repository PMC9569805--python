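"""Transcript-curation rules and the coding-consensus classifier.

Curation mirrors the three-step cleanup applied to a merged short-read +
long-read transcriptome assembly:

1. drop transcripts below an expression floor (1 TPM by default);
2. drop probable fragments: transcripts closer to a scaffold edge than the
   pooled intron-length quantile threshold and lacking long-read support;
3. drop probable precursors: single-exon transcripts inside genes that also
   contain multi-exon transcripts.

Coding classification is a two-predictor consensus: both non-coding →
lncRNA, both coding → mRNA, discordant → TUCP (transcript of uncertain
coding potential). A gene takes its transcripts' class when uniform,
otherwise "misc".

All filters are idempotent and report per-rule attrition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io import ExpressionMatrix, GeneModel

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_low_expression",
    "intron_length_percentile",
    "filter_fragmented",
    "filter_precursor_singletons",
    "classify_coding_consensus",
    "assign_gene_class",
    "run_filters",
]


@dataclass
class FilterConfig:
    tpm_floor: float = 1.0
    intron_percentile_q: float = 0.95
    #: edge-distance threshold in bp; None = derive from the intron quantile
    edge_distance_threshold: int | None = None
    #: how the TPM floor aggregates across samples: "max" | "mean" | "all"
    tpm_rule: str = "max"

    def __post_init__(self) -> None:
        if not 0.0 < self.intron_percentile_q < 1.0:
            raise ValueError("intron_percentile_q must be in (0, 1)")
        if self.tpm_floor < 0:
            raise ValueError("tpm_floor must be >= 0")
        if self.tpm_rule not in {"max", "mean", "all"}:
            raise ValueError("tpm_rule must be max, mean or all")


@dataclass
class FilterReport:
    rule: str
    n_input: int
    removed: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed


def _count_tx(genes: list[GeneModel]) -> int:
    return sum(len(g.transcripts) for g in genes)


def _drop(genes: list[GeneModel], removed_ids: set[str]) -> list[GeneModel]:
    out = []
    for g in genes:
        kept = [t for t in g.transcripts if t.transcript_id not in removed_ids]
        if kept:
            out.append(GeneModel(g.gene_id, kept))
    return out


def filter_low_expression(
    genes: list[GeneModel],
    matrix: ExpressionMatrix,
    floor: float = 1.0,
    rule: str = "max",
) -> tuple[list[GeneModel], FilterReport]:
    """Remove transcripts whose expression never reaches ``floor`` TPM.

    ``rule`` chooses the across-sample aggregation: "max" keeps a transcript
    expressed at the floor in at least one sample (the default: per-sample
    filtering would delete stage-specific transcripts), "mean" uses the
    sample mean, "all" requires every sample at the floor. Transcripts
    absent from the matrix are treated as unexpressed.
    """
    agg = {"max": matrix.max(axis=1), "mean": matrix.mean(axis=1), "all": matrix.min(axis=1)}[rule]
    removed: list[str] = []
    for g in genes:
        for t in g.transcripts:
            value = float(agg.get(t.transcript_id, 0.0))
            if value < floor:
                removed.append(t.transcript_id)
    report = FilterReport("low_expression", _count_tx(genes), removed)
    return _drop(genes, set(removed)), report


def intron_length_percentile(genes: list[GeneModel], q: float = 0.95) -> int:
    """Nearest-rank (type-1) q-quantile of all intron lengths, pooled.

    The value is the smallest pooled intron length L such that at least a
    fraction q of introns have length <= L; a single reproducible integer,
    suitable as a fragment edge-distance threshold.
    """
    lengths = sorted(
        a - d for g in genes for t in g.transcripts for d, a in t.introns
    )
    if not lengths:
        raise ValueError("no introns in the input gene models")
    rank = max(1, math.ceil(q * len(lengths)))
    return int(lengths[rank - 1])


def filter_fragmented(
    genes: list[GeneModel],
    scaffold_lengths: dict[str, int],
    threshold: int,
) -> tuple[list[GeneModel], FilterReport]:
    """Remove probable fragments near scaffold edges.

    A transcript is removed iff its genomic span lies closer than
    ``threshold`` bp to either scaffold boundary AND it is not long-read
    supported. Edge distance uses the genomic span, strand-ignorant:
    fragmentation is a physical scaffold-boundary artifact.
    """
    removed: list[str] = []
    for g in genes:
        for t in g.transcripts:
            if t.scaffold not in scaffold_lengths:
                raise ValueError(f"no scaffold length for {t.scaffold}")
            L = scaffold_lengths[t.scaffold]
            if t.end > L or t.start < 0:
                raise ValueError(
                    f"{t.transcript_id} extends beyond scaffold {t.scaffold}"
                )
            edge_distance = min(t.start, L - t.end)
            if edge_distance < threshold and not t.smrt_supported:
                removed.append(t.transcript_id)
    report = FilterReport("fragmented", _count_tx(genes), removed)
    return _drop(genes, set(removed)), report


def filter_precursor_singletons(
    genes: list[GeneModel],
) -> tuple[list[GeneModel], FilterReport]:
    """Remove single-exon transcripts from genes that also have multi-exon ones.

    Such singletons exactly tile a continuous genomic region and are most
    plausibly unspliced precursors. Genes containing only single-exon
    transcripts are untouched.
    """
    removed: list[str] = []
    for g in genes:
        if any(len(t.exons) > 1 for t in g.transcripts):
            removed.extend(
                t.transcript_id for t in g.transcripts if len(t.exons) == 1
            )
    report = FilterReport("precursor", _count_tx(genes), removed)
    return _drop(genes, set(removed)), report


def run_filters(
    genes: list[GeneModel],
    matrix: ExpressionMatrix,
    scaffold_lengths: dict[str, int],
    config: FilterConfig | None = None,
) -> tuple[list[GeneModel], list[FilterReport], int]:
    """Apply the three curation rules in order: TPM → fragmented → precursor.

    Returns the curated models, one report per rule, and the edge-distance
    threshold actually used (derived from the pooled intron-length quantile
    when not overridden).
    """
    config = config or FilterConfig()
    genes, rep1 = filter_low_expression(
        genes, matrix, config.tpm_floor, config.tpm_rule
    )
    threshold = config.edge_distance_threshold
    if threshold is None:
        threshold = intron_length_percentile(genes, config.intron_percentile_q)
    genes, rep2 = filter_fragmented(genes, scaffold_lengths, threshold)
    genes, rep3 = filter_precursor_singletons(genes)
    return genes, [rep1, rep2, rep3], threshold


# ---------------------------------------------------------------------------
# Coding-potential consensus
# ---------------------------------------------------------------------------

_CODING_LABELS = {"coding", "noncoding"}


def classify_coding_consensus(label_a: str, label_b: str) -> str:
    """Consensus of two coding-potential predictors for one transcript."""
    if label_a not in _CODING_LABELS or label_b not in _CODING_LABELS:
        raise ValueError(f"labels must be in {_CODING_LABELS}: got {label_a!r}, {label_b!r}")
    if label_a == label_b:
        return "mRNA" if label_a == "coding" else "lncRNA"
    return "TUCP"


def assign_gene_class(transcript_classes: list[str]) -> str:
    """Gene class: the shared transcript class, or "misc" when mixed."""
    if not transcript_classes:
        raise ValueError("gene has no classified transcripts")
    unique = set(transcript_classes)
    return transcript_classes[0] if len(unique) == 1 else "misc"


def classify_table(labels: pd.DataFrame) -> pd.Series:
    """Vectorized consensus over a two-column (predictor A, B) label table."""
    return pd.Series(
        [classify_coding_consensus(a, b) for a, b in labels.itertuples(index=False)],
        index=labels.index,
        name="class",
    )
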