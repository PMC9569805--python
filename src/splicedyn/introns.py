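"""Intron extraction, sequence features, and category comparisons.

Alternative introns are the retained introns of RI events; constitutive
introns are present in every isoform of their gene and take part in no
splicing event. Both sets are crossed with the host gene's "over"/"normal"
retention-dynamics label, giving four categories: alt_over, alt_normal,
cons_over, cons_normal.

Per intron the module computes length, GC content, position relative to the
transcription start site, donor/acceptor splice-site strengths, and a
branch-point score:

* Splice-site strength is an independent-position log-odds score against a
  position frequency matrix trained on the input's own constitutive sites
  (donor window: 3 exonic + 6 intronic bases; acceptor window: 20 intronic
  + 3 exonic bases). Scores are comparative, not calibrated probabilities.
* The branch-point score slides a 7-mer NNNYNAN weight matrix (position 4
  pyrimidine-weighted, position 6 adenosine-dominant) over a window
  upstream of the 3' splice site (default 18–44 bp).

Category distributions are contrasted feature by feature with two-sided
Mann–Whitney U tests, with direction given by the median difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .events import SpliceEvent, form_junctions
from .io import GeneModel, reverse_complement

__all__ = [
    "IntronFeatureRecord",
    "SpliceSiteModel",
    "CATEGORIES",
    "extract_introns",
    "relative_position",
    "gc_content",
    "donor_window",
    "acceptor_window",
    "intron_sequence",
    "train_splice_model",
    "score_splice_site",
    "bps_matrix",
    "score_bps",
    "characterize_introns",
    "compare_feature_distributions",
]

CATEGORIES = ("alt_over", "alt_normal", "cons_over", "cons_normal")

DONOR_EXONIC, DONOR_INTRONIC = 3, 6        # 9-mer donor window
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3  # 23-mer acceptor window
BPS_WIDTH = 7
BPS_WINDOW = (18, 44)  # motif-start offsets upstream of the 3' splice site

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class IntronFeatureRecord:
    intron_id: str     # scaffold:start-end:strand
    gene_id: str
    category: str
    length: int
    gc: float
    relative_position: float
    ss5_score: float
    ss3_score: float
    bps_score: float
    bps_position: float  # motif start relative to the intron 3' end (negative)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Intron:
    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    category: str

    @property
    def intron_id(self) -> str:
        return f"{self.scaffold}:{self.start}-{self.end}:{self.strand}"


def extract_introns(
    genes: list[GeneModel],
    events: list[SpliceEvent],
    over_labels: dict[str, str],
) -> list[_Intron]:
    """Categorized alternative and constitutive introns.

    ``over_labels`` maps RI event ids to "over"/"normal". Alternative
    introns come from labelled RI events. Constitutive introns of a gene
    hosting labelled RI events are those spliced in every isoform and
    untouched by any enumerated event of that gene; they inherit "over"
    when the gene hosts at least one over event, else "normal".
    Genes without a labelled RI event contribute nothing.
    """
    gene_map = {g.gene_id: g for g in genes}
    events_by_gene: dict[str, list[SpliceEvent]] = {}
    for ev in events:
        events_by_gene.setdefault(ev.gene_id, []).append(ev)

    out: list[_Intron] = []
    gene_dyn: dict[str, str] = {}
    for ev in events:
        if ev.event_type != "RI" or ev.event_id not in over_labels:
            continue
        label = over_labels[ev.event_id]
        gene = gene_map[ev.gene_id]
        s, d, a, e = ev.form1_signature
        out.append(_Intron(ev.gene_id, gene.scaffold, gene.strand, d, a, f"alt_{label}"))
        if label == "over" or ev.gene_id not in gene_dyn:
            gene_dyn[ev.gene_id] = label

    for gid, label in gene_dyn.items():
        gene = gene_map[gid]
        shared = set(gene.transcripts[0].introns)
        for tx in gene.transcripts[1:]:
            shared &= tx.junctions
        event_junctions: set[tuple[int, int]] = set()
        for ev in events_by_gene.get(gid, []):
            event_junctions |= form_junctions(ev)
        for d, a in sorted(shared):
            if (d, a) in event_junctions:
                continue
            out.append(_Intron(gid, gene.scaffold, gene.strand, d, a, f"cons_{label}"))
    return out


def all_constitutive_introns(
    genes: list[GeneModel], events: list[SpliceEvent]
) -> list[_Intron]:
    """Constitutive introns of every gene, for splice-model training.

    An intron qualifies when present in all of its gene's isoforms and not
    a junction of any enumerated event; the retention-dynamics category is
    left blank.
    """
    events_by_gene: dict[str, set[tuple[int, int]]] = {}
    for ev in events:
        events_by_gene.setdefault(ev.gene_id, set()).update(form_junctions(ev))
    out = []
    for gene in genes:
        shared = set(gene.transcripts[0].introns)
        for tx in gene.transcripts[1:]:
            shared &= tx.junctions
        excluded = events_by_gene.get(gene.gene_id, set())
        for d, a in sorted(shared):
            if (d, a) not in excluded:
                out.append(_Intron(gene.gene_id, gene.scaffold, gene.strand, d, a, "cons_all"))
    return out


def train_site_models_from_genes(
    genes: list[GeneModel],
    events: list[SpliceEvent],
    genome,
    min_sites: int = 50,
) -> tuple["SpliceSiteModel", "SpliceSiteModel"]:
    """Donor and acceptor models trained on all constitutive introns."""
    cons = all_constitutive_introns(genes, events)
    donors = [donor_window(genome, iv.scaffold, iv.start, iv.end, iv.strand) for iv in cons]
    acceptors = [acceptor_window(genome, iv.scaffold, iv.start, iv.end, iv.strand) for iv in cons]
    return (
        train_splice_model(donors, "donor", min_sites),
        train_splice_model(acceptors, "acceptor", min_sites),
    )


def relative_position(
    intron_start: int, intron_end: int, gene: GeneModel
) -> float:
    """Strand-aware intron 5'-end position as a fraction of the gene span.

    The reference span is the gene's longest transcript; 0 = at the
    transcription start site, 1 = at the gene's far end.
    """
    ref = max(gene.transcripts, key=lambda t: t.end - t.start)
    span = ref.end - ref.start
    if intron_start < ref.start or intron_end > ref.end:
        raise ValueError("intron outside the reference transcript span")
    if gene.strand == "+":
        return (intron_start - ref.start) / span
    return (ref.end - intron_end) / span


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N and other ambiguity codes excluded."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


# ---------------------------------------------------------------------------
# Window extraction (transcript orientation)
# ---------------------------------------------------------------------------

def intron_sequence(genome, scaffold: str, start: int, end: int, strand: str) -> str:
    seq = genome[scaffold][start:end]
    if isinstance(seq, (bytes, bytearray)):
        seq = seq.decode()
    return reverse_complement(seq) if strand == "-" else seq


def donor_window(genome, scaffold: str, start: int, end: int, strand: str) -> str:
    """3 exonic + 6 intronic bases around the 5' splice site."""
    chrom = genome[scaffold]
    if strand == "+":
        seq = chrom[start - DONOR_EXONIC:start + DONOR_INTRONIC]
    else:
        seq = chrom[end - DONOR_INTRONIC:end + DONOR_EXONIC]
    if isinstance(seq, (bytes, bytearray)):
        seq = seq.decode()
    return reverse_complement(seq) if strand == "-" else seq


def acceptor_window(genome, scaffold: str, start: int, end: int, strand: str) -> str:
    """20 intronic + 3 exonic bases around the 3' splice site."""
    chrom = genome[scaffold]
    if strand == "+":
        seq = chrom[end - ACCEPTOR_INTRONIC:end + ACCEPTOR_EXONIC]
    else:
        seq = chrom[start - ACCEPTOR_EXONIC:start + ACCEPTOR_INTRONIC]
    if isinstance(seq, (bytes, bytearray)):
        seq = seq.decode()
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# Splice-site model
# ---------------------------------------------------------------------------

@dataclass
class SpliceSiteModel:
    """Independent-position log-odds model of donor or acceptor windows."""

    site_kind: str  # "donor" | "acceptor"
    freq: np.ndarray        # width x 4 position frequencies
    background: np.ndarray  # length-4 window-wide base composition

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("frequency rows must sum to 1")

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-scoring sequence: per-position argmax of freq/background."""
        ratio = self.freq / self.background[None, :]
        return "".join("ACGT"[i] for i in ratio.argmax(axis=1))


def train_splice_model(
    sites: list[str],
    site_kind: str,
    min_sites: int = 50,
    pseudocount: float = 0.5,
) -> SpliceSiteModel:
    """Position frequency model from training site windows.

    All windows must share the kind's width (9 for donors, 23 for
    acceptors). Counts get a pseudocount; the background is the base
    composition pooled over all window positions.
    """
    width = {"donor": DONOR_EXONIC + DONOR_INTRONIC,
             "acceptor": ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC}[site_kind]
    usable = [s.upper() for s in sites if len(s) == width and set(s.upper()) <= set("ACGT")]
    if len(usable) < min_sites:
        raise ValueError(
            f"need >= {min_sites} clean {site_kind} windows, got {len(usable)}"
        )
    counts = np.full((width, 4), pseudocount)
    for s in usable:
        for i, b in enumerate(s):
            counts[i, _BASE_INDEX[b]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    bg_counts = counts.sum(axis=0)
    background = bg_counts / bg_counts.sum()
    return SpliceSiteModel(site_kind, freq, background)


def score_splice_site(model: SpliceSiteModel, site: str) -> float:
    """Σ_i log2(freq[i, base_i] / background[base_i]); higher = stronger."""
    site = site.upper()
    if len(site) != model.width:
        raise ValueError(f"site length {len(site)} != model width {model.width}")
    score = 0.0
    for i, b in enumerate(site):
        if b not in _BASE_INDEX:
            return float("nan")
        j = _BASE_INDEX[b]
        score += np.log2(model.freq[i, j] / model.background[j])
    return float(score)


# ---------------------------------------------------------------------------
# Branch point
# ---------------------------------------------------------------------------

def bps_matrix() -> np.ndarray:
    """7-mer NNNYNAN weight matrix (rows A, C, G, T per position)."""
    m = np.full((BPS_WIDTH, 4), 0.25)
    m[3] = [0.05, 0.45, 0.05, 0.45]   # Y: pyrimidine-weighted
    m[5] = [0.85, 0.05, 0.05, 0.05]   # A-dominant branch adenosine
    return m


_BPS_LOG_ODDS = np.log2(bps_matrix() / 0.25)


def score_bps(
    intron_seq: str, window: tuple[int, int] = BPS_WINDOW
) -> tuple[float, float]:
    """Best branch-point score and its motif-start offset from the 3' end.

    Scans motif starts between ``window`` bp (inclusive) upstream of the
    intron 3' end; offsets are reported negative (e.g. −25). Introns too
    short for the window return (nan, nan).
    """
    seq = intron_seq.upper()
    L = len(seq)
    near, far = window
    starts = [L - off for off in range(near, far + 1) if 0 <= L - off <= L - BPS_WIDTH]
    best: tuple[float, int] | None = None
    for p in starts:
        sub = seq[p:p + BPS_WIDTH]
        if not set(sub) <= set("ACGT"):
            continue
        score = sum(_BPS_LOG_ODDS[i, _BASE_INDEX[b]] for i, b in enumerate(sub))
        if best is None or score > best[0]:
            best = (score, p)
    if best is None:
        return float("nan"), float("nan")
    return float(best[0]), float(best[1] - L)


# ---------------------------------------------------------------------------
# End-to-end characterization and comparisons
# ---------------------------------------------------------------------------

def characterize_introns(
    introns: list[_Intron],
    genes: list[GeneModel],
    genome,
    donor_model: SpliceSiteModel | None = None,
    acceptor_model: SpliceSiteModel | None = None,
    min_training_sites: int = 50,
) -> list[IntronFeatureRecord]:
    """Full feature records for categorized introns.

    When no site models are passed they are trained on the constitutive
    introns in the input — strengths are then relative to the dataset's own
    typical sites, which is all the downstream contrasts require.
    """
    gene_map = {g.gene_id: g for g in genes}
    if donor_model is None or acceptor_model is None:
        cons = [iv for iv in introns if iv.category.startswith("cons_")]
        donors = [donor_window(genome, iv.scaffold, iv.start, iv.end, iv.strand) for iv in cons]
        acceptors = [acceptor_window(genome, iv.scaffold, iv.start, iv.end, iv.strand) for iv in cons]
        donor_model = donor_model or train_splice_model(donors, "donor", min_training_sites)
        acceptor_model = acceptor_model or train_splice_model(acceptors, "acceptor", min_training_sites)
    records = []
    for iv in introns:
        seq = intron_sequence(genome, iv.scaffold, iv.start, iv.end, iv.strand)
        bscore, bpos = score_bps(seq)
        records.append(
            IntronFeatureRecord(
                intron_id=iv.intron_id,
                gene_id=iv.gene_id,
                category=iv.category,
                length=iv.end - iv.start,
                gc=gc_content(seq),
                relative_position=relative_position(iv.start, iv.end, gene_map[iv.gene_id]),
                ss5_score=score_splice_site(
                    donor_model,
                    donor_window(genome, iv.scaffold, iv.start, iv.end, iv.strand),
                ),
                ss3_score=score_splice_site(
                    acceptor_model,
                    acceptor_window(genome, iv.scaffold, iv.start, iv.end, iv.strand),
                ),
                bps_score=bscore,
                bps_position=bpos,
            )
        )
    return records


FEATURES = ("relative_position", "length", "gc", "ss5_score", "ss3_score", "bps_score")


def compare_feature_distributions(
    records: list[IntronFeatureRecord],
    features: tuple[str, ...] = FEATURES,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per feature per category pair.

    ``direction`` is the sign of median(category a) − median(category b):
    "greater", "less" or "similar". Pairs with an empty or too-small
    category are skipped with a reason.
    """
    df = pd.DataFrame([vars(r) for r in records])
    rows = []
    present = [c for c in CATEGORIES if (df["category"] == c).any()]
    for feat in features:
        for ca, cb in combinations(present, 2):
            a = df.loc[df["category"] == ca, feat].dropna().to_numpy()
            b = df.loc[df["category"] == cb, feat].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                rows.append(
                    dict(feature=feat, category_a=ca, category_b=cb,
                         n_a=len(a), n_b=len(b), statistic=np.nan,
                         p_value=np.nan, direction="skipped: too few records")
                )
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            diff = float(np.median(a) - np.median(b))
            direction = "greater" if diff > 0 else "less" if diff < 0 else "similar"
            rows.append(
                dict(feature=feat, category_a=ca, category_b=cb,
                     n_a=len(a), n_b=len(b), statistic=float(res.statistic),
                     p_value=float(res.pvalue), direction=direction)
            )
    return pd.DataFrame(rows)
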