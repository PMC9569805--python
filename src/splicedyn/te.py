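"""Transposon-transcript classification and positional motif scanning.

A transcript is called an *expressed transposon* when the reciprocal overlap
with repeat-element annotation exceeds 90% on both sides: more than 90% of
the intersecting repeat bases are covered by the transcript AND more than
90% of the transcript's own exonic bases are covered by repeats. When only
the repeat side exceeds 90% the transcript is *TE-associated*; otherwise it
is unlabelled. Expressed transposons flanked by assembly-gap N bases within
20 bp of either end of their genomic span are discarded as unreliable.

Motif scanning is FIMO-like log-odds scoring of a position weight matrix
along the transcript's sense sequence, with a positional constraint: a hit
counts only when the best-scoring start lies before the motif's
``max_start`` (the motifs model tRNA-derived SINE head sequences, which are
anchored near the transcript 5' end).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RepeatInterval, TranscriptModel

__all__ = [
    "TEClassification",
    "MotifModel",
    "MotifHit",
    "overlap_fractions",
    "classify_te_transcript",
    "classify_transcripts",
    "filter_n_flanked",
    "family_composition",
    "scan_motif",
    "classify_motif_combination",
    "motifs_to_json",
    "motifs_from_json",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def percent(count: float, total: float, decimals: int = 2) -> float:
    """Percentage rendered with half-up rounding (2/64 -> 3.13, not 3.12)."""
    if total <= 0:
        raise ValueError("total must be positive")
    scale = 10 ** decimals
    return math.floor(100.0 * count / total * scale + 0.5) / scale


@dataclass
class TEClassification:
    transcript_id: str
    label: str  # expressed_transposon | te_associated | none
    repeat_overlap_fraction: float
    self_overlap_fraction: float
    family: str = ""


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersection_size(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def overlap_fractions(
    tx: TranscriptModel,
    repeats: list[RepeatInterval],
    on: str = "exonic",
) -> tuple[float, float]:
    """(repeat-side, transcript-side) overlap fractions for one transcript.

    Repeats on the transcript's scaffold that intersect its exonic bases
    (or genomic span, with ``on="span"``) are merged; the repeat fraction is
    covered repeat bases over total bases of those intersecting repeats, the
    self fraction is covered transcript bases over transcript length. Both
    are 0 when no repeat intersects.
    """
    if on not in {"exonic", "span"}:
        raise ValueError("on must be 'exonic' or 'span'")
    tx_iv = _merge(list(tx.exons)) if on == "exonic" else [(tx.start, tx.end)]
    tx_len = sum(e - s for s, e in tx_iv)
    if tx_len == 0:
        raise ValueError(f"{tx.transcript_id}: zero-length transcript")
    touching = [
        (r.start, r.end)
        for r in repeats
        if r.scaffold == tx.scaffold and _intersection_size(tx_iv, [(r.start, r.end)]) > 0
    ]
    rep_iv = _merge(touching)
    rep_len = sum(e - s for s, e in rep_iv)
    if rep_len == 0:
        return 0.0, 0.0
    covered = _intersection_size(tx_iv, rep_iv)
    return covered / rep_len, covered / tx_len


def _dominant_family(
    tx: TranscriptModel, repeats: list[RepeatInterval], on: str = "exonic"
) -> str:
    tx_iv = _merge(list(tx.exons)) if on == "exonic" else [(tx.start, tx.end)]
    by_family: dict[str, int] = {}
    for r in repeats:
        if r.scaffold != tx.scaffold:
            continue
        ov = _intersection_size(tx_iv, [(r.start, r.end)])
        if ov > 0:
            by_family[r.family] = by_family.get(r.family, 0) + ov
    if not by_family:
        return ""
    return max(sorted(by_family), key=by_family.get)


def classify_te_transcript(
    tx: TranscriptModel,
    repeats: list[RepeatInterval],
    threshold: float = 0.9,
    on: str = "exonic",
) -> TEClassification:
    """Apply the reciprocal >90% rule (strict inequalities) to one transcript."""
    rep_frac, self_frac = overlap_fractions(tx, repeats, on=on)
    if rep_frac > threshold and self_frac > threshold:
        label = "expressed_transposon"
    elif rep_frac > threshold:
        label = "te_associated"
    else:
        label = "none"
    return TEClassification(
        transcript_id=tx.transcript_id,
        label=label,
        repeat_overlap_fraction=rep_frac,
        self_overlap_fraction=self_frac,
        family=_dominant_family(tx, repeats, on=on) if label != "none" else "",
    )


def classify_transcripts(
    transcripts: list[TranscriptModel],
    repeats: list[RepeatInterval],
    threshold: float = 0.9,
    on: str = "exonic",
) -> list[TEClassification]:
    by_scaffold: dict[str, list[RepeatInterval]] = {}
    for r in repeats:
        by_scaffold.setdefault(r.scaffold, []).append(r)
    return [
        classify_te_transcript(tx, by_scaffold.get(tx.scaffold, []), threshold, on)
        for tx in transcripts
    ]


def filter_n_flanked(
    transposons: list[TranscriptModel],
    genome,
    window: int = 20,
) -> tuple[list[TranscriptModel], list[str]]:
    """Drop transposon transcripts with an N within ``window`` bp of either end.

    The windows flank the genomic span ([start − w, start) and
    [end, end + w)) and are clipped at scaffold boundaries. Returns
    (kept, removed ids).
    """
    kept, removed = [], []
    for tx in transposons:
        chrom = genome[tx.scaffold]
        up = chrom[max(0, tx.start - window):tx.start]
        down = chrom[tx.end:tx.end + window]
        if isinstance(up, (bytes, bytearray)):
            flank = (bytes(up) + bytes(down)).decode()
        else:
            flank = up + down
        if "N" in flank.upper():
            removed.append(tx.transcript_id)
        else:
            kept.append(tx)
    return kept, removed


def family_composition(
    classifications: list[TEClassification],
    genome_repeats: list[RepeatInterval] | None = None,
) -> pd.DataFrame:
    """Family composition of expressed transposons, with genome-side context.

    One row per repeat family: count among expressed transposons and its
    percentage of all expressed transposons (ratios sum to 100%), plus, when
    a genome-wide repeat annotation is given, the family's interval count
    and its percentage of total repeat bases. Percentages are rendered to
    two decimals.
    """
    expressed = [c for c in classifications if c.label == "expressed_transposon"]
    if not expressed:
        raise ValueError("no expressed transposons to summarize")
    counts = pd.Series([c.family for c in expressed]).value_counts()
    df = pd.DataFrame(
        {
            "family": counts.index,
            "count": counts.values,
            "ratio_in_expressed_te": [percent(c, counts.sum()) for c in counts.values],
        }
    )
    if genome_repeats:
        total_bases = sum(r.end - r.start for r in genome_repeats)
        g_counts, g_bases = {}, {}
        for r in genome_repeats:
            g_counts[r.family] = g_counts.get(r.family, 0) + 1
            g_bases[r.family] = g_bases.get(r.family, 0) + (r.end - r.start)
        df["count_in_genome"] = [g_counts.get(f, 0) for f in df["family"]]
        df["fraction_of_te_bases"] = [
            percent(g_bases.get(f, 0), total_bases) for f in df["family"]
        ]
    return df.sort_values("count", ascending=True).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A PWM with a positional constraint on the hit start.

    ``pwm`` is width × 4 (A, C, G, T) column-stochastic per position;
    ``score_threshold`` defaults to 60% of the consensus log-odds score.
    """

    motif_id: str
    pwm: np.ndarray
    max_start: int
    score_threshold: float | None = None
    background: np.ndarray | None = None
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be width x 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1")
        if self.max_start < 0:
            raise ValueError("max_start must be >= 0")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2((self.pwm + self.pseudocount) / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pwm.argmax(axis=1))

    @property
    def consensus_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def effective_threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return 0.6 * self.consensus_score


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int
    score: float
    strand: str = "+"


def scan_motif(model: MotifModel, sequence: str) -> MotifHit | None:
    """Best positional hit of ``model`` on a sense-strand sequence, or None.

    Every start position is scored as the summed log-odds of the PWM against
    a uniform background; positions whose window contains a base outside
    A/C/G/T (e.g. N) are skipped. A hit is reported only when the best score
    over the whole sequence reaches the model's threshold and its start lies
    below ``max_start``.
    """
    w = model.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than the PWM width")
    lo = model.log_odds
    seq = sequence.upper()
    best: tuple[float, int] | None = None
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        try:
            score = sum(lo[i, _BASE_INDEX[b]] for i, b in enumerate(window))
        except KeyError:
            continue  # ambiguous base in window
        if best is None or score > best[0]:
            best = (score, start)
    if best is None or best[0] < model.effective_threshold():
        return None
    if best[1] >= model.max_start:
        return None
    return MotifHit(model.motif_id, best[1], best[0])


def classify_motif_combination(
    hit1: MotifHit | None, hit5: MotifHit | None
) -> str:
    """Co-occurrence group for the motif-1/motif-5 pair on one transcript."""
    if hit1 and hit5:
        return "both"
    if hit1:
        return "only_motif1"
    if hit5:
        return "only_motif5"
    return "none"


def motifs_to_json(models: list[MotifModel], path) -> None:
    payload = [
        {
            "motif_id": m.motif_id,
            "pwm": m.pwm.tolist(),
            "max_start": m.max_start,
            "score_threshold": m.score_threshold,
        }
        for m in models
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def motifs_from_json(path) -> list[MotifModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        MotifModel(
            motif_id=m["motif_id"],
            pwm=np.asarray(m["pwm"]),
            max_start=int(m["max_start"]),
            score_threshold=m.get("score_threshold"),
        )
        for m in payload
    ]
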