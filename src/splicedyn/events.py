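"""Enumeration of local alternative-splicing events from gene models.

Seven binary event types are detected by exhaustive pairwise comparison of a
gene's transcript structures, in the style of transcript-model (ioe) event
catalogues:

* ``SE`` — skipping exon: an internal cassette exon present in one form,
  spliced over by a single junction in the other.
* ``RI`` — retained intron: a junction in one form lies fully inside a single
  exon of the other, whose boundaries match the flanking exons.
* ``A5`` / ``A3`` — alternative 5'/3' splice site: two junctions share one
  boundary and differ at the donor (A5) or acceptor (A3) end, with the
  alternative exon portions overlapping.
* ``MX`` — mutually exclusive exons: two non-overlapping internal exons,
  each flanked by junctions anchored at shared outer coordinates.
* ``AF`` / ``AL`` — alternative first/last exon: distinct, non-overlapping
  terminal exons splicing into a shared gene-body exon.

Only simple binary events are produced; combinations of events are never
merged into complex multi-way structures. Event identifiers are derived from
genomic coordinates, so the same local event discovered from several
transcript pairs is counted once.

Form-1 orientation per type (form 2 is the complementary form): RI = the
intron-retaining form; A5/A3 = the longer-exon (intron-proximal splice site)
form; SE = the inclusion form; MX = the transcriptionally 5'-most exon form;
AF/AL = the distal (outermost) terminal exon form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GeneModel, TranscriptModel

__all__ = ["SpliceEvent", "EVENT_TYPES", "enumerate_events", "assign_transcripts"]

EVENT_TYPES = ("A3", "A5", "AF", "AL", "MX", "RI", "SE")


@dataclass
class SpliceEvent:
    """One local alternative-splicing event with its two splicing forms.

    ``form1_signature`` / ``form2_signature`` are tuples of genomic
    coordinates anchoring each form (see the per-type builders below); ``F1``
    and ``F2`` are the disjoint sets of transcript ids compatible with each
    form.
    """

    event_id: str
    gene_id: str
    event_type: str
    scaffold: str
    strand: str
    form1_signature: tuple
    form2_signature: tuple
    F1: set[str] = field(default_factory=set)
    F2: set[str] = field(default_factory=set)

    @property
    def coordinates(self) -> tuple:
        return tuple(sorted({c for sig in (self.form1_signature, self.form2_signature) for c in sig}))


def _event_id(gene_id: str, etype: str, form1: tuple, form2: tuple) -> str:
    coords = ",".join(str(c) for c in form1) + "|" + ",".join(str(c) for c in form2)
    return f"{gene_id};{etype};{coords}"


def _make_event(gene: GeneModel, etype: str, form1: tuple, form2: tuple) -> SpliceEvent:
    return SpliceEvent(
        event_id=_event_id(gene.gene_id, etype, form1, form2),
        gene_id=gene.gene_id,
        event_type=etype,
        scaffold=gene.scaffold,
        strand=gene.strand,
        form1_signature=form1,
        form2_signature=form2,
    )


# ---------------------------------------------------------------------------
# Pairwise candidate generation
# ---------------------------------------------------------------------------

def _pair_candidates(t1: TranscriptModel, t2: TranscriptModel, strand: str):
    """Yield (type, form1_signature, form2_signature) for one ordered pair.

    Signatures are genomic; transcript-orientation semantics (5' vs 3',
    first vs last) are resolved through ``strand``.
    """
    yield from _ri_candidates(t1, t2)
    yield from _ri_candidates(t2, t1)
    yield from _se_candidates(t1, t2)
    yield from _se_candidates(t2, t1)
    yield from _ss_candidates(t1, t2, strand)
    yield from _mx_candidates(t1, t2, strand)
    yield from _terminal_candidates(t1, t2, strand)


def _ri_candidates(ta: TranscriptModel, tb: TranscriptModel):
    """RI: an exon of ``ta`` spans exactly two consecutive exons of ``tb``."""
    exons_b = tb.exons
    for i, (d, a) in enumerate(tb.introns):
        s = exons_b[i][0]
        e = exons_b[i + 1][1]
        for (xs, xe) in ta.exons:
            if xs == s and xe == e:
                # form 1 = retaining: the spanning exon; form 2 = the junction
                yield ("RI", (s, d, a, e), (s, d, a, e))


def _se_candidates(ta: TranscriptModel, tb: TranscriptModel):
    """SE: internal exon of ``ta`` skipped by a single junction of ``tb``."""
    exons_a = ta.exons
    junc_b = tb.junctions
    for i in range(1, len(exons_a) - 1):
        s, e = exons_a[i]
        c1 = exons_a[i - 1][1]
        c2 = exons_a[i + 1][0]
        if (c1, c2) in junc_b:
            yield ("SE", (c1, s, e, c2), (c1, c2))


def _ss_candidates(t1: TranscriptModel, t2: TranscriptModel, strand: str):
    """A5/A3: junction pairs sharing one boundary, alternative exons overlapping."""
    for (d1, a1) in t1.introns:
        for (d2, a2) in t2.introns:
            if a1 == a2 and d1 != d2:
                # shared genomic-right boundary, differing left (donor on +)
                lo, hi = min(d1, d2), max(d1, d2)
                # the long-form exon (ending at hi) must overlap the short one
                long_tx = t1 if d1 == hi else t2
                if any(xe == hi and xs < lo for xs, xe in long_tx.exons):
                    etype = "A5" if strand == "+" else "A3"
                    # form 1 = longer exon = boundary deeper into the intron
                    yield (etype, (hi, a1), (lo, a1))
            if d1 == d2 and a1 != a2:
                lo, hi = min(a1, a2), max(a1, a2)
                long_tx = t1 if a1 == lo else t2
                if any(xs == lo and xe > hi for xs, xe in long_tx.exons):
                    etype = "A3" if strand == "+" else "A5"
                    yield (etype, (d1, lo), (d1, hi))


def _mx_candidates(t1: TranscriptModel, t2: TranscriptModel, strand: str):
    """MX: non-overlapping internal exons with shared outer junction anchors."""
    def flanked_exons(t: TranscriptModel):
        # internal exon [a, f) together with its bounding junctions (d,a),(f,g)
        for i in range(1, len(t.exons) - 1):
            a, f = t.exons[i]
            d = t.exons[i - 1][1]
            g = t.exons[i + 1][0]
            yield d, a, f, g

    for d1, a1, f1, g1 in flanked_exons(t1):
        for d2, a2, f2, g2 in flanked_exons(t2):
            if d1 == d2 and g1 == g2 and (a1, f1) != (a2, f2):
                if f1 <= a2 or f2 <= a1:  # internal exons must not overlap
                    # form 1 = transcriptionally 5'-most internal exon
                    if (a1 < a2) == (strand == "+"):
                        yield ("MX", (d1, a1, f1, g1), (d1, a2, f2, g1))
                    else:
                        yield ("MX", (d1, a2, f2, g1), (d1, a1, f1, g1))


def _terminal_candidates(t1: TranscriptModel, t2: TranscriptModel, strand: str):
    """AF/AL: distinct non-overlapping terminal exons joining a shared exon."""
    if len(t1.exons) < 2 or len(t2.exons) < 2:
        return
    # genomic-left terminal exons sharing the downstream acceptor
    # Signatures: left-terminal (s, e, a) = exon [s, e) + intron (e, a);
    # right-terminal (d, s, e) = intron (d, s) + exon [s, e). Which side a
    # signature describes is recovered from (type, strand) when matching.
    fe1, fe2 = t1.exons[0], t2.exons[0]
    j1 = t1.introns[0]
    j2 = t2.introns[0]
    if j1[1] == j2[1] and fe1 != fe2 and (fe1[1] <= fe2[0] or fe2[1] <= fe1[0]):
        etype = "AF" if strand == "+" else "AL"
        # form 1 = distal terminal exon = genomically outermost (which is
        # also the transcriptionally outermost on either strand)
        distal_first = fe1[0] < fe2[0]
        sig1 = (fe1[0], fe1[1], j1[1])
        sig2 = (fe2[0], fe2[1], j2[1])
        yield (etype, sig1, sig2) if distal_first else (etype, sig2, sig1)
    # genomic-right terminal exons sharing the upstream donor
    le1, le2 = t1.exons[-1], t2.exons[-1]
    k1 = t1.introns[-1]
    k2 = t2.introns[-1]
    if k1[0] == k2[0] and le1 != le2 and (le1[1] <= le2[0] or le2[1] <= le1[0]):
        etype = "AL" if strand == "+" else "AF"
        distal_first = le1[1] > le2[1]
        sig1 = (k1[0], le1[0], le1[1])
        sig2 = (k2[0], le2[0], le2[1])
        yield (etype, sig1, sig2) if distal_first else (etype, sig2, sig1)


# ---------------------------------------------------------------------------
# Enumeration and assignment
# ---------------------------------------------------------------------------

def enumerate_events(gene: GeneModel, smrt_only: bool = False) -> list[SpliceEvent]:
    """Enumerate all simple binary splicing events of one gene.

    Candidates from all transcript pairs are deduplicated on
    (type, coordinate signature). With ``smrt_only`` only transcripts whose
    structure is long-read supported participate. Transcript sets F1/F2 are
    assigned before returning. Single-transcript genes yield an empty list.
    """
    txs = [t for t in gene.transcripts if t.smrt_supported or not smrt_only]
    if len(txs) < 2:
        return []
    seen: dict[tuple, SpliceEvent] = {}
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for etype, f1, f2 in _pair_candidates(txs[i], txs[j], gene.strand):
                key = (etype, f1, f2)
                if key not in seen:
                    seen[key] = _make_event(gene, etype, f1, f2)
    events = sorted(seen.values(), key=lambda e: (e.event_type, e.form1_signature))
    for ev in events:
        assign_transcripts(ev, gene, smrt_only=smrt_only)
    return [ev for ev in events if ev.F1 and ev.F2]


def _matches_form(ev: SpliceEvent, form: int, tx: TranscriptModel) -> bool:
    sig = ev.form1_signature if form == 1 else ev.form2_signature
    junc = tx.junctions
    t = ev.event_type
    if t == "RI":
        s, d, a, e = sig
        if form == 1:  # retaining: one exon covers the whole [d, a) intron
            return any(xs <= d and xe >= a for xs, xe in tx.exons)
        return (d, a) in junc
    if t == "SE":
        if form == 1:
            c1, s, e, c2 = sig
            return (c1, s) in junc and (e, c2) in junc
        return tuple(sig) in junc
    if t in ("A5", "A3"):
        return tuple(sig) in junc
    if t == "MX":
        d, a, f, g = sig
        return (d, a) in junc and (f, g) in junc
    if t in ("AF", "AL"):
        if len(tx.exons) < 2:
            return False
        left_terminal = (t == "AF") == (ev.strand == "+")
        if left_terminal:
            s, e, a = sig
            return tx.exons[0] == (s, e) and tx.introns[0] == (e, a)
        d, s, e = sig
        return tx.exons[-1] == (s, e) and tx.introns[-1] == (d, s)
    raise ValueError(f"unknown event type {t}")


def form_junctions(ev: SpliceEvent) -> set[tuple[int, int]]:
    """All intron (donor, acceptor) pairs appearing in either form signature."""
    t = ev.event_type
    s1, s2 = ev.form1_signature, ev.form2_signature
    if t == "RI":
        s, d, a, e = s1
        return {(d, a)}
    if t == "SE":
        c1, s, e, c2 = s1
        return {(c1, s), (e, c2), tuple(s2)}
    if t in ("A5", "A3"):
        return {tuple(s1), tuple(s2)}
    if t == "MX":
        d, a1, f1, g = s1
        _, a2, f2, _ = s2
        return {(d, a1), (f1, g), (d, a2), (f2, g)}
    if t in ("AF", "AL"):
        left_terminal = (t == "AF") == (ev.strand == "+")
        if left_terminal:
            return {(s1[1], s1[2]), (s2[1], s2[2])}
        return {(s1[0], s1[1]), (s2[0], s2[1])}
    raise ValueError(f"unknown event type {t}")


def assign_transcripts(
    ev: SpliceEvent, gene: GeneModel, smrt_only: bool = False
) -> SpliceEvent:
    """Populate F1/F2 with every gene transcript compatible with each form.

    A transcript joins a form when its junction chain (or exon cover, for the
    intron-retaining form) contains that form's full signature; transcripts
    matching neither are excluded. Matching both is impossible for these
    binary signatures and raises if ever observed.
    """
    txs = [t for t in gene.transcripts if t.smrt_supported or not smrt_only]
    ev.F1, ev.F2 = set(), set()
    for tx in txs:
        in1 = _matches_form(ev, 1, tx)
        in2 = _matches_form(ev, 2, tx)
        if in1 and in2:
            raise RuntimeError(
                f"{tx.transcript_id} matches both forms of {ev.event_id}"
            )
        if in1:
            ev.F1.add(tx.transcript_id)
        elif in2:
            ev.F2.add(tx.transcript_id)
    return ev
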