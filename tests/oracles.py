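"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal style possible
(per-base bitmaps, exhaustive enumeration, explicit condition checks) and
imports nothing from the package's computational paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# Interval overlap via per-base bitmaps
# ---------------------------------------------------------------------------

def bitmap_overlap_fractions(exons, repeat_intervals, span=100_000):
    """(repeat-side, transcript-side) fractions by marking individual bases."""
    tx = np.zeros(span, dtype=bool)
    for s, e in exons:
        tx[s:e] = True
    touching = []
    for s, e in repeat_intervals:
        if tx[s:e].any():
            touching.append((s, e))
    rep = np.zeros(span, dtype=bool)
    for s, e in touching:
        rep[s:e] = True
    if not rep.any():
        return 0.0, 0.0
    covered = int((tx & rep).sum())
    return covered / int(rep.sum()), covered / int(tx.sum())


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def brute_motif_scores(pwm, sequence, pseudocount=0.01, background=0.25):
    """Log-odds score at every start; None where the window has an N."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(pwm)
    scores = []
    for start in range(len(sequence) - w + 1):
        window = sequence[start:start + w]
        if any(b not in idx for b in window):
            scores.append(None)
            continue
        s = 0.0
        for i, b in enumerate(window):
            s += math.log2((pwm[i][idx[b]] + pseudocount) / background)
        scores.append(s)
    return scores


# ---------------------------------------------------------------------------
# Exact test distributions
# ---------------------------------------------------------------------------

def exact_wilcoxon_p(x, y):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Pratt handling of zero differences: zeros keep their ranks but are
    forced to contribute to neither sign sum. Requires untied non-zero
    |differences| for a well-defined exact distribution.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    nonzero = d != 0
    w_plus = float(ranks[(d > 0)].sum())
    w_minus = float(ranks[(d < 0)].sum())
    observed = min(w_plus, w_minus)
    count = 0
    total = 0
    free = np.flatnonzero(nonzero)
    for signs in itertools.product([1, -1], repeat=len(free)):
        wp = sum(ranks[i] for i, s in zip(free, signs) if s > 0)
        wm = sum(ranks[i] for i, s in zip(free, signs) if s < 0)
        total += 1
        if min(wp, wm) <= observed + 1e-12:
            count += 1
    return count / total


def exact_mannwhitney_p(a, b):
    """Two-sided Mann–Whitney p by enumerating all group-label assignments.

    Symmetric tail definition: the fraction of assignments whose
    min(U_a, U_b) is at most the observed minimum. Assumes no ties across
    the pooled sample.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)

    def u_min(group_a):
        r = sum(rank[v] for v in group_a)
        u_a = r - n_a * (n_a + 1) / 2
        return min(u_a, n_a * n_b - u_a)

    observed = u_min(a)
    count = total = 0
    for combo in itertools.combinations(pooled, n_a):
        total += 1
        if u_min(list(combo)) <= observed + 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Splicing-event comparator
# ---------------------------------------------------------------------------

def _introns_of(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def oracle_pair_events(ex1, ex2, strand):
    """All simple binary events between two exon structures.

    Returns a set of (type, frozenset-of-signature-tuples) in the package's
    documented signature shapes, derived here from first principles.
    """
    found = set()
    in1, in2 = _introns_of(ex1), _introns_of(ex2)

    # retained intron: one structure has an exon exactly equal to two
    # consecutive exons of the other, intron included
    for (ea, eb), introns in (((ex1, ex2), in2), ((ex2, ex1), in1)):
        for i, (d, a) in enumerate(introns):
            spanning = (eb[i][0], eb[i + 1][1])
            if spanning in ea:
                sig = (eb[i][0], d, a, eb[i + 1][1])
                found.add(("RI", frozenset({sig})))

    # skipping exon: a middle exon of one structure is bridged by a single
    # intron of the other
    for (ea, eb) in ((ex1, ex2), (ex2, ex1)):
        for i in range(1, len(ea) - 1):
            left_end = ea[i - 1][1]
            right_start = ea[i + 1][0]
            if (left_end, right_start) in _introns_of(eb):
                inc = (left_end, ea[i][0], ea[i][1], right_start)
                found.add(("SE", frozenset({inc, (left_end, right_start)})))

    # alternative donor/acceptor: introns sharing exactly one boundary, the
    # two versions of the flanking exon overlapping each other
    for (d1, a1) in in1:
        for (d2, a2) in in2:
            if a1 == a2 and d1 != d2:
                long_exons = ex1 if d1 > d2 else ex2
                hi, lo = max(d1, d2), min(d1, d2)
                if any(e == hi and s < lo for s, e in long_exons):
                    etype = "A5" if strand == "+" else "A3"
                    found.add((etype, frozenset({(hi, a1), (lo, a1)})))
            if d1 == d2 and a1 != a2:
                long_exons = ex1 if a1 < a2 else ex2
                lo, hi = min(a1, a2), max(a1, a2)
                if any(s == lo and e > hi for s, e in long_exons):
                    etype = "A3" if strand == "+" else "A5"
                    found.add((etype, frozenset({(d1, lo), (d1, hi)})))

    # mutually exclusive exons: internal exons of each structure that do not
    # overlap each other, with identical outer junction anchors
    for i in range(1, len(ex1) - 1):
        for j in range(1, len(ex2) - 1):
            a1, f1 = ex1[i]
            a2, f2 = ex2[j]
            d_1, g_1 = ex1[i - 1][1], ex1[i + 1][0]
            d_2, g_2 = ex2[j - 1][1], ex2[j + 1][0]
            if d_1 == d_2 and g_1 == g_2 and (a1, f1) != (a2, f2):
                if f1 <= a2 or f2 <= a1:
                    found.add(
                        ("MX", frozenset({(d_1, a1, f1, g_1), (d_1, a2, f2, g_1)}))
                    )

    # alternative first/last exons: distinct non-overlapping terminal exons
    # splicing into the same gene-body exon boundary
    if len(ex1) >= 2 and len(ex2) >= 2:
        f1, f2 = ex1[0], ex2[0]
        if in1[0][1] == in2[0][1] and f1 != f2 and (f1[1] <= f2[0] or f2[1] <= f1[0]):
            etype = "AF" if strand == "+" else "AL"
            found.add(
                (etype, frozenset({(f1[0], f1[1], in1[0][1]),
                                   (f2[0], f2[1], in2[0][1])}))
            )
        l1, l2 = ex1[-1], ex2[-1]
        if in1[-1][0] == in2[-1][0] and l1 != l2 and (l1[1] <= l2[0] or l2[1] <= l1[0]):
            etype = "AL" if strand == "+" else "AF"
            found.add(
                (etype, frozenset({(in1[-1][0], l1[0], l1[1]),
                                   (in2[-1][0], l2[0], l2[1])}))
            )
    return found


def oracle_gene_events(exon_structures, strand):
    """Deduplicated union of pairwise events over a gene's isoforms."""
    found = set()
    for ex1, ex2 in itertools.combinations(exon_structures, 2):
        found |= oracle_pair_events(ex1, ex2, strand)
    return found


# ---------------------------------------------------------------------------
# Random gene structures
# ---------------------------------------------------------------------------

def random_gene_structures(rng, max_isoforms=4):
    """Random isoform exon structures from a variant-rich gene skeleton.

    The skeleton has 4–6 exon slots; terminal slots may have two
    non-overlapping position variants, internal slots may be absent or
    boundary-shifted, and adjacent internal slots may be merged (intron
    retention). This produces all seven event classes across many draws.
    """
    n_slots = int(rng.integers(4, 7))
    # slot layout with generous introns so variants never collide
    slot_bounds = []
    pos = 1000
    for _ in range(n_slots):
        length = int(rng.integers(60, 140))
        slot_bounds.append((pos, pos + length))
        pos += length + int(rng.integers(150, 300))

    # optional alternative variants for terminal slots (shifted copies)
    first_variants = [slot_bounds[0]]
    if rng.random() < 0.5:
        s, e = slot_bounds[0]
        w = int(rng.integers(50, 90))
        first_variants.append((s - w - 60, s - 60))
    last_variants = [slot_bounds[-1]]
    if rng.random() < 0.5:
        s, e = slot_bounds[-1]
        w = int(rng.integers(50, 90))
        last_variants.append((e + 60, e + 60 + w))

    def draw_isoform():
        exons = []
        exons.append(first_variants[int(rng.integers(0, len(first_variants)))])
        for i in range(1, n_slots - 1):
            if rng.random() < 0.25:
                continue  # skipped slot
            s, e = slot_bounds[i]
            if rng.random() < 0.3:  # boundary variant
                if rng.random() < 0.5:
                    s -= int(rng.integers(10, 50))
                else:
                    e += int(rng.integers(10, 50))
            exons.append((s, e))
        exons.append(last_variants[int(rng.integers(0, len(last_variants)))])
        # occasional retention of one intron
        if len(exons) >= 2 and rng.random() < 0.3:
            i = int(rng.integers(0, len(exons) - 1))
            exons[i:i + 2] = [(exons[i][0], exons[i + 1][1])]
        return tuple(exons)

    n_iso = int(rng.integers(2, max_isoforms + 1))
    isoforms = {draw_isoform() for _ in range(n_iso)}
    return [list(iso) for iso in isoforms]
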