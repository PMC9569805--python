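# Methods

This note documents the models, conventions, parameters and design
choices behind each stage, and what the synthetic-data suite does and
does not demonstrate.

## Coordinates and formats

All interval arithmetic uses 0-based half-open coordinates on the forward
genomic strand. GTF's 1-based inclusive convention is converted only at
the read/write boundary; BED shares the internal convention. Soft-masked
FASTA bases are uppercased on read, but N is preserved because the
transposon N-flank filter depends on it. Long-read ("SMRT") support is an
input property carried as a per-transcript GTF attribute
(`smrt_supported`, default false), never recomputed.

## Transcript curation

Three rules run in a fixed order, each reporting its own attrition:

1. **Expression floor** (default 1 TPM). A transcript is kept when its
   maximum TPM across samples reaches the floor. The aggregation is
   configurable (`max`/`mean`/`all`); max is the default because
   per-sample filtering would delete stage-specific transcripts (e.g.
   transposons expressed only around genome activation) that the analysis
   is specifically interested in.
2. **Fragment removal.** Fragmented assemblies concentrate near scaffold
   edges. The edge-distance threshold defaults to the 0.95 nearest-rank
   quantile of all pooled intron lengths — a reproducible integer, since
   a transcript whose gene body could extend past the scaffold edge by
   less than a typical intron cannot be distinguished from a fragment.
   A transcript is removed when its genomic span (strand-ignorant —
   fragmentation is a physical artifact) lies closer than the threshold
   to either scaffold boundary *and* it lacks long-read support.
3. **Precursor removal.** Within genes that contain both multi- and
   single-exon transcripts, the single-exon ones exactly tile a
   continuous genomic region and are treated as unspliced precursors.
   Genes with only single-exon transcripts are untouched.

Coding classification is a consensus of two external predictors consumed
as labels: both non-coding → lncRNA, both coding → mRNA, discordant →
TUCP. A gene takes the uniform class of its transcripts, otherwise
"misc".

## Event enumeration

Seven binary local event types are derived from all transcript pairs of a
gene and deduplicated on genomic coordinate signatures, so an event
discovered from several pairs counts once. Only simple binary events are
produced; combinations are never merged into multi-way complexes.
Transcripts are assigned to a form when their junction chain (or exon
cover, for intron retention) contains the form's full signature; the two
signatures of a binary event are mutually exclusive within one junction
chain, which guarantees F₁ ∩ F₂ = ∅.

Form-1 orientation must be fixed for ΔΨ to be interpretable. Intron
retention defines it naturally (form 1 = retaining). For the other types
the package uses the common transcript-model-catalogue convention,
recorded in event metadata: A5/A3 = longer-exon (intron-proximal splice
site) form; SE = inclusion form; MX = transcriptionally 5′-most exon
form; AF/AL = distal (outermost) terminal-exon form. Signatures are
stored in genomic coordinates with strand recorded; 5′/3′ semantics are
resolved through the strand.

## Ψ and its statistics

Ψ = Σ_{F1} TPM / Σ_{F1∪F2} TPM, undefined (missing, never 0) when the
total is at or below the floor — 0 is a meaningful Ψ value and the floor
is strict ("more than 1 TPM"). Ψ is scale-invariant in TPM and
antisymmetric under form swap (Ψ → 1 − Ψ).

Adjacent time points are compared with the two-sided Wilcoxon signed-rank
test on events defined at both members of the pair. Zero differences are
handled by the Pratt policy (zeros ranked, then dropped from the sign
sums): many Ψ pairs tie exactly, and discarding them would silently
shrink n. Identical vectors return p = 1 directly. Exact null
distributions are used where scipy's policy permits (small n, no zeros);
the normal approximation otherwise. Tissue comparisons run the same
paired test over all unordered tissue pairs, with each tissue's Ψ taken
as the mean over its replicate sampling dates' defined cells. Raw
p-values are reported to mirror the upstream analysis style; a
Benjamini–Hochberg column is emitted alongside for users who want the
modern default. Comparisons with fewer than `min_pairs` (default 8)
paired events are flagged underpowered but not dropped.

"Over"/"normal" classification applies a strict ΔΨ > 0.07 rule across a
designated transition (default: the activation step). It is restricted to
RI events by default — the threshold comes from the shape of the RI ΔΨ
distribution — but can be widened to any type by argument.

## Intron features

Alternative introns are the retained introns of labelled RI events;
constitutive introns are present in every isoform of their gene and are
not a junction of any enumerated event. Constitutive introns inherit the
gene-level dynamics label ("over" when the gene hosts at least one over
event): the categories describe transcripts of over/normal genes rather
than specific isoforms, which is the coarser but unambiguous reading.

Splice-site strength is an independent-position log-odds score,
Σᵢ log₂(freqᵢ(base)/background(base)), against position-frequency models
trained on the input's own constitutive sites (pseudocount 0.5;
background = pooled window composition). Windows are donor = 3 exonic +
6 intronic bases (9-mer), acceptor = 20 intronic + 3 exonic bases
(23-mer). A first-order model rather than a higher-order maximum-entropy
model keeps the stage self-contained with no external score tables; all
downstream use is comparative (alternative vs constitutive on the same
model), where the ordering, not the absolute score, matters.

The branch-point score slides a 7-mer NNNYNAN weight matrix (position 4:
C/T at 0.45 each; position 6: A at 0.85; other positions uniform) over
motif starts 18–44 bp upstream of the 3′ splice site (a typical
branch-point search region; configurable). The best score and its offset
are reported; introns too short for the window yield a missing score.

Relative position is the strand-aware distance from the transcription
start site to the intron 5′ end, as a fraction of the gene's longest
transcript span. GC content is computed on the intron sequence including
the terminal dinucleotides, with N excluded from the denominator.

Category contrasts use two-sided Mann–Whitney U per feature per category
pair, with direction reported as the sign of the median difference.

## Transposons and motifs

A transcript is an expressed transposon when strictly more than 90% of
the intersecting repeat bases are covered by the transcript and strictly
more than 90% of the transcript's bases are covered by repeats;
repeat-side-only coverage >90% gives "TE-associated". Overlap is computed
on exonic (spliced) bases by default — the objects being classified are
transcripts — with a genomic-span mode behind a switch. Intersecting
repeats are merged before fractions are taken. Expressed transposons with
an N within 20 bp of either end of their genomic span (windows clipped at
scaffold edges) are discarded as adjacent-to-gap assemblies. Family
composition tables render percentages half-up to two decimals, so ratios
sum to 100% up to the last rendered digit.

Motif scanning scores a PWM (pseudocount 0.01, uniform background) at
every start of the transcript's sense sequence — the motifs model
tRNA-derived SINE head sequences, which are strand-defined — skipping
windows with ambiguous bases. A hit is reported only when the best score
reaches the threshold (default 60% of the consensus score; no published
match-significance cutoff exists for these motifs, so the threshold is
explicit and configurable) *and* the best start lies below the motif's
positional bound (motif1 < 50, motif5 < 40). Transcripts are then grouped
as both / only-motif1 / only-motif5 / none.

## PCA contributions

Expression is log2(TPM+1)-transformed and mean-centered (not unit-scaled,
matching the common unscaled-PCA default) with samples as observations.
Contribution(t, k) = 100·loading(t,k)²/Σₜloading(t,k)², summing to 100
per component. Each transcript is assigned to its argmax-contribution
component among those considered; ties break to the lowest component
index. Component signs are fixed so each component's largest-|loading|
transcript loads positively, making outputs backend-independent.

## The synthetic-data generator

The generator emulates the study design: an 18-point ordered embryo
series (T2, T4–T20; the sampling scheme has no T3) with the activation
transition between indices 3 and 4 (T6 → T7), plus nine juvenile tissues
at two sampling dates. Defaults: four genes per event type, planted ΔΨ
step 0.2 at the transition for designated "over" RI events (20% of RI
genes by default), gene totals around 20 TPM, multiplicative log-normal
expression noise (σ = 0.05 on the natural-log scale — positivity-
preserving and typical of abundance estimates), canonical GT..AG planted
at every intron boundary so splice-model training has signal, repeat
intervals at controlled overlap fractions (~100%/95%, 100%/50%, 51%/95%)
for the three transposon classes, and motif consensus sequences embedded
at controlled transcript offsets. Per-event TPM magnitudes are free
parameters of the generator (no published per-event values exist) and
are documented in `SimulationConfig`.

The intron-feature study generator plants the over/normal ×
alternative/constitutive contrasts directly: over-alternative introns
long (μ=700 vs 400 bp), normal-alternative short (μ=250), alternative
introns high-GC (0.50 vs 0.38), alternative splice sites sampled at lower
consensus fidelity (normal-alternative lowest), and constitutive introns
given a strong planted branch point while alternative introns carry an
adenosine-depleted branch-search region. The depletion is deliberate:
with only two informative positions in the NNNYNAN matrix, the maximum
over a 27-offset window saturates on random sequence, so a weak-branch
contrast must be planted at the sequence level to be recoverable.

What passing the synthetic suite shows: the detectors, classifiers and
statistics recover exactly what was planted under the stated noise model,
at the stated effect sizes, with correctly oriented forms and exact
noise-free Ψ. What it does not show: robustness to assembly artifacts
other than the two planted classes, to non-canonical splice sites, to
correlated (batch) expression noise, or to repeat annotations with
fragmented/nested intervals — real data have all of these.

## Problem sizes and numerical choices

The parameter-recovery suite uses 1000 RI genes (200 stepped + 800 null,
noise σ = 0.05) on four 1 Mb scaffolds — large enough for stable rank
statistics while keeping the whole test run in seconds. The
event-detection equivalence check runs 500 random variant-rich genes with
up to 4 isoforms against an independent brute-force comparator.
Tie-breaks and degenerate inputs are fixed throughout: strict
inequalities at the 0.9 overlap, 0.07 ΔΨ and 1 TPM thresholds; identical
paired vectors → p = 1; undefined Ψ propagates as missing; empty
categories are skipped with a recorded reason; PC ties go to the lowest
index.

## Known limitations

- Events are binary and local; nested or combined events are neither
  merged nor specially flagged.
- Ψ is transcript-TPM-based; junction-read-based Ψ and replicate variance
  modeling are out of scope.
- Splice-site scores are first-order log-odds; they order sites well but
  are not calibrated against published maximum-entropy scores.
- The branch-point model encodes only the NNNYNAN consensus; it cannot
  distinguish branch points beyond pyrimidine/adenosine content.
- Coding-potential labels are consumed, not computed.
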