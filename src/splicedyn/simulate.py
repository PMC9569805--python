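"""Synthetic genomes, gene models, repeats, motifs and expression tables.

Every downstream stage of the pipeline is testable against planted ground
truth produced here: multi-scaffold genomes, genes carrying the seven
alternative-splicing event types as isoform pairs, time-series TPM profiles
with a controlled Ψ step at a designated activation transition (emulating
the zygotic-genome-activation jump between the 256-cell and dome stages),
repeat intervals at controlled overlap fractions, and sequence motifs at
controlled transcript offsets.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .events import EVENT_TYPES
from .io import (
    GeneModel,
    RepeatInterval,
    TranscriptModel,
    reverse_complement,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedEvent",
    "SimulatedDataset",
    "PlacementError",
    "generate_genome",
    "generate_gene_models",
    "simulate_expression",
    "plant_repeats_and_motifs",
    "simulate_dataset",
    "write_dataset",
    "default_motif_models",
    "simulate_intron_features",
]

#: Embryo time-series sample labels (ovum through 20 days post fertilization;
#: the series has no T3 sample). The activation transition T6→T7 sits at
#: indices 3→4.
TIME_SAMPLES = ("T2", "T4") + tuple(f"T{i}" for i in range(5, 21))

#: Juvenile tissues sampled at the two latest dates.
TISSUES = ("B", "M", "L", "G", "Sk", "Sp", "K", "H", "I")
TISSUE_DATES = ("134dpf", "197dpf")

REPEAT_FAMILIES = ("unclassified SINE", "LINE/L2", "DNA/TcMar", "unclassified LTR")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(ValueError):
    """A gene or repeat does not fit on its scaffold."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_scaffolds: int = 2
    scaffold_length: int = 500_000
    event_mix: dict[str, int] = field(
        default_factory=lambda: {t: 4 for t in EVENT_TYPES}
    )
    n_background_genes: int = 10
    #: ordered time-point sample ids
    samples: tuple[str, ...] = TIME_SAMPLES
    #: index of the first sample AFTER the planted activation step (T7)
    activation_index: int = 4
    planted_delta_psi: float = 0.2
    #: number of RI events stepping by planted_delta_psi at activation;
    #: None = 20% of RI events
    n_over_ri: int | None = None
    noise_sd: float = 0.05
    base_total_tpm: float = 20.0
    include_tissues: bool = True
    #: optional (tissue, delta): over-RI events also shift Ψ in this tissue
    tissue_ri_shift: tuple[str, float] | None = None
    #: events whose total TPM is planted below the definedness floor
    n_low_expression: int = 0
    #: transcripts planted near a scaffold edge without long-read support
    n_fragmented: int = 2
    #: genes given an extra single-exon precursor-like isoform
    n_precursor: int = 2
    # --- repeats / transposons ---
    n_te_expressed: int = 4
    n_te_associated: int = 3
    n_te_none: int = 3
    #: expressed transposons additionally flanked by an N run within 20 bp
    n_te_n_flanked: int = 1
    n_genome_repeats: int = 20
    # --- motifs: list of (((motif_id, offset), ...), count) ---
    motif_plant: tuple = (
        ((("motif1", 10), ("motif5", 5)), 2),
        ((("motif1", 30),), 2),
        ((("motif5", 20),), 2),
        ((("motif1", 60),), 1),  # outside the positional window: no hit
    )

    def __post_init__(self) -> None:
        if self.scaffold_length < 10_000:
            raise ValueError("scaffold_length must be >= 10000")
        if self.n_scaffolds <= 0:
            raise ValueError("n_scaffolds must be positive")
        bad = set(self.event_mix) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types in event_mix: {sorted(bad)}")
        if any(v < 0 for v in self.event_mix.values()):
            raise ValueError("event_mix counts must be >= 0")
        if not 0.0 <= self.planted_delta_psi <= 1.0:
            raise ValueError("planted_delta_psi must be in [0, 1]")
        if not 0 <= self.activation_index < len(self.samples):
            raise ValueError("activation_index must index into samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def all_samples(self) -> list[str]:
        cols = list(self.samples)
        if self.include_tissues:
            cols += [f"{t}_{d}" for t in TISSUES for d in TISSUE_DATES]
        return cols


@dataclass(frozen=True)
class PlantedEvent:
    gene_id: str
    event_type: str
    form1_tx: str  # intron-retaining / inclusion / longer-exon / distal form
    form2_tx: str

    @property
    def key(self) -> str:
        return f"{self.gene_id}:{self.event_type}"


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream recovery."""

    events: list[PlantedEvent] = field(default_factory=list)
    #: true (pre-noise) Ψ per event key per sample
    psi_trajectory: pd.DataFrame | None = None
    over_events: set[str] = field(default_factory=set)
    low_expression_events: set[str] = field(default_factory=set)
    te_labels: dict[str, str] = field(default_factory=dict)
    te_n_flanked: set[str] = field(default_factory=set)
    #: transcript -> {motif_id: planted offset}
    motif_offsets: dict[str, dict[str, int]] = field(default_factory=dict)
    #: transcript -> expected combination group given positional windows
    motif_combination: dict[str, str] = field(default_factory=dict)
    fragmented_tx: set[str] = field(default_factory=set)
    precursor_tx: set[str] = field(default_factory=set)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatInterval]
    tpm: pd.DataFrame
    truth: GroundTruth
    motif_models: list


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> dict[str, bytearray]:
    """Random uppercase A/C/G/T scaffolds as mutable ASCII bytearrays.

    Mutability lets later stages plant splice sites, repeats, motifs and N
    runs in place; convert with ``bytes(seq).decode()`` when done.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, bytearray] = {}
    for i in range(config.n_scaffolds):
        arr = rng.choice(BASES, size=config.scaffold_length)
        genome[f"scaffold_{i + 1}"] = bytearray(arr.tobytes())
    return genome


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _chain(lengths: list[int]) -> list[tuple[int, int]]:
    """Alternate exon/intron lengths -> local exon intervals from 0."""
    pos = 0
    exons = []
    for i, ln in enumerate(lengths):
        if i % 2 == 0:
            exons.append((pos, pos + ln))
        pos += ln
    return exons


def _event_isoforms(etype: str, rng: np.random.Generator):
    """Two local-coordinate isoforms differing exactly in one event.

    Isoform 1 realizes splicing form 1 under the package's orientation
    convention (retained / inclusion / longer exon / 5'-most / distal).
    Local coordinates run 5'→3' along the transcript.
    """
    ex = lambda: int(rng.integers(90, 180))
    iv = lambda: int(rng.integers(200, 600))
    if etype == "SE":
        exons = _chain([ex(), iv(), ex(), iv(), ex(), iv(), ex()])
        return exons, [exons[0], exons[2], exons[3]]
    if etype == "RI":
        exons = _chain([ex(), iv(), ex(), iv(), ex(), iv(), ex()])
        retained = [exons[0], (exons[1][0], exons[2][1]), exons[3]]
        return retained, exons
    if etype in ("A5", "A3"):
        delta = int(rng.integers(20, 60))
        exons = _chain([ex(), iv() + delta, ex(), iv(), ex()])
        (s0, e0), (s1, e1), (s2, e2) = exons
        if etype == "A5":
            longer = [(s0, e0 + delta), (s1, e1), (s2, e2)]
        else:
            longer = [(s0, e0), (s1 - delta, e1), (s2, e2)]
        return longer, exons
    if etype == "MX":
        exons = _chain([ex(), iv(), ex(), iv(), ex(), iv(), ex()])
        iso1 = [exons[0], exons[1], exons[3]]
        iso2 = [exons[0], exons[2], exons[3]]
        return iso1, iso2
    if etype == "AF":
        la, lb, l1, l2 = ex(), ex(), ex(), ex()
        g1, g2, g3 = iv(), iv(), iv()
        fa = (0, la)
        fb = (la + g1, la + g1 + lb)
        e1 = (fb[1] + g2, fb[1] + g2 + l1)
        e2 = (e1[1] + g3, e1[1] + g3 + l2)
        return [fa, e1, e2], [fb, e1, e2]
    if etype == "AL":
        l0, l1, la, lb = ex(), ex(), ex(), ex()
        g1, g2, g3 = iv(), iv(), iv()
        e0 = (0, l0)
        e1 = (e0[1] + g1, e0[1] + g1 + l1)
        pa = (e1[1] + g2, e1[1] + g2 + la)   # proximal last exon
        pb = (pa[1] + g3, pa[1] + g3 + lb)   # distal last exon
        return [e0, e1, pb], [e0, e1, pa]
    raise ValueError(f"unknown event type {etype}")


def _to_genomic(local_exons, gene_start: int, gene_len: int, strand: str):
    if strand == "+":
        return [(gene_start + s, gene_start + e) for s, e in local_exons]
    return sorted(
        (gene_start + gene_len - e, gene_start + gene_len - s)
        for s, e in local_exons
    )


def _plant_splice_sites(genome: dict[str, bytearray], tx: TranscriptModel) -> None:
    chrom = genome[tx.scaffold]
    for d, a in tx.introns:
        if tx.strand == "+":
            chrom[d:d + 2] = b"GT"
            chrom[a - 2:a] = b"AG"
        else:
            chrom[d:d + 2] = b"CT"
            chrom[a - 2:a] = b"AC"


class _Placer:
    """Sequential gene placement, round-robin over scaffolds.

    A margin larger than the fragmented-transcript edge threshold keeps
    ordinary genes clear of scaffold boundaries.
    """

    def __init__(self, config: SimulationConfig, margin: int = 9000, gap: int = 400):
        self.length = config.scaffold_length
        self.margin = margin
        self.gap = gap
        self.names = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
        self.cursor = {n: margin for n in self.names}
        self._next = 0

    def place(self, span: int) -> tuple[str, int]:
        for _ in range(len(self.names)):
            name = self.names[self._next % len(self.names)]
            self._next += 1
            start = self.cursor[name]
            if start + span <= self.length - self.margin:
                self.cursor[name] = start + span + self.gap
                return name, start
        raise PlacementError(
            f"no scaffold can hold a {span} bp gene; increase scaffold_length"
        )


def generate_gene_models(
    config: SimulationConfig, genome: dict[str, bytearray]
) -> tuple[list[GeneModel], GroundTruth]:
    """Plant event genes, background genes, and filter-rule violators.

    Each planted event becomes one gene with exactly two isoforms differing
    only in that event; canonical GT..AG dinucleotides are written at every
    intron boundary (strand-aware). Fragmented-transcript and precursor
    violators are planted for the curation filters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    placer = _Placer(config)
    truth = GroundTruth()
    genes: list[GeneModel] = []

    for etype in EVENT_TYPES:  # fixed order for determinism
        for k in range(config.event_mix.get(etype, 0)):
            gid = f"gene_{etype}_{k + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            iso1, iso2 = _event_isoforms(etype, rng)
            gene_len = max(e for _, e in iso1 + iso2)
            scaffold, start = placer.place(gene_len)
            t1 = TranscriptModel(
                f"{gid}.t1", gid, scaffold, strand,
                _to_genomic(iso1, start, gene_len, strand), smrt_supported=True,
            )
            t2 = TranscriptModel(
                f"{gid}.t2", gid, scaffold, strand,
                _to_genomic(iso2, start, gene_len, strand), smrt_supported=True,
            )
            _plant_splice_sites(genome, t1)
            _plant_splice_sites(genome, t2)
            genes.append(GeneModel(gid, [t1, t2]))
            truth.events.append(PlantedEvent(gid, etype, t1.transcript_id, t2.transcript_id))

    for k in range(config.n_background_genes):
        gid = f"gene_bg_{k + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        # precursor hosts need >= 3 exons: a 2-exon gene plus its unspliced
        # span is indistinguishable from a planted intron-retention pair
        n_ex = int(rng.integers(3 if k < config.n_precursor else 2, 5))
        lengths = []
        for i in range(2 * n_ex - 1):
            lengths.append(int(rng.integers(90, 180)) if i % 2 == 0 else int(rng.integers(200, 600)))
        exons = _chain(lengths)
        gene_len = exons[-1][1]
        scaffold, start = placer.place(gene_len)
        tx = TranscriptModel(
            f"{gid}.t1", gid, scaffold, strand,
            _to_genomic(exons, start, gene_len, strand),
            smrt_supported=bool(rng.random() < 0.7),
        )
        _plant_splice_sites(genome, tx)
        gene = GeneModel(gid, [tx])
        # precursor-like extra isoform: unspliced single exon over the span
        if k < config.n_precursor and n_ex >= 2:
            pre = TranscriptModel(
                f"{gid}.pre", gid, scaffold, strand,
                [(tx.start, tx.end)], smrt_supported=False,
            )
            gene.transcripts.append(pre)
            truth.precursor_tx.add(pre.transcript_id)
        genes.append(gene)

    # fragmented transcripts: close to a scaffold edge, no long-read support
    for k in range(config.n_fragmented):
        gid = f"gene_frag_{k + 1}"
        scaffold = placer.names[k % len(placer.names)]
        exons = _chain([120, 250, 140])
        start = 50 + 500 * k  # well inside the edge threshold
        tx = TranscriptModel(
            f"{gid}.t1", gid, scaffold, "+",
            [(start + s, start + e) for s, e in exons],
            smrt_supported=False,
        )
        _plant_splice_sites(genome, tx)
        genes.append(GeneModel(gid, [tx]))
        truth.fragmented_tx.add(tx.transcript_id)

    # Ψ step designation for RI events
    ri_keys = [ev.key for ev in truth.events if ev.event_type == "RI"]
    n_over = config.n_over_ri
    if n_over is None:
        n_over = max(1, len(ri_keys) // 5) if ri_keys else 0
    truth.over_events = set(ri_keys[:n_over])
    low = [ev.key for ev in truth.events][: config.n_low_expression]
    truth.low_expression_events = set(low)
    return genes, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
) -> pd.DataFrame:
    """Per-sample transcript TPMs realizing the true Ψ trajectories.

    For each planted event, form-1 and form-2 isoform TPMs split a gene
    total so that TPM-implied Ψ equals the true trajectory before noise.
    Over-designated RI events step by ``planted_delta_psi`` from
    ``activation_index`` on. Noise is multiplicative log-normal
    (``noise_sd`` on the natural-log scale), preserving positivity.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = config.all_samples()
    n = len(samples)
    tissue_cols = [
        i for i, s in enumerate(samples)
        if config.tissue_ri_shift and s.startswith(config.tissue_ri_shift[0] + "_")
    ]

    event_by_gene = {ev.gene_id: ev for ev in truth.events}
    psi_rows = {}
    tpm: dict[str, np.ndarray] = {}
    for gene in genes:
        ev = event_by_gene.get(gene.gene_id)
        if ev is not None:
            base = float(rng.uniform(0.25, 0.60))
            traj = np.full(n, base)
            if ev.key in truth.over_events:
                step = min(config.planted_delta_psi, 0.95 - base)
                traj[config.activation_index:len(config.samples)] += step
                for i in tissue_cols:
                    traj[i] = min(0.95, base + config.tissue_ri_shift[1])
            psi_rows[ev.key] = traj
            if ev.key in truth.low_expression_events:
                total = np.full(n, 0.5)
            else:
                total = config.base_total_tpm * rng.lognormal(0.0, 0.25, size=n)
            tpm[ev.form1_tx] = traj * total
            tpm[ev.form2_tx] = (1.0 - traj) * total
        else:
            for tx in gene.transcripts:
                tpm[tx.transcript_id] = float(rng.uniform(2.0, 50.0)) * np.ones(n)

    df = pd.DataFrame(tpm, index=samples).T
    if config.noise_sd > 0:
        df = df * np.exp(rng.normal(0.0, config.noise_sd, size=df.shape))
    truth.psi_trajectory = pd.DataFrame(psi_rows, index=samples).T
    return df


# ---------------------------------------------------------------------------
# Repeats and motifs
# ---------------------------------------------------------------------------

def default_motif_models():
    """The two positional motif models used throughout the synthetic suite.

    Stand-ins for the two head-sequence motifs of the expressed-SINE
    analysis: motif1 must start before position 50 of the transcript,
    motif5 before position 40.
    """
    from .te import MotifModel  # deferred: te imports io only

    def pwm(consensus: str) -> np.ndarray:
        idx = {b: i for i, b in enumerate("ACGT")}
        m = np.full((len(consensus), 4), 0.05)
        for i, b in enumerate(consensus):
            m[i, idx[b]] = 0.85
        return m

    return [
        MotifModel("motif1", pwm("TGGCTCACAC"), max_start=50),
        MotifModel("motif5", pwm("GAGACAGG"), max_start=40),
    ]


def _write_seq(genome, tx: TranscriptModel, offset: int, seq: str) -> None:
    """Write ``seq`` so it appears at ``offset`` of the spliced transcript.

    Planted hosts are single-exon, so transcript offsets map directly onto
    the genome (reverse-complemented on the minus strand).
    """
    chrom = genome[tx.scaffold]
    s, e = tx.exons[0]
    if tx.strand == "+":
        chrom[s + offset:s + offset + len(seq)] = seq.encode()
    else:
        rc = reverse_complement(seq)
        chrom[e - offset - len(seq):e - offset] = rc.encode()


def plant_repeats_and_motifs(
    config: SimulationConfig,
    genome: dict[str, bytearray],
    genes: list[GeneModel],
    truth: GroundTruth,
) -> tuple[list[RepeatInterval], list]:
    """Plant repeat intervals, transposon transcripts, and motif hosts.

    Transposon-candidate transcripts are single-exon genes overlapped by
    repeats at controlled fractions: ~(100%, 95%) of (repeat, transcript)
    for expressed transposons, (100%, 50%) for TE-associated transcripts,
    and (~51%, 95%) for neither. Motif consensus sequences are embedded at
    controlled transcript offsets. Returns (repeats, motif models) and
    updates the ground truth in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    placer = _Placer(config, margin=12_000)
    # restart placement beyond everything placed so far
    for gene in genes:
        sc, s, e = gene.span
        placer.cursor[sc] = max(placer.cursor[sc], e + 400)
    repeats: list[RepeatInterval] = []
    motif_models = default_motif_models()
    consensus = {
        m.motif_id: "".join("ACGT"[i] for i in m.pwm.argmax(axis=1))
        for m in motif_models
    }

    def add_te_gene(label: str, idx: int, n_flank: bool = False):
        gid = f"gene_te_{label}_{idx + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        length = 200
        scaffold, start = placer.place(length + 400)
        start += 200  # leave room for an oversized repeat upstream
        tx = TranscriptModel(
            f"{gid}.t1", gid, scaffold, strand,
            [(start, start + length)], smrt_supported=True,
        )
        family = REPEAT_FAMILIES[idx % len(REPEAT_FAMILIES)]
        if label == "expressed_transposon":
            rep = (start + 5, start + 195)        # (1.00, 0.95)
        elif label == "te_associated":
            rep = (start + 5, start + 105)        # (1.00, 0.50)
        else:
            rep = (start - 180, start + 190)      # (0.51, 0.95)
        repeats.append(RepeatInterval(scaffold, rep[0], rep[1], family))
        if n_flank:
            genome[scaffold][start - 6:start - 3] = b"NNN"
            truth.te_n_flanked.add(tx.transcript_id)
        genes.append(GeneModel(gid, [tx]))
        truth.te_labels[tx.transcript_id] = label
        return tx

    for i in range(config.n_te_expressed):
        add_te_gene("expressed_transposon", i, n_flank=i < config.n_te_n_flanked)
    for i in range(config.n_te_associated):
        add_te_gene("te_associated", i)
    for i in range(config.n_te_none):
        add_te_gene("none", i)

    # motif hosts: single-exon genes carrying consensus plants
    host_idx = 0
    for plants, count in config.motif_plant:
        for _ in range(count):
            host_idx += 1
            gid = f"gene_motif_{host_idx}"
            strand = "+" if rng.random() < 0.5 else "-"
            length = 300
            scaffold, start = placer.place(length)
            tx = TranscriptModel(
                f"{gid}.t1", gid, scaffold, strand,
                [(start, start + length)], smrt_supported=True,
            )
            offsets = {}
            for motif_id, off in plants:
                _write_seq(genome, tx, off, consensus[motif_id])
                offsets[motif_id] = off
            genes.append(GeneModel(gid, [tx]))
            truth.motif_offsets[tx.transcript_id] = offsets
            windows = {m.motif_id: m.max_start for m in motif_models}
            hits = {m for m, off in offsets.items() if off < windows[m]}
            truth.motif_combination[tx.transcript_id] = (
                "both" if hits == {"motif1", "motif5"}
                else "only_motif1" if hits == {"motif1"}
                else "only_motif5" if hits == {"motif5"}
                else "none"
            )

    # genome-side repeats in gene-free territory (for composition tables)
    for i in range(config.n_genome_repeats):
        family = REPEAT_FAMILIES[int(rng.integers(0, len(REPEAT_FAMILIES)))]
        length = int(rng.integers(150, 600))
        scaffold, start = placer.place(length)
        repeats.append(RepeatInterval(scaffold, start, start + length, family))

    repeats.sort(key=lambda r: (r.scaffold, r.start, r.end))
    return repeats, motif_models


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome, genes, repeats, motifs, expression."""
    genome = generate_genome(config)
    genes, truth = generate_gene_models(config, genome)
    repeats, motif_models = plant_repeats_and_motifs(config, genome, genes, truth)
    tpm = simulate_expression(config, genes, truth)
    return SimulatedDataset(
        config=config,
        genome={k: bytes(v).decode() for k, v in genome.items()},
        genes=genes,
        repeats=repeats,
        tpm=tpm,
        truth=truth,
        motif_models=motif_models,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write FASTA/GTF/BED/TSV/JSON artifacts; returns the path map."""
    import json
    import os

    from . import io as sio
    from .te import motifs_to_json

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gtf"),
        "repeats": os.path.join(outdir, "repeats.bed"),
        "tpm": os.path.join(outdir, "tpm.tsv"),
        "motifs": os.path.join(outdir, "motifs.json"),
        "config": os.path.join(outdir, "config.json"),
        "truth_events": os.path.join(outdir, "truth_events.tsv"),
        "truth_psi": os.path.join(outdir, "truth_psi.tsv"),
    }
    sio.write_fasta(ds.genome, paths["genome"])
    sio.write_gtf(ds.genes, paths["annotation"])
    sio.write_bed_repeats(ds.repeats, paths["repeats"])
    sio.write_tpm(ds.tpm, paths["tpm"])
    motifs_to_json(ds.motif_models, paths["motifs"])
    cfg = asdict(ds.config)
    cfg["event_mix"] = dict(cfg["event_mix"])
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=1, default=list)
    rows = [
        {
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "form1_tx": ev.form1_tx,
            "form2_tx": ev.form2_tx,
            "over": ev.key in ds.truth.over_events,
        }
        for ev in ds.truth.events
    ]
    pd.DataFrame(rows).to_csv(paths["truth_events"], sep="\t", index=False)
    if ds.truth.psi_trajectory is not None:
        ds.truth.psi_trajectory.to_csv(paths["truth_psi"], sep="\t", index_label="event")
    return paths


# ---------------------------------------------------------------------------
# Intron-feature study generator
# ---------------------------------------------------------------------------

def _biased_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(rng.choice(BASES, size=length, p=p)).decode()


def _sample_site(rng, consensus: str, strength: float, fixed: set[int]) -> str:
    """Sample a site: consensus base with prob ``strength`` per position.

    Positions in ``fixed`` (the invariant GT/AG dinucleotides) always take
    the consensus base.
    """
    out = []
    for i, b in enumerate(consensus):
        if i in fixed or rng.random() < strength:
            out.append(b)
        else:
            out.append("ACGT"[int(rng.integers(0, 4))])
    return "".join(out)


DONOR_CONSENSUS = "CAGGTAAGT"          # 3 exonic | 6 intronic
ACCEPTOR_CONSENSUS = "TTTTTTTTTTTTTTTCTCAGGTG"  # 20 intronic | 3 exonic
_DONOR_FIXED = {3, 4}                  # the GT
_ACCEPTOR_FIXED = {18, 19}             # the AG
BPS_STRONG = "TACTAAC"                 # matches the NNNYNAN consensus


@dataclass(frozen=True)
class PlantedIntron:
    category: str           # alt_over / alt_normal / cons_over / cons_normal
    sequence: str           # intron sequence (terminal dinucleotides included)
    donor_window: str       # 3 exonic + 6 intronic bases
    acceptor_window: str    # 20 intronic + 3 exonic bases
    relative_position: float


def simulate_intron_features(
    seed: int, n_per_category: int = 120
) -> list[PlantedIntron]:
    """Intron sets with the planted over/normal × alt/cons feature pattern.

    Planted contrasts (alternative vs constitutive within each class):
    over-alternative introns LONG, both alternative sets HIGH-GC,
    alternative splice sites WEAK with normal-alternative the weakest, and
    alternative branch points weak. Over-alternative introns sit toward the
    5' end of the gene, normal-alternative toward the middle.
    """
    rng = np.random.default_rng(seed)
    spec = {
        #            len_mu len_sd   gc    ss_strength  bps_strong  pos_rng
        "cons_over":   (400,  60,  0.38,   0.92,        True,  (0.05, 0.95)),
        "cons_normal": (400,  60,  0.38,   0.92,        True,  (0.05, 0.95)),
        "alt_over":    (700,  80,  0.50,   0.70,        False, (0.05, 0.40)),
        "alt_normal":  (250,  40,  0.50,   0.55,        False, (0.30, 0.70)),
    }
    out: list[PlantedIntron] = []
    for category, (mu, sd, gc, strength, strong_bps, pos) in spec.items():
        for _ in range(n_per_category):
            length = max(80, int(rng.normal(mu, sd)))
            seq = list(_biased_seq(rng, length, gc))
            seq[0:2] = "GT"
            seq[-2:] = "AG"
            if strong_bps:
                off = int(rng.integers(20, 36))  # branch point start, from 3' end
                seq[length - off:length - off + 7] = BPS_STRONG
            else:
                # weak branch region: no adenosine where the branch-point
                # scan looks, so the A-dominant position can never match
                for i in range(max(0, length - 50), length - 8):
                    if seq[i] == "A":
                        seq[i] = "CGT"[int(rng.integers(0, 3))]
            donor = _sample_site(rng, DONOR_CONSENSUS, strength, _DONOR_FIXED)
            acceptor = _sample_site(rng, ACCEPTOR_CONSENSUS, strength, _ACCEPTOR_FIXED)
            out.append(
                PlantedIntron(
                    category=category,
                    sequence="".join(seq),
                    donor_window=donor,
                    acceptor_window=acceptor,
                    relative_position=float(rng.uniform(*pos)),
                )
            )
    return out
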