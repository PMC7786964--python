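"""Seeded generator of a two-species toy dataset with planted truth for
every pipeline stage.

The generator emulates the downstream structure of the study data the
pipeline was designed for: a moth-like genome with protein-coding genes
(PCGs), planted lncRNA candidates of the three genomic-context classes
(intergenic / intronic / antisense), sense-overlap and coding decoys, a TE
track hitting configured overlap fractions exactly, a 14-group expression
design (9 tissues, several sex-matched with two replicates; male/female
antennae and 5 developmental stages without replicates; 21 samples), a
testis-vs-ovary DE table, and a second species whose gene order is a
block-preserving shuffle of the first with 1:1 orthology, so that synteny
families have a known planted answer.

Everything is deterministic under the seed: the same config regenerates
byte-identical fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Annotation,
    EvidenceTable,
    ExpressionTable,
    GOAnnotation,
    IntervalTrack,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_te_bed,
)
from .lncrna_identification import longest_orf

__all__ = [
    "SimConfig",
    "TruthTables",
    "SimBundle",
    "GROUPS",
    "TISSUE_GROUPS",
    "STAGE_GROUPS",
    "REPLICATES",
    "simulate",
    "write_fixture",
    "simulate_profiles",
    "simulate_correlated_profiles",
]

#: the 14 expression groups: 9 tissues then 5 developmental stages
GROUPS = ["Ag", "Ma", "Fa", "Tes", "Ov", "Mhd", "Fhd", "Mmg", "Fmg",
          "E1", "E4", "L5", "FP", "AF"]
TISSUE_GROUPS = GROUPS[:9]
STAGE_GROUPS = GROUPS[9:]
#: sex-matched tissues carry two biological replicates; antennae and the
#: developmental stages have one (21 samples in total)
REPLICATES = {"Ag": 2, "Ma": 1, "Fa": 1, "Tes": 2, "Ov": 2,
              "Mhd": 2, "Fhd": 2, "Mmg": 2, "Fmg": 2,
              "E1": 1, "E4": 1, "L5": 1, "FP": 1, "AF": 1}

STOPS = {"TAA", "TAG", "TGA"}
BASES = np.array(list("ACGT"))

TE_CLASSES = ["Unknown", "LINE", "RC/Helitron", "DNA", "LTR", "SINE"]
TE_WEIGHTS = [0.35, 0.25, 0.15, 0.12, 0.08, 0.05]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chrom: int = 3
    chrom_len: int = 400_000
    gc: float = 0.38                 # moth-like genomic GC fraction
    pcgs_per_chrom: int = 40
    # planted candidates
    n_lnc_u: int = 30
    n_lnc_i: int = 12
    n_lnc_x: int = 18
    n_sense_decoys: int = 8
    n_coding_decoys: int = 12        # long ORF + coding evidence, u context
    n_short_decoys: int = 4          # < 200 nt
    n_monoexonic_decoys: int = 3
    n_lowexpr_decoys: int = 4        # RPKM_max < 1
    # expression design
    mean_library_size: float = 5e6
    dispersion: float = 0.05         # NB alpha; 0 -> deterministic counts
    pcg_specific_frac: float = 0.3
    pcg_sex_biased_frac: float = 0.15   # each of male- and female-biased
    lnc_specific_frac: float = 0.3
    lnc_testis_frac: float = 0.3
    # planted neighbour-pair correlation
    rho: float = 0.8
    n_corr_pairs: int = 8
    n_indep_pairs: int = 8
    # synteny
    blocks_per_chrom: int = 4
    n_conserved_lnc: int = 10
    n_rearranged_lnc: int = 5
    n_b_only_lnc: int = 3
    # TE track
    te_overlap_lnc: float = 0.5
    te_overlap_pcg: float = 0.3
    n_desert_tes_per_chrom: int = 6

    def __post_init__(self) -> None:
        for frac in (self.gc, self.pcg_specific_frac, self.lnc_specific_frac,
                     self.lnc_testis_frac, self.te_overlap_lnc,
                     self.te_overlap_pcg):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_chrom, self.chrom_len, self.pcgs_per_chrom) <= 0:
            raise ValueError("counts must be positive")
        if self.pcgs_per_chrom % self.blocks_per_chrom != 0:
            raise ValueError(
                "pcgs_per_chrom must be divisible by blocks_per_chrom so "
                "synteny blocks do not straddle chromosome boundaries"
            )


@dataclass
class TruthTables:
    """Planted ground truth covering every generated feature."""

    transcript_class: dict[str, str] = field(default_factory=dict)  # u/i/x/sense
    coding: dict[str, bool] = field(default_factory=dict)
    passes_cascade: dict[str, bool] = field(default_factory=dict)
    profile_type: dict[str, str] = field(default_factory=dict)
    pair_rho: dict[tuple[str, str], float] = field(default_factory=dict)
    family_pairs: list[tuple[str, str]] = field(default_factory=list)
    rearranged_lnc: set[str] = field(default_factory=set)
    b_only_lnc: set[str] = field(default_factory=set)
    te_lnc_fraction: float = float("nan")
    te_pcg_fraction: float = float("nan")
    planted_go_term: str = ""
    designated_go_genes: set[str] = field(default_factory=set)


@dataclass
class SimBundle:
    cfg: SimConfig
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    ref_a: Annotation
    ref_b: Annotation
    candidates: Annotation
    lnc_b_loci: dict[str, tuple[str, int, int]]
    te_track: IntervalTrack
    expression: ExpressionTable
    evidence: EvidenceTable
    de_table: pd.DataFrame
    orthologs: pd.DataFrame
    go: GOAnnotation
    truth: TruthTables


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _noncoding_seq(rng: np.random.Generator, n: int, gc: float,
                   max_orf: int = 300) -> str:
    """A random sequence of length n whose longest ORF is < max_orf."""
    for _ in range(200):
        seq = "".join(_random_seq(rng, n, gc))
        if longest_orf(seq) < max_orf:
            return seq
    raise RuntimeError("could not draw a noncoding sequence")


def _coding_seq(rng: np.random.Generator, n: int, orf_nt: int = 366) -> str:
    """A sequence of length n containing an ORF of exactly orf_nt nt."""
    if n < orf_nt + 6:
        raise ValueError("sequence too short to host the ORF")
    n_codons = orf_nt // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in STOPS and c != "ATG":
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"
    lead = n - orf_nt
    prefix = "C" * (lead - lead // 2)
    suffix = "C" * (lead // 2)
    return prefix + orf + suffix


def _write_spliced(genome: dict[str, np.ndarray], t: TranscriptModel,
                   spliced: str) -> None:
    """Write a designed spliced sequence into the genome at t's exons."""
    genomic = _revcomp(spliced) if t.strand == "-" else spliced
    pos = 0
    arr = genome[t.chrom]
    for s, e in t.exons:
        seg = genomic[pos:pos + (e - s + 1)]
        arr[s - 1:e] = list(seg)
        pos += e - s + 1


def _write_splice_signals(genome: dict[str, np.ndarray],
                          t: TranscriptModel) -> None:
    """Force canonical GT...AG boundaries (transcript orientation) on every
    intron of t."""
    arr = genome[t.chrom]
    for gs, ge in t.introns:
        if t.strand == "+":
            arr[gs - 1:gs + 1] = list("GT")
            arr[ge - 2:ge] = list("AG")
        else:
            arr[ge - 2:ge] = list("AC")   # revcomp -> GT
            arr[gs - 1:gs + 1] = list("CT")  # revcomp -> AG


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def generate_genomes(cfg: SimConfig, rng: np.random.Generator | None = None,
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Two sets of random chromosomes at the configured GC, as mutable
    arrays (annotation planting writes designed sequence into them)."""
    rng = rng or np.random.default_rng(cfg.seed)
    genome_a = {f"A_chr{i + 1}": _random_seq(rng, cfg.chrom_len, cfg.gc)
                for i in range(cfg.n_chrom)}
    genome_b = {f"B_chr{i + 1}": _random_seq(rng, cfg.chrom_len, cfg.gc)
                for i in range(cfg.n_chrom)}
    return genome_a, genome_b


def _layout_species_a(cfg: SimConfig, rng: np.random.Generator):
    """Place PCGs and record intergenic gaps for species A.

    Returns (genes, gaps, conserved_lefts): ``genes`` is a list of dicts
    (global order) with chrom/exons/strand and reserved host roles;
    ``gaps`` are interior intergenic intervals keyed by the global index of
    the gene on their left; ``conserved_lefts`` are the left-gene indices
    of the gaps reserved for syntenically conserved lncRNAs.

    Conserved gaps are picked first (one interior position per synteny
    block) and every other planted locus is kept at least four gene slots
    away, so that no unplanned locus can share three orthologous flankers
    with a planted counterpart: the planted pairs are then exactly the
    accepted ones.
    """
    n_total = cfg.n_chrom * cfg.pcgs_per_chrom
    per_block = cfg.pcgs_per_chrom // cfg.blocks_per_chrom
    if per_block < 8:
        raise ValueError("synteny blocks need at least 8 genes")
    block_starts = list(range(0, n_total, per_block))
    interior = [b + per_block // 2 for b in block_starts]
    conserved_lefts = sorted(
        rng.choice(interior, size=min(cfg.n_conserved_lnc, len(interior)),
                   replace=False).tolist()
    )
    exclusion = {g + d for g in conserved_lefts for d in range(-3, 4)}

    # reserve host roles outside the conserved windows
    eligible = np.array([g for g in range(n_total) if g not in exclusion])
    n_hosts = cfg.n_lnc_i + cfg.n_lnc_x + cfg.n_sense_decoys
    if n_hosts > eligible.size:
        raise ValueError("infeasible density: not enough host genes")
    idx = rng.permutation(eligible)
    i_hosts = set(idx[:cfg.n_lnc_i].tolist())
    x_hosts = set(idx[cfg.n_lnc_i:cfg.n_lnc_i + cfg.n_lnc_x].tolist())
    s_hosts = set(idx[cfg.n_lnc_i + cfg.n_lnc_x:n_hosts].tolist())

    genes, gaps = [], []
    g = 0
    for c in range(cfg.n_chrom):
        chrom = f"A_chr{c + 1}"
        cursor = 5_000
        for j in range(cfg.pcgs_per_chrom):
            n_exons = int(rng.integers(2, 6))
            exon_lens = rng.integers(150, 301, size=n_exons)
            intron_lens = rng.integers(400, 1201, size=n_exons - 1)
            if g in i_hosts:
                intron_lens[0] = 2_500
            if g in x_hosts or g in s_hosts:
                exon_lens[0] = 220
            exons = []
            pos = cursor
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                pos = exons[-1][1] + 1
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append({
                "global": g, "chrom": chrom, "order": j,
                "exons": exons, "strand": strand,
                "i_host": g in i_hosts, "x_host": g in x_hosts,
                "s_host": g in s_hosts,
            })
            gap_len = int(rng.integers(2_000, 4_001))
            gap_start = exons[-1][1] + 1
            if j < cfg.pcgs_per_chrom - 1:
                gaps.append({
                    "chrom": chrom, "left_global": g, "left_order": j,
                    "start": gap_start + 200, "end": gap_start + gap_len - 200,
                })
            cursor = gap_start + gap_len
            g += 1
        if cursor > cfg.chrom_len - 2_000:
            raise ValueError(
                f"infeasible density: layout needs {cursor} bp on {chrom} "
                f"of length {cfg.chrom_len}"
            )
    return genes, gaps, conserved_lefts


def _two_exon_lnc(rng, tid, gene_id, chrom, start, strand, biotype="candidate",
                  exon1=160, exon2=160, intron=320) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=[(start, start + exon1 - 1),
               (start + exon1 + intron, start + exon1 + intron + exon2 - 1)],
        biotype=biotype,
    )


def generate_annotations(
    cfg: SimConfig,
    genome_a: dict[str, np.ndarray],
    genome_b: dict[str, np.ndarray],
    rng: np.random.Generator,
):
    """Plant PCGs, lncRNA candidates and decoys in species A, a shuffled
    orthologous gene order plus counterpart lncRNAs in species B, and a TE
    track hitting the configured overlap fractions exactly.
    """
    truth = TruthTables()
    genes, gaps, conserved_lefts = _layout_species_a(cfg, rng)
    exclusion = {g + d for g in conserved_lefts for d in range(-3, 4)}

    # --- species A reference PCGs -------------------------------------
    ref_a = Annotation(chrom_sizes={c: len(s) for c, s in genome_a.items()})
    for gene in genes:
        gid = f"PCGA{gene['global']:04d}"
        gene["gene_id"] = gid
        ref_a.add(TranscriptModel(
            transcript_id=f"{gid}.t1", gene_id=gid, chrom=gene["chrom"],
            strand=gene["strand"], exons=gene["exons"], biotype="coding",
        ))

    # --- candidate transcripts ----------------------------------------
    candidates = Annotation(chrom_sizes=dict(ref_a.chrom_sizes))
    u_gap_of: dict[str, dict] = {}  # u-class tid -> its gap record
    counter = [0]

    def next_tid(prefix="CAND") -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:04d}"

    conserved_gaps = [g for g in gaps if g["left_global"] in conserved_lefts]
    other_gaps = [g for g in gaps if g["left_global"] not in exclusion]
    free_gaps = [other_gaps[i] for i in rng.permutation(len(other_gaps))]
    reserved = list(reversed(conserved_gaps))  # consumed first, in order

    def take_gap(conserved: bool = False) -> dict:
        if conserved:
            return reserved.pop()
        if not free_gaps:
            raise ValueError("infeasible density: ran out of intergenic gaps")
        return free_gaps.pop()

    def plant_u(kind: str, exon1=160, exon2=160, intron=320,
                n_exons=2, conserved: bool = False) -> TranscriptModel:
        gap = take_gap(conserved)
        tid = next_tid()
        strand = "+" if rng.random() < 0.5 else "-"
        start = gap["start"] + 120
        if n_exons == 1:
            t = TranscriptModel(tid, f"LOC_{tid}", gap["chrom"], strand,
                                [(start, start + exon1 - 1)])
        else:
            t = _two_exon_lnc(rng, tid, f"LOC_{tid}", gap["chrom"], start,
                              strand, exon1=exon1, exon2=exon2, intron=intron)
        candidates.add(t)
        truth.transcript_class[tid] = "u"
        truth.coding[tid] = kind == "coding_decoy"
        truth.passes_cascade[tid] = kind == "lnc"
        u_gap_of[tid] = gap
        return t

    n_conserved = len(conserved_gaps)
    if cfg.n_lnc_u < n_conserved:
        raise ValueError("n_lnc_u must cover the conserved gap count")
    conserved_u_ids = [plant_u("lnc", conserved=True).transcript_id
                       for _ in range(n_conserved)]
    u_lnc_ids = conserved_u_ids + [
        plant_u("lnc").transcript_id
        for _ in range(cfg.n_lnc_u - n_conserved)
    ]
    coding_ids = [plant_u("coding_decoy", exon1=230, exon2=230).transcript_id
                  for _ in range(cfg.n_coding_decoys)]
    short_ids = [plant_u("short_decoy", exon1=80, exon2=60).transcript_id
                 for _ in range(cfg.n_short_decoys)]
    mono_ids = [plant_u("mono_decoy", exon1=400, n_exons=1).transcript_id
                for _ in range(cfg.n_monoexonic_decoys)]
    lowexpr_ids = [plant_u("lowexpr_decoy").transcript_id
                   for _ in range(cfg.n_lowexpr_decoys)]
    for tid in short_ids + mono_ids + lowexpr_ids:
        truth.passes_cascade[tid] = False

    i_lnc_ids, x_lnc_ids, sense_ids = [], [], []
    for gene in genes:
        if gene["i_host"]:
            # fully inside the (2500 bp) first intron, 60 bp margins
            intron1 = (gene["exons"][0][1] + 1, gene["exons"][1][0] - 1)
            tid = next_tid()
            strand = "+" if rng.random() < 0.5 else "-"
            t = _two_exon_lnc(rng, tid, f"LOC_{tid}", gene["chrom"],
                              intron1[0] + 60, strand,
                              exon1=150, exon2=150, intron=300)
            assert t.end <= intron1[1] - 60
            candidates.add(t)
            truth.transcript_class[tid] = "i"
            truth.coding[tid] = False
            truth.passes_cascade[tid] = True
            i_lnc_ids.append(tid)
        if gene["x_host"] or gene["s_host"]:
            # exon_b overlaps the host's (220 bp) first exon; exon_a sits in
            # the upstream intergenic space
            gs = gene["exons"][0][0]
            tid = next_tid()
            if gene["x_host"]:
                strand = "-" if gene["strand"] == "+" else "+"
            else:
                strand = gene["strand"]
            t = TranscriptModel(
                transcript_id=tid, gene_id=f"LOC_{tid}", chrom=gene["chrom"],
                strand=strand,
                exons=[(gs - 400, gs - 241), (gs + 10, gs + 159)],
            )
            candidates.add(t)
            if gene["x_host"]:
                truth.transcript_class[tid] = "x"
                truth.coding[tid] = False
                truth.passes_cascade[tid] = True
                x_lnc_ids.append(tid)
            else:
                truth.transcript_class[tid] = "sense"
                truth.coding[tid] = False
                truth.passes_cascade[tid] = False
                sense_ids.append(tid)

    # --- designed sequences -------------------------------------------
    for t in ref_a:
        _write_splice_signals(genome_a, t)
    for tid, t in candidates.transcripts.items():
        if truth.coding[tid]:
            _write_spliced(genome_a, t, _coding_seq(rng, t.exonic_length))
        else:
            _write_spliced(
                genome_a, t, _noncoding_seq(rng, t.exonic_length, cfg.gc)
            )
    for t in candidates:
        if t.n_exons > 1:
            _write_splice_signals(genome_a, t)

    # --- TE track: exact planted overlap fractions --------------------
    te_records: list[tuple[str, int, int, str]] = []
    true_lnc = u_lnc_ids + i_lnc_ids + x_lnc_ids

    def te_class() -> str:
        return TE_CLASSES[rng.choice(len(TE_CLASSES), p=TE_WEIGHTS)]

    n_te_lnc = math.floor(cfg.te_overlap_lnc * len(true_lnc))
    for tid in rng.choice(true_lnc, size=n_te_lnc, replace=False):
        t = candidates[str(tid)]
        s, _e = t.exons[0]
        # 0-based half-open BED record inside the first exon
        te_records.append((t.chrom, s + 4, s + 4 + 80, te_class()))
    eligible_pcg = [g for g in genes if not (g["x_host"] or g["s_host"])]
    n_te_pcg = math.floor(cfg.te_overlap_pcg * len(genes))
    te_pcg_idx = rng.choice(len(eligible_pcg), size=n_te_pcg, replace=False)
    te_pcg_gene_ids = set()
    for k in te_pcg_idx:
        gene = eligible_pcg[int(k)]
        s, _e = gene["exons"][0]
        te_records.append((gene["chrom"], s + 4, s + 4 + 80, te_class()))
        te_pcg_gene_ids.add(gene["gene_id"])
    truth.te_lnc_fraction = n_te_lnc / len(true_lnc)
    truth.te_pcg_fraction = n_te_pcg / len(genes)
    for c, arr in genome_a.items():
        desert_start = max(g["exons"][-1][1] for g in genes
                           if g["chrom"] == c) + 6_000
        for k in range(cfg.n_desert_tes_per_chrom):
            s = desert_start + k * 500
            if s + 120 < len(arr):
                te_records.append((c, s, s + 120, te_class()))
    te_track = IntervalTrack(sorted(te_records))

    # --- species B: block-preserving shuffle + counterpart lncRNAs ----
    n_total = len(genes)
    per_block = cfg.pcgs_per_chrom // cfg.blocks_per_chrom
    blocks = [list(range(b, min(b + per_block, n_total)))
              for b in range(0, n_total, per_block)]
    order = rng.permutation(len(blocks))
    shuffled = [blocks[i] for i in order]
    per_chrom_b = len(shuffled) // cfg.n_chrom

    ref_b = Annotation(chrom_sizes={c: len(s) for c, s in genome_b.items()})
    b_pos: dict[int, tuple[str, int, int, int]] = {}  # global -> chrom,order,start,end
    b_gap_after: dict[int, tuple[str, int]] = {}      # global -> (chrom, gap start)
    for bc in range(cfg.n_chrom):
        chrom = f"B_chr{bc + 1}"
        cursor = 5_000
        pos_in_chrom = 0
        for block in shuffled[bc * per_chrom_b:(bc + 1) * per_chrom_b]:
            for g in block:
                gid = f"PCGB{g:04d}"
                exons = [(cursor, cursor + 199),
                         (cursor + 700, cursor + 899)]
                ref_b.add(TranscriptModel(
                    transcript_id=f"{gid}.t1", gene_id=gid, chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons, biotype="coding",
                ))
                b_pos[g] = (chrom, pos_in_chrom, exons[0][0], exons[-1][1])
                b_gap_after[g] = (chrom, exons[-1][1] + 1)
                cursor = exons[-1][1] + 1 + 2_500
                pos_in_chrom += 1
        if cursor > cfg.chrom_len - 2_000:
            raise ValueError("infeasible density in species B layout")

    # conserved u-lncs were planted in the reserved block-interior gaps;
    # every other locus is >= 4 gene slots away, so the planted pairs are
    # exactly the recoverable ones
    conserved = conserved_u_ids
    remaining = [tid for tid in u_lnc_ids if tid not in conserved]
    rearranged = remaining[:cfg.n_rearranged_lnc]

    lnc_b_loci: dict[str, tuple[str, int, int]] = {}
    b_counter = [0]

    def plant_b_lnc(chrom: str, gap_start: int) -> str:
        b_counter[0] += 1
        bid = f"lncB{b_counter[0]:04d}"
        start = gap_start + 500
        lnc_b_loci[bid] = (chrom, start, start + 600)
        return bid

    for tid in conserved:
        g = u_gap_of[tid]["left_global"]
        chrom, gap_start = b_gap_after[g]
        bid = plant_b_lnc(chrom, gap_start)
        truth.family_pairs.append((candidates[tid].gene_id, bid))
    # rearranged loci sit outside any conserved block in B: their
    # counterparts land in the gene-free 5' margin of a B chromosome, so no
    # flanking orthologs exist and no syntenic pair can be accepted
    b_chrom_names = sorted({c for c, _p, _s, _e in b_pos.values()})
    for k, tid in enumerate(rearranged):
        chrom = b_chrom_names[k % len(b_chrom_names)]
        plant_b_lnc(chrom, 200 + 800 * (k // len(b_chrom_names)))
        truth.rearranged_lnc.add(tid)
    for k in range(cfg.n_b_only_lnc):
        chrom = b_chrom_names[k % len(b_chrom_names)]
        truth.b_only_lnc.add(
            plant_b_lnc(chrom, 2_600 + 800 * (k // len(b_chrom_names)))
        )

    orthologs = pd.DataFrame({
        "gene_a": [f"PCGA{g:04d}" for g in range(n_total)],
        "gene_b": [f"PCGB{g:04d}" for g in range(n_total)],
        "group_id": [f"OG{g:04d}" for g in range(n_total)],
    })

    extras = {
        "u_lnc_ids": u_lnc_ids, "i_lnc_ids": i_lnc_ids,
        "x_lnc_ids": x_lnc_ids, "sense_ids": sense_ids,
        "coding_ids": coding_ids, "short_ids": short_ids,
        "mono_ids": mono_ids, "lowexpr_ids": lowexpr_ids,
        "true_lnc": true_lnc, "u_gap_of": u_gap_of,
        "te_pcg_gene_ids": te_pcg_gene_ids,
    }
    return ref_a, ref_b, candidates, lnc_b_loci, te_track, orthologs, truth, extras


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _profile_vector(rng: np.random.Generator, kind: str) -> np.ndarray:
    """Group-mean RPKM over the 14 groups for one planted profile type."""
    n = len(GROUPS)
    if kind == "housekeeping":
        base = float(rng.lognormal(np.log(15.0), 0.2))
        return base * rng.lognormal(0.0, 0.15, size=n)
    if kind.startswith("specific:"):
        group = kind.split(":", 1)[1]
        v = rng.uniform(0.0, 0.3, size=n)
        v[GROUPS.index(group)] = float(rng.uniform(20.0, 80.0))
        return v
    if kind == "testis":
        v = rng.uniform(0.2, 2.0, size=n)
        v[GROUPS.index("Tes")] = float(rng.uniform(20.0, 60.0))
        v[GROUPS.index("Ov")] = 0.05
        return v
    if kind in {"male_biased", "female_biased"}:
        base = float(rng.lognormal(np.log(15.0), 0.2))
        v = base * rng.lognormal(0.0, 0.1, size=n)
        v[GROUPS.index("Tes" if kind == "male_biased" else "Ov")] *= 4.0
        return v
    if kind == "silent":
        return rng.uniform(0.01, 0.03, size=n)
    raise ValueError(f"unknown profile type {kind!r}")


def _log_mixing_weight(rho: float, sigma: float) -> float:
    """Log-scale mixing weight that yields a *linear*-scale correlation of
    rho between the two lognormal profiles (the lognormal transform
    attenuates correlation, which is compensated here)."""
    if rho <= 0:
        return 0.0
    rho_log = math.log1p(rho * math.expm1(sigma ** 2)) / sigma ** 2
    return min(rho_log, 1.0)


def _correlated_log_profiles(rng: np.random.Generator, rho: float,
                             sigma: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """A pair of RPKM profiles sharing a latent mixed to a linear-scale
    target correlation rho."""
    n = len(GROUPS)
    z = rng.normal(0.0, 1.0, size=n)
    e1 = rng.normal(0.0, 1.0, size=n)
    e2 = rng.normal(0.0, 1.0, size=n)
    w = _log_mixing_weight(rho, sigma)
    a, b = math.sqrt(w), math.sqrt(1.0 - w)
    x = np.exp(np.log(10.0) + sigma * (a * z + b * e1))
    y = np.exp(np.log(10.0) + sigma * (a * z + b * e2))
    return x, y


def generate_expression(cfg: SimConfig, ref_a: Annotation,
                        candidates: Annotation, truth: TruthTables,
                        extras: dict, rng: np.random.Generator):
    """Counts for 21 samples over all PCGs and candidates, plus a
    testis-vs-ovary DE table, with planted profile types in the truth."""
    features: dict[str, int] = {}
    for t in ref_a:
        features[t.gene_id] = t.exonic_length
    for t in candidates:
        features[t.transcript_id] = t.exonic_length

    # planted profile types; a slice of PCGs carries an explicit sex bias
    # (testis- or ovary-elevated) so the lncRNA male-bias enrichment test
    # has a realistic PCG background
    profile: dict[str, np.ndarray] = {}
    pcg_ids = sorted({t.gene_id for t in ref_a})
    n_spec = math.floor(cfg.pcg_specific_frac * len(pcg_ids))
    n_sex = math.floor(cfg.pcg_sex_biased_frac * len(pcg_ids))
    shuffled_pcgs = [str(g) for g in rng.permutation(pcg_ids)]
    pcg_kind = {}
    for j, gid in enumerate(shuffled_pcgs):
        if j < n_spec:
            pcg_kind[gid] = f"specific:{TISSUE_GROUPS[rng.integers(0, 9)]}"
        elif j < n_spec + n_sex:
            pcg_kind[gid] = "male_biased"
        elif j < n_spec + 2 * n_sex:
            pcg_kind[gid] = "female_biased"
        else:
            pcg_kind[gid] = "housekeeping"
    for gid in pcg_ids:
        truth.profile_type[gid] = pcg_kind[gid]
        profile[gid] = _profile_vector(rng, pcg_kind[gid])

    true_lnc = extras["true_lnc"]
    n_tes = math.floor(cfg.lnc_testis_frac * len(true_lnc))
    n_lspec = math.floor(cfg.lnc_specific_frac * len(true_lnc))
    shuffled = list(rng.permutation(true_lnc))
    assignment = (["testis"] * n_tes
                  + [f"specific:{TISSUE_GROUPS[rng.integers(0, 9)]}"
                     for _ in range(n_lspec)]
                  + ["housekeeping"] * (len(true_lnc) - n_tes - n_lspec))
    for tid, kind in zip(shuffled, assignment):
        truth.profile_type[tid] = kind
        profile[tid] = _profile_vector(rng, kind)
    for tid in (extras["coding_ids"] + extras["short_ids"]
                + extras["mono_ids"] + extras["sense_ids"]):
        truth.profile_type[tid] = "housekeeping"
        profile[tid] = _profile_vector(rng, "housekeeping")
    for tid in extras["lowexpr_ids"]:
        truth.profile_type[tid] = "silent"
        profile[tid] = _profile_vector(rng, "silent")

    # planted neighbour-pair correlations: u-lnc anchors with the PCG on
    # the left of their gap; testis-biased lncRNAs are never overridden so
    # the planted sex-bias contrast stays intact
    u_gap_of = extras["u_gap_of"]
    pool = [tid for tid in extras["u_lnc_ids"]
            if truth.profile_type[tid] == "housekeeping"]
    pool += [tid for tid in extras["u_lnc_ids"]
             if tid not in pool and truth.profile_type[tid] != "testis"]
    k = 0
    for tid in pool:
        if k >= cfg.n_corr_pairs + cfg.n_indep_pairs:
            break
        partner = f"PCGA{u_gap_of[tid]['left_global']:04d}"
        if truth.profile_type.get(partner, "").startswith("pair"):
            continue
        if k < cfg.n_corr_pairs:
            x, y = _correlated_log_profiles(rng, cfg.rho)
            truth.pair_rho[(tid, partner)] = cfg.rho
            label = "pair_corr"
        else:
            x, _ = _correlated_log_profiles(rng, 0.0)
            _, y = _correlated_log_profiles(rng, 0.0)
            truth.pair_rho[(tid, partner)] = 0.0
            label = "pair_indep"
        profile[tid], profile[partner] = x, y
        truth.profile_type[tid] = label
        truth.profile_type[partner] = label
        k += 1

    # samples and counts
    samples, sample_groups = [], {}
    for g in GROUPS:
        for r in range(1, REPLICATES[g] + 1):
            name = f"{g}_r{r}"
            samples.append(name)
            sample_groups[name] = g
    library_sizes = pd.Series(
        cfg.mean_library_size * rng.lognormal(0.0, 0.05, size=len(samples)),
        index=samples,
    ).round()

    feat_ids = sorted(features)
    lengths = pd.Series({f: float(features[f]) for f in feat_ids})
    silent = set(extras["lowexpr_ids"])
    counts = np.zeros((len(feat_ids), len(samples)))
    for si, s in enumerate(samples):
        g_idx = GROUPS.index(sample_groups[s])
        n_lib = float(library_sizes[s])
        for fi, f in enumerate(feat_ids):
            mu = profile[f][g_idx] * lengths[f] * n_lib / 1e9
            if cfg.dispersion == 0:
                c = round(mu)
            elif mu == 0:
                c = 0
            else:
                r = 1.0 / cfg.dispersion
                c = int(rng.negative_binomial(r, r / (r + mu)))
            if f in silent:
                c = min(c, 1)  # planted low-abundance: RPKM_max stays < 1
            counts[fi, si] = c
    counts_df = pd.DataFrame(counts, index=feat_ids, columns=samples)
    expression = ExpressionTable(counts_df, lengths, sample_groups,
                                 library_sizes)

    # DE table (testis vs ovary): fold changes follow the planted profiles
    # and adjusted p-values are significant exactly for the profile types
    # planted with a sex-biased direction
    tes_i, ov_i = GROUPS.index("Tes"), GROUPS.index("Ov")
    biased_kinds = {"testis", "male_biased", "female_biased",
                    "specific:Tes", "specific:Ov"}
    rows = []
    for f in feat_ids:
        v = profile[f]
        log2fc = math.log2((v[tes_i] + 0.1) / (v[ov_i] + 0.1))
        sig = truth.profile_type.get(f) in biased_kinds
        rows.append({
            "feature_id": f,
            "log2fc": round(log2fc, 4),
            "pvalue": 1e-9 if sig else round(float(rng.uniform(0.1, 0.9)), 4),
            "padj": 1e-8 if sig else round(float(rng.uniform(0.2, 0.95)), 4),
        })
    de_table = pd.DataFrame(rows)

    evidence = EvidenceTable(pd.DataFrame(
        {
            "cpc_coding": [truth.coding[t] for t in sorted(truth.coding)],
            "cnci_coding": [truth.coding[t] for t in sorted(truth.coding)],
            "blastx_hit": [truth.coding[t] for t in sorted(truth.coding)],
            "pfam_hit": [False for _ in truth.coding],
        },
        index=sorted(truth.coding),
    ))
    return expression, de_table, evidence, profile


def generate_go(cfg: SimConfig, ref_a: Annotation, truth: TruthTables,
                designated: set[str], rng: np.random.Generator) -> GOAnnotation:
    """Uniform background terms plus one planted term concentrated in the
    designated gene set."""
    pcg_ids = sorted({t.gene_id for t in ref_a})
    background_terms = [f"GO:{i:07d}" for i in range(1, 31)]
    planted = "GO:0000042"
    gene_terms: dict[str, set[str]] = {}
    for gid in pcg_ids:
        terms = set(rng.choice(background_terms, size=3, replace=False))
        gene_terms[gid] = terms
    for gid in designated:
        gene_terms.setdefault(gid, set()).add(planted)
    # two background carriers so the planted term is concentrated, not pure
    others = [g for g in pcg_ids if g not in designated]
    for gid in rng.choice(others, size=2, replace=False):
        gene_terms[str(gid)].add(planted)
    term_info = {t: (f"background process {i}", "BP")
                 for i, t in enumerate(background_terms, start=1)}
    term_info[planted] = ("planted process", "BP")
    truth.planted_go_term = planted
    truth.designated_go_genes = set(designated)
    return GOAnnotation(gene_terms, term_info)


# ---------------------------------------------------------------------------
# top-level orchestration
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig = SimConfig()) -> SimBundle:
    """Generate the full two-species fixture with planted truth."""
    rng = np.random.default_rng(cfg.seed)
    genome_a, genome_b = generate_genomes(cfg, rng)
    (ref_a, ref_b, candidates, lnc_b_loci, te_track, orthologs, truth,
     extras) = generate_annotations(cfg, genome_a, genome_b, rng)
    expression, de_table, evidence, _profile = generate_expression(
        cfg, ref_a, candidates, truth, extras, rng
    )
    designated = {p for (_a, p), rho in truth.pair_rho.items() if rho > 0}
    go = generate_go(cfg, ref_a, truth, designated, rng)
    return SimBundle(
        cfg=cfg,
        genome_a={c: "".join(s) for c, s in genome_a.items()},
        genome_b={c: "".join(s) for c, s in genome_b.items()},
        ref_a=ref_a, ref_b=ref_b, candidates=candidates,
        lnc_b_loci=lnc_b_loci, te_track=te_track,
        expression=expression, evidence=evidence, de_table=de_table,
        orthologs=orthologs, go=go, truth=truth,
    )


def write_fixture(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the plain-text files the CLI consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "genome_a": "genome_a.fa", "genome_b": "genome_b.fa",
        "ref_a": "ref_a.gtf", "ref_b": "ref_b.gtf",
        "candidates": "candidates.gtf", "te": "te.bed",
        "counts": "counts.tsv", "groups": "groups.tsv",
        "lengths": "lengths.tsv", "library_sizes": "library_sizes.tsv",
        "evidence": "evidence.tsv", "de": "de_testis_vs_ovary.tsv",
        "orthologs": "orthologs.tsv", "go": "go.tsv",
        "go_terms": "go_terms.tsv", "lnc_b": "lnc_b_loci.tsv",
        "truth_class": "truth_transcripts.tsv",
        "truth_pairs": "truth_pairs.tsv",
        "truth_families": "truth_families.tsv",
    }.items()}
    write_fasta(bundle.genome_a, paths["genome_a"])
    write_fasta(bundle.genome_b, paths["genome_b"])
    write_gtf(bundle.ref_a, paths["ref_a"])
    write_gtf(bundle.ref_b, paths["ref_b"])
    write_gtf(bundle.candidates, paths["candidates"])
    write_te_bed(bundle.te_track, paths["te"])

    expr = bundle.expression
    expr.counts.astype(int).to_csv(paths["counts"], sep="\t",
                                   index_label="feature_id")
    pd.DataFrame({"sample": expr.samples,
                  "group": [expr.sample_groups[s] for s in expr.samples]}
                 ).to_csv(paths["groups"], sep="\t", index=False)
    expr.feature_lengths.astype(int).rename("length").to_csv(
        paths["lengths"], sep="\t", index_label="feature_id")
    expr.library_sizes.astype(int).rename("library_size").to_csv(
        paths["library_sizes"], sep="\t", index_label="sample")
    bundle.evidence.table.astype(int).to_csv(
        paths["evidence"], sep="\t", index_label="transcript_id")
    bundle.de_table.to_csv(paths["de"], sep="\t", index=False)
    bundle.orthologs.to_csv(paths["orthologs"], sep="\t", index=False)

    with open(paths["go"], "w") as fh:
        for gene in sorted(bundle.go.gene_terms):
            fh.write(f"{gene}\t{';'.join(sorted(bundle.go.gene_terms[gene]))}\n")
    pd.DataFrame(
        [(t, n, ns) for t, (n, ns) in sorted(bundle.go.term_info.items())],
        columns=["term", "name", "namespace"],
    ).to_csv(paths["go_terms"], sep="\t", index=False)
    pd.DataFrame(
        [(lid, c, s, e) for lid, (c, s, e) in sorted(bundle.lnc_b_loci.items())],
        columns=["locus_id", "chrom", "start", "end"],
    ).to_csv(paths["lnc_b"], sep="\t", index=False)

    truth = bundle.truth
    pd.DataFrame({
        "transcript_id": sorted(truth.transcript_class),
        "planted_class": [truth.transcript_class[t]
                          for t in sorted(truth.transcript_class)],
        "planted_coding": [int(truth.coding.get(t, False))
                           for t in sorted(truth.transcript_class)],
        "passes_cascade": [int(truth.passes_cascade.get(t, False))
                           for t in sorted(truth.transcript_class)],
    }).to_csv(paths["truth_class"], sep="\t", index=False)
    pd.DataFrame(
        [(a, p, rho) for (a, p), rho in sorted(truth.pair_rho.items())],
        columns=["anchor", "partner", "planted_rho"],
    ).to_csv(paths["truth_pairs"], sep="\t", index=False)
    pd.DataFrame(truth.family_pairs, columns=["locus_a", "locus_b"]
                 ).to_csv(paths["truth_families"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# light-weight profile simulators for statistical recovery checks
# ---------------------------------------------------------------------------

def simulate_profiles(
    n_specific: int,
    n_housekeeping: int,
    n_groups: int = 9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Dirichlet-shaped group-mean profiles: a tissue-specific class
    (concentrated on one random group) and a near-uniform housekeeping
    class.  Returns (profiles, truth labels)."""
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for i in range(n_specific):
        alpha = np.full(n_groups, 0.2)
        alpha[rng.integers(0, n_groups)] = 8.0
        rows.append(rng.dirichlet(alpha) * float(rng.uniform(20, 100)))
        labels.append("specific")
        index.append(f"spec{i:04d}")
    for i in range(n_housekeeping):
        rows.append(rng.dirichlet(np.full(n_groups, 50.0))
                    * float(rng.uniform(20, 100)))
        labels.append("housekeeping")
        index.append(f"hk{i:04d}")
    cols = [f"g{j}" for j in range(n_groups)]
    return (pd.DataFrame(rows, index=index, columns=cols),
            pd.Series(labels, index=index))


def simulate_correlated_profiles(
    n_pairs: int,
    rho: float,
    n_groups: int = 14,
    seed: int = 0,
    sigma: float = 0.8,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pairs of RPKM vectors sharing a latent profile mixed to a target
    linear-scale correlation rho (rho = 0 gives independent pairs)."""
    rng = np.random.default_rng(seed)
    w = _log_mixing_weight(rho, sigma)
    a, b = math.sqrt(w), math.sqrt(1.0 - w)
    pairs = []
    for _ in range(n_pairs):
        z = rng.normal(0.0, 1.0, size=n_groups)
        x = np.exp(np.log(10.0) + sigma * (a * z + b * rng.normal(size=n_groups)))
        y = np.exp(np.log(10.0) + sigma * (a * z + b * rng.normal(size=n_groups)))
        pairs.append((x, y))
    return pairs
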