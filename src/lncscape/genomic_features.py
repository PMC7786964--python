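"""Descriptive genomics of a transcript set: length/exon/intron/GC
statistics, splice-site context, TE overlap with enrichment test, and
chromosome-distribution correlations.

TE overlap is exon-based by default (a feature overlaps a TE iff any exon
shares >= 1 bp with any TE record); span-based overlap is available via
``mode="span"``.  In class-composition tallies each overlapped TE record
contributes once per record, so the shares count TEs, not features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import Annotation, IntervalTrack, TranscriptModel
from .lncrna_identification import round_half_up
from .stat_tests import TestResult, fisher_exact_2x2, pearson

__all__ = [
    "FeatureStats",
    "size_stats",
    "gc_content",
    "splice_site_context",
    "te_overlap",
    "te_class_composition",
    "chromosome_distribution",
]


@dataclass
class FeatureStats:
    transcript_lengths: np.ndarray
    exon_counts: np.ndarray
    exon_lengths: np.ndarray   # pooled over transcripts
    intron_lengths: np.ndarray  # pooled

    def medians(self) -> dict[str, float]:
        return {
            "transcript_length": float(np.median(self.transcript_lengths)),
            "exon_count": float(np.median(self.exon_counts)),
            "exon_length": float(np.median(self.exon_lengths))
            if self.exon_lengths.size else float("nan"),
            "intron_length": float(np.median(self.intron_lengths))
            if self.intron_lengths.size else float("nan"),
        }


def size_stats(transcripts: Iterable[TranscriptModel]) -> FeatureStats:
    """Per-transcript exonic length and exon count, pooled exon/intron
    length vectors."""
    tlens, counts, elens, ilens = [], [], [], []
    for t in transcripts:
        tlens.append(t.exonic_length)
        counts.append(t.n_exons)
        elens.extend(e - s + 1 for s, e in t.exons)
        ilens.extend(e - s + 1 for s, e in t.introns)
    return FeatureStats(
        np.asarray(tlens), np.asarray(counts),
        np.asarray(elens), np.asarray(ilens),
    )


def gc_content(seq: str) -> float:
    """100*(G+C)/(A+C+G+T); N and ambiguity codes are excluded from the
    denominator; NaN when no unambiguous base remains."""
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def splice_site_context(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    flank: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Positional base frequencies around donor and acceptor sites.

    Each window covers ``flank`` exonic plus ``flank`` intronic bases around
    the junction, strand-corrected so position 0 is the first intronic base
    at the donor and the last intronic base sits at position -1 of the
    acceptor window.  Introns shorter than the window contribute only their
    available positions.  Also returns the fraction of introns whose
    transcript-orientation boundary dinucleotides are GT...AG.
    """
    width = 2 * flank
    donor_counts = np.zeros((width, 4))
    acceptor_counts = np.zeros((width, 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_introns = 0
    n_canonical = 0

    def tally(counts: np.ndarray, window: str, valid: np.ndarray) -> None:
        for pos, (base, ok) in enumerate(zip(window, valid)):
            if ok and base in base_idx:
                counts[pos, base_idx[base]] += 1

    for t in transcripts:
        seq = genome[t.chrom]
        for gs, ge in t.introns:
            n_introns += 1
            ilen = ge - gs + 1
            # genomic windows, 0-based slices; exonic flank | intronic flank
            left = seq[gs - 1 - flank: gs - 1 + flank]
            right = seq[ge - flank: ge + flank]
            # validity mask: intronic positions beyond the intron are masked
            lvalid = np.array([True] * flank + [i < ilen for i in range(flank)])
            rvalid = np.array([ilen - flank + i >= 0 for i in range(flank)]
                              + [True] * flank)
            if t.strand == "+":
                donor5 = seq[gs - 1: gs + 1]
                accept3 = seq[ge - 2: ge]
                tally(donor_counts, left, lvalid)
                tally(acceptor_counts, right, rvalid)
            else:
                donor5 = _revcomp(seq[ge - 2: ge])
                accept3 = _revcomp(seq[gs - 1: gs + 1])
                tally(donor_counts, _revcomp(right), rvalid[::-1])
                tally(acceptor_counts, _revcomp(left), lvalid[::-1])
            if donor5 == "GT" and accept3 == "AG":
                n_canonical += 1

    positions = list(range(-flank, 0)) + list(range(0, flank))

    def normalise(counts: np.ndarray) -> pd.DataFrame:
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            freq = np.where(totals > 0, counts / totals, np.nan)
        return pd.DataFrame(freq, index=positions, columns=list("ACGT"))

    frac = n_canonical / n_introns if n_introns else float("nan")
    return normalise(donor_counts), normalise(acceptor_counts), frac


def _feature_te_hits(
    features: Iterable[TranscriptModel],
    trees,
    mode: str,
) -> dict[str, list[tuple[int, str]]]:
    """feature id -> list of (TE record index, TE class) it overlaps."""
    hits: dict[str, list[tuple[int, str]]] = {}
    for t in features:
        tree = trees.get(t.chrom)
        found: dict[int, str] = {}
        if tree is not None:
            intervals = (
                [(t.start, t.end)] if mode == "span" else t.exons
            )
            for s, e in intervals:
                for iv in tree.overlap(s, e + 1):
                    idx, label = iv.data
                    found[idx] = label
        hits[t.transcript_id] = sorted(found.items())
    return hits


def te_overlap(
    features_a: Iterable[TranscriptModel],
    te: IntervalTrack,
    features_b: Iterable[TranscriptModel],
    mode: str = "exon",
) -> tuple[pd.Series, pd.Series, np.ndarray, TestResult | None]:
    """Per-feature TE-overlap flags for two feature classes, the 2x2
    contingency table [[a_overlap, a_not], [b_overlap, b_not]] and a
    two-sided Fisher p.  An empty TE track gives all-False flags and skips
    the test (None).
    """
    if mode not in {"exon", "span"}:
        raise ValueError("mode must be 'exon' or 'span'")
    features_a = list(features_a)
    features_b = list(features_b)
    if len(te) == 0:
        flags_a = pd.Series(False, index=[t.transcript_id for t in features_a])
        flags_b = pd.Series(False, index=[t.transcript_id for t in features_b])
        table = np.array([[0, len(features_a)], [0, len(features_b)]])
        return flags_a, flags_b, table, None
    trees = te.index()
    hits_a = _feature_te_hits(features_a, trees, mode)
    hits_b = _feature_te_hits(features_b, trees, mode)
    flags_a = pd.Series({k: bool(v) for k, v in hits_a.items()})
    flags_b = pd.Series({k: bool(v) for k, v in hits_b.items()})
    table = np.array([
        [int(flags_a.sum()), int((~flags_a).sum())],
        [int(flags_b.sum()), int((~flags_b).sum())],
    ])
    return flags_a, flags_b, table, fisher_exact_2x2(table)


def te_class_composition(
    features: Iterable[TranscriptModel],
    te: IntervalTrack,
    mode: str = "exon",
) -> pd.DataFrame:
    """Counts and shares of TE classes among overlapped TE records.

    Every (feature, TE record) overlap contributes the record's class once,
    so a feature overlapping three LINE records adds three LINE counts.
    """
    trees = te.index()
    hits = _feature_te_hits(list(features), trees, mode)
    labels: list[str] = []
    for pairs in hits.values():
        labels.extend(label for _idx, label in pairs)
    if not labels:
        return pd.DataFrame(columns=["count", "pct"])
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame({
        "count": counts,
        "pct": [round_half_up(100.0 * c / counts.sum(), 2) for c in counts],
    })
    out.index.name = "te_class"
    return out


def chromosome_distribution(
    lnc_transcripts: Iterable[TranscriptModel],
    reference: Annotation,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-chromosome lncRNA counts and their Pearson correlations with
    chromosome size and with PCG count (two-sided p from the t
    distribution).  Correlations are skipped below three chromosomes.
    """
    if not reference.chrom_sizes:
        raise ValueError("reference annotation lacks chrom_sizes")
    chroms = sorted(reference.chrom_sizes)
    lnc_counts = pd.Series(0, index=chroms, dtype=int)
    for t in lnc_transcripts:
        if t.chrom in lnc_counts.index:
            lnc_counts[t.chrom] += 1
    pcg_counts = pd.Series(0, index=chroms, dtype=int)
    for _, row in reference.gene_spans().iterrows():
        if row["chrom"] in pcg_counts.index:
            pcg_counts[row["chrom"]] += 1
    sizes = pd.Series({c: reference.chrom_sizes[c] for c in chroms}, dtype=float)
    table = pd.DataFrame({
        "n_lnc": lnc_counts, "n_pcg": pcg_counts, "size_bp": sizes,
    })
    correlations: dict[str, tuple[float, float]] = {}
    if len(chroms) >= 3:
        # a zero-variance vector (equal-sized chromosomes) makes the
        # correlation undefined; that pairing is skipped, not an error
        for name, other in (("vs_chrom_size", table["size_bp"]),
                            ("vs_pcg_count", table["n_pcg"])):
            if np.ptp(table["n_lnc"]) > 0 and np.ptp(other) > 0:
                correlations[name] = pearson(table["n_lnc"], other)
    return table, correlations
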