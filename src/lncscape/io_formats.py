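"""Readers, writers and domain containers for every external format the
pipeline touches.

Coordinate conventions
----------------------
GTF exons are 1-based inclusive and stay that way internally; BED-like TE
input is 0-based half-open and is converted exactly once, at the parse
boundary.  All interval arithmetic elsewhere in the package is 1-based
inclusive.

Strand "." is accepted at parse time but transcripts without a resolved
strand are excluded from classification (the genomic-context classes are
strand-defined); exclusions are logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger("lncscape")

__all__ = [
    "TranscriptModel",
    "Annotation",
    "IntervalTrack",
    "ExpressionTable",
    "EvidenceTable",
    "GOAnnotation",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_te_bed",
    "write_te_bed",
    "read_expression_table",
    "read_evidence_table",
    "read_blast_tabular",
    "read_ortholog_table",
    "read_de_table",
    "read_go_annotations",
]

BLAST_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class GtfParseError(ValueError):
    """Malformed GTF input; message carries the offending line number."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A stranded, exon-structured feature on a chromosome.

    Exons are (start, end) pairs in 1-based inclusive genomic coordinates,
    sorted ascending and pairwise non-overlapping; introns are the gaps
    between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with zero exons")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s < 1:
                raise ValueError(f"{self.transcript_id}: exon start {s} < 1")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        """[min exon start, max exon end], 1-based inclusive."""
        return self.start, self.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e0 + 1, s1 - 1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]


class Annotation:
    """A collection of transcripts with a per-chromosome interval index.

    The index answers span-intersection queries exactly: a lookup returns
    the transcripts whose [start, end] span intersects the query interval.
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel] = (),
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})
        self._index: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        size = self.chrom_sizes.get(t.chrom)
        if size is not None and t.end > size:
            raise ValueError(
                f"{t.transcript_id}: exon end {t.end} beyond {t.chrom} length {size}"
            )
        self.transcripts[t.transcript_id] = t
        # half-open interval tree over 1-based inclusive spans
        self._index.setdefault(t.chrom, IntervalTree()).addi(
            t.start, t.end + 1, t.transcript_id
        )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span intersects [start, end] (1-based inclusive)."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return [self.transcripts[iv.data] for iv in tree.overlap(start, end + 1)]

    def gene_ids(self) -> set[str]:
        return {t.gene_id for t in self}

    def gene_spans(self) -> pd.DataFrame:
        """One row per gene: chrom, start, end, strand (union of transcripts)."""
        rows: dict[str, list] = {}
        for t in self:
            row = rows.get(t.gene_id)
            if row is None:
                rows[t.gene_id] = [t.chrom, t.start, t.end, t.strand]
            else:
                row[1] = min(row[1], t.start)
                row[2] = max(row[2], t.end)
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["chrom", "start", "end", "strand"]
        )
        df.index.name = "gene_id"
        return df.sort_values(["chrom", "start"])


@dataclass
class IntervalTrack:
    """Labelled genomic intervals (e.g. TE classes), 0-based half-open."""

    records: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, _label in self.records:
            if start >= end:
                raise ValueError(f"{chrom}:{start}-{end}: start must be < end")
            if start < 0:
                raise ValueError(f"{chrom}:{start}-{end}: negative coordinate")

    def __len__(self) -> int:
        return len(self.records)

    def to_1based(self) -> Iterator[tuple[str, int, int, str]]:
        """Yield records converted to 1-based inclusive coordinates."""
        for chrom, start, end, label in self.records:
            yield chrom, start + 1, end, label

    def index(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval tree over 1-based inclusive coordinates."""
        trees: dict[str, IntervalTree] = {}
        for i, (chrom, start, end, label) in enumerate(self.to_1based()):
            trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, (i, label))
        return trees


class ExpressionTable:
    """Raw counts per feature per sample plus the metadata RPKM needs.

    RPKM = 1e9 * C / (N * L) with C the read count, N the per-sample
    library size (total mapped reads; defaults to the column sum) and L
    the feature's exon-model length in bp.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        feature_lengths: pd.Series,
        sample_groups: Mapping[str, str],
        library_sizes: pd.Series | None = None,
    ) -> None:
        if (counts.values < 0).any():
            raise ValueError("negative entry in counts table")
        self.counts = counts.astype(float)
        self.feature_lengths = feature_lengths.reindex(counts.index)
        if self.feature_lengths.isna().any():
            missing = self.feature_lengths.index[self.feature_lengths.isna()]
            raise ValueError(f"missing feature length for {list(missing)[:5]}")
        if (self.feature_lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        self.sample_groups = dict(sample_groups)
        unmapped = [s for s in counts.columns if s not in self.sample_groups]
        if unmapped:
            raise ValueError(f"samples without a group: {unmapped}")
        if library_sizes is None:
            library_sizes = counts.sum(axis=0)
        self.library_sizes = library_sizes.reindex(counts.columns)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def rpkm_matrix(self) -> pd.DataFrame:
        """Per-sample RPKM, feature x sample."""
        C = self.counts
        N = self.library_sizes
        L = self.feature_lengths
        return 1e9 * C.div(N, axis=1).div(L, axis=0)

    def rpkm_max(self) -> pd.Series:
        """Maximum per-sample RPKM across all samples, per feature."""
        return self.rpkm_matrix().max(axis=1)


class EvidenceTable:
    """Boolean coding-evidence verdicts from external tools (CPC, CNCI,
    BLASTX vs SwissProt, Pfam), each at the tools' E <= 1e-3 cutoff.

    A transcript absent from the table carries no evidence of coding: all
    flags default to False.
    """

    FLAGS = ("cpc_coding", "cnci_coding", "blastx_hit", "pfam_hit")

    def __init__(self, table: pd.DataFrame) -> None:
        for col in self.FLAGS:
            if col not in table.columns:
                raise ValueError(f"evidence table missing column {col}")
        self.table = table[list(self.FLAGS)].astype(bool)

    def flags(self, transcript_id: str) -> dict[str, bool]:
        if transcript_id in self.table.index:
            return self.table.loc[transcript_id].to_dict()
        return {col: False for col in self.FLAGS}


@dataclass
class GOAnnotation:
    """Gene -> set of GO term IDs, with term ID -> (name, namespace)."""

    gene_terms: dict[str, set[str]]
    term_info: dict[str, tuple[str, str]] = field(default_factory=dict)

    def orphan_terms(self) -> set[str]:
        used = set().union(*self.gene_terms.values()) if self.gene_terms else set()
        return used - set(self.term_info)

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    Only ``exon`` features are consumed; each must carry ``transcript_id``
    and ``gene_id`` attributes.  Coordinates are kept 1-based inclusive.
    Malformed lines raise :class:`GtfParseError` with the line number.
    """
    path = Path(path)
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from None
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id"
                )
            rec = per_tx.get(tid)
            if rec is None:
                per_tx[tid] = rec = {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "biotype": attr.get("biotype", "candidate"),
                }
                order.append(tid)
            elif rec["chrom"] != chrom or rec["strand"] != strand:
                raise GtfParseError(
                    f"{path}:{lineno}: transcript {tid} switches "
                    "chromosome or strand between exons"
                )
            rec["exons"].append((start_i, end_i))

    ann = Annotation()
    for tid in order:
        rec = per_tx[tid]
        ann.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                biotype=rec["biotype"],
            )
        )
    if not ann.transcripts:
        logger.warning("read_gtf: no exon features found in %s", path)
    return ann


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write exon lines sorted by (chrom, start); the class label is carried
    as a ``biotype`` transcript attribute, GTF2.2 quoting."""
    lines = []
    for t in annotation:
        for s, e in t.exons:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'biotype "{t.biotype}";'
            )
            lines.append((t.chrom, s, e, t.strand, attrs))
    lines.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, s, e, strand, attrs in lines:
            fh.write(
                f"{chrom}\tlncscape\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """chrom -> uppercase sequence; duplicate headers are an error."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def chrom_sizes(genome: Mapping[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# tabular formats (all tab-separated text)
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, n_columns: int | None = None, **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], **kwargs)
    if n_columns is not None and df.shape[1] != n_columns:
        raise ValueError(
            f"{path}: expected {n_columns} columns, found {df.shape[1]}"
        )
    return df


def read_te_bed(path: str | Path) -> IntervalTrack:
    """BED3+label: chrom, start, end (0-based half-open), TE class label."""
    df = _read_tsv(path, header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: TE BED needs 4 columns (chrom,start,end,label)")
    records = [
        (str(r[0]), int(r[1]), int(r[2]), str(r[3]))
        for r in df.itertuples(index=False)
    ]
    return IntervalTrack(records)


def write_te_bed(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in track.records:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_expression_table(
    counts_path: str | Path,
    groups_path: str | Path,
    lengths_path: str | Path,
    library_sizes_path: str | Path | None = None,
) -> ExpressionTable:
    """Counts TSV (feature rows x sample columns), sample->group map TSV
    (columns sample, group) and feature-length TSV (columns feature, length)."""
    counts = _read_tsv(counts_path, index_col=0)
    groups = _read_tsv(groups_path)
    lengths = _read_tsv(lengths_path)
    sample_groups = dict(zip(groups.iloc[:, 0].astype(str), groups.iloc[:, 1].astype(str)))
    feature_lengths = pd.Series(
        lengths.iloc[:, 1].values, index=lengths.iloc[:, 0].astype(str), dtype=float
    )
    library_sizes = None
    if library_sizes_path is not None:
        lib = _read_tsv(library_sizes_path)
        library_sizes = pd.Series(
            lib.iloc[:, 1].values, index=lib.iloc[:, 0].astype(str), dtype=float
        )
    return ExpressionTable(counts, feature_lengths, sample_groups, library_sizes)


def read_evidence_table(path: str | Path) -> EvidenceTable:
    """TSV with columns transcript_id, cpc_coding, cnci_coding, blastx_hit,
    pfam_hit; truth values parsed from {0,1,true,false} case-insensitively."""
    df = _read_tsv(path, index_col=0)

    def to_bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in {"1", "true", "yes"}
        return bool(v)

    return EvidenceTable(df.map(to_bool))


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """BLAST outfmt-6 (12 columns) into a typed DataFrame."""
    df = _read_tsv(path, header=None, n_columns=12)
    df.columns = BLAST_OUTFMT6_COLUMNS
    df["evalue"] = df["evalue"].astype(float)
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-value")
    return df


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Columns: gene_a, gene_b, group_id (OrthoMCL-style 1:1 pairs)."""
    df = _read_tsv(path)
    df.columns = ["gene_a", "gene_b", "group_id"]
    for col in ("gene_a", "gene_b"):
        dup = df[col][df[col].duplicated()]
        if not dup.empty:
            raise ValueError(
                f"{path}: gene {dup.iloc[0]!r} appears in more than one group"
            )
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Columns: feature_id, log2fc, pvalue, padj; 'NA'/'' parse as missing."""
    df = _read_tsv(path)
    df.columns = ["feature_id", "log2fc", "pvalue", "padj"][: df.shape[1]]
    df["log2fc"] = df["log2fc"].astype(float)
    return df


def read_go_annotations(
    path: str | Path, terms_path: str | Path | None = None
) -> GOAnnotation:
    """gene<TAB>term;term;...  plus optional term table (id, name, namespace)."""
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, _, terms = line.partition("\t")
            gene_terms[gene] = {t for t in terms.split(";") if t}
    term_info: dict[str, tuple[str, str]] = {}
    if terms_path is not None:
        tdf = _read_tsv(terms_path)
        for row in tdf.itertuples(index=False):
            term_info[str(row[0])] = (str(row[1]), str(row[2]))
    ann = GOAnnotation(gene_terms, term_info)
    orphans = ann.orphan_terms()
    if term_info and orphans:
        logger.warning("GO annotation: %d orphan terms without names", len(orphans))
    return ann
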