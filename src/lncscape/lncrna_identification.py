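"""The lncRNA filter cascade.

Transcripts that classified as intergenic ('u'), intronic ('i') or
antisense ('x') pass through six criteria in order:

a) length >= 200 nt and at least two exons;
b) no coding potential called by either CPC or CNCI;
c) longest predicted ORF < 300 nt;
d) no significant BLASTX hit against SwissProt (E <= 1e-3);
e) no significant Pfam domain hit (E <= 1e-3);
f) RPKM_max >= 1.0 across all samples.

Survivors are partitioned by their class code: u -> lincRNA, i -> ilncRNA,
x -> lncNAT.  Because criteria b-e are independent predicates, permuting
them changes per-stage counts but never the final set.

ORF convention: an ORF starts at an ATG in any forward frame; its length
includes the stop codon when one is present, and a stop-less ORF extends to
the last complete codon and is still counted.  This is deliberately
conservative toward discarding possibly-coding fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .context_classifier import CANDIDATE_CODES, ClassCode
from .io_formats import EvidenceTable, ExpressionTable, TranscriptModel

logger = logging.getLogger("lncscape")

__all__ = [
    "FilterCriteria",
    "LncRNARecord",
    "FilterReport",
    "CLASS_NAMES",
    "round_half_up",
    "longest_orf",
    "spliced_sequence",
    "apply_filter_cascade",
    "summarize_composition",
]

#: bijection from retained class codes to lncRNA class names
CLASS_NAMES = {
    ClassCode.U_INTERGENIC: "lincRNA",
    ClassCode.I_INTRONIC: "ilncRNA",
    ClassCode.X_ANTISENSE: "lncNAT",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class FilterCriteria:
    min_length_nt: int = 200
    min_exons: int = 2
    max_orf_nt: int = 300
    min_rpkm_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_length_nt, self.min_exons, self.max_orf_nt) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_rpkm_max <= 0:
            raise ValueError("min_rpkm_max must be positive")


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    lnc_class: str  # lincRNA | ilncRNA | lncNAT
    provenance: dict[str, bool]
    rpkm_max: float


@dataclass
class FilterReport:
    """Ordered survivor accounting: (stage name, input count, surviving)."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and n_in != self.stages[-1][2]:
            raise ValueError("cascade stages must chain survivor counts")
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (2.675 -> 2.68), as used for every printed
    percentage in the reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def longest_orf(transcript_seq: str) -> int:
    """Length in nt of the longest ORF in the three forward frames.

    An ORF opens at ATG; it closes at the first in-frame stop (length
    includes the stop codon) or, lacking one, at the last complete codon of
    the frame.  Returns 0 when no ATG exists.
    """
    seq = transcript_seq.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                best = max(best, pos + 3 - start)
                start = None
            pos += 3
        if start is not None:  # stop-less ORF: extend to last complete codon
            best = max(best, pos - start)
    return best


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Exon sequences concatenated 5'->3' (reverse-complemented on '-')."""
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise ValueError(
            f"{t.transcript_id}: exon end {t.end} beyond {t.chrom} "
            f"length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[s - 1:e] for s, e in t.exons)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def apply_filter_cascade(
    transcripts: Iterable[TranscriptModel],
    codes: Mapping[str, ClassCode],
    genome: Mapping[str, str],
    evidence: EvidenceTable,
    expression: ExpressionTable,
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[LncRNARecord], FilterReport]:
    """Run criteria a-f over the classified candidates.

    ``transcripts`` must already be restricted to codes u/i/x (others raise).
    A transcript missing from the expression table is treated as
    RPKM_max = 0 and fails (f), with a warning.
    """
    candidates = list(transcripts)
    for t in candidates:
        if codes[t.transcript_id] not in CANDIDATE_CODES:
            raise ValueError(
                f"{t.transcript_id}: code {codes[t.transcript_id]} is not a "
                "lncRNA candidate code"
            )

    rpkm_max = expression.rpkm_max()
    missing = [t.transcript_id for t in candidates
               if t.transcript_id not in rpkm_max.index]
    if missing:
        logger.warning(
            "apply_filter_cascade: %d transcripts missing from expression "
            "table, treated as RPKM_max = 0: %s",
            len(missing), ", ".join(missing[:10]),
        )

    provenance: dict[str, dict[str, bool]] = {}

    def run_stage(pool, name, predicate, report):
        survivors = []
        for t in pool:
            ok = predicate(t)
            provenance.setdefault(t.transcript_id, {})[name] = ok
            if ok:
                survivors.append(t)
        report.record(name, len(pool), len(survivors))
        return survivors

    report = FilterReport()
    pool = candidates
    pool = run_stage(
        pool, "a_length_exons",
        lambda t: t.exonic_length >= criteria.min_length_nt
        and t.n_exons >= criteria.min_exons,
        report,
    )
    pool = run_stage(
        pool, "b_cpc_cnci",
        lambda t: not evidence.flags(t.transcript_id)["cpc_coding"]
        and not evidence.flags(t.transcript_id)["cnci_coding"],
        report,
    )
    pool = run_stage(
        pool, "c_orf",
        lambda t: longest_orf(spliced_sequence(t, genome)) < criteria.max_orf_nt,
        report,
    )
    pool = run_stage(
        pool, "d_blastx",
        lambda t: not evidence.flags(t.transcript_id)["blastx_hit"],
        report,
    )
    pool = run_stage(
        pool, "e_pfam",
        lambda t: not evidence.flags(t.transcript_id)["pfam_hit"],
        report,
    )
    pool = run_stage(
        pool, "f_rpkm_max",
        lambda t: float(rpkm_max.get(t.transcript_id, 0.0)) >= criteria.min_rpkm_max,
        report,
    )

    records = []
    for t in pool:
        cls = CLASS_NAMES[codes[t.transcript_id]]
        t.biotype = cls
        records.append(
            LncRNARecord(
                transcript=t,
                lnc_class=cls,
                provenance=provenance[t.transcript_id],
                rpkm_max=float(rpkm_max.get(t.transcript_id, 0.0)),
            )
        )
    return records, report


def summarize_composition(records: Iterable[LncRNARecord]) -> pd.DataFrame:
    """Counts, distinct loci and round-half-up percentages per lncRNA class."""
    records = list(records)
    if not records:
        return pd.DataFrame(columns=["count", "loci", "pct"])
    classes = sorted({r.lnc_class for r in records})
    total = len(records)
    rows = []
    for cls in classes:
        sub = [r for r in records if r.lnc_class == cls]
        rows.append({
            "count": len(sub),
            "loci": len({r.transcript.gene_id for r in sub}),
            "pct": round_half_up(100.0 * len(sub) / total, 2),
        })
    return pd.DataFrame(rows, index=pd.Index(classes, name="class"))
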