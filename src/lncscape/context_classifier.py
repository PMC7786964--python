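"""Genomic-context class codes for assembled transcripts.

Each novel transcript is compared against the reference annotation and
assigned exactly one code, with gffcompare-style semantics reduced to the
four outcomes the lncRNA cascade needs:

* ``SENSE_OVERLAP`` — any same-strand exonic overlap with a reference
  transcript (collapses '=', 'j', 'c', 'o', ...); excluded downstream.
* ``X_ANTISENSE`` ('x') — exonic overlap with a reference transcript on the
  opposite strand.
* ``I_INTRONIC`` ('i') — span fully contained within a single intron of a
  reference transcript (either strand, once exonic overlap is ruled out).
* ``U_INTERGENIC`` ('u') — none of the above.

Precedence is sense overlap > antisense overlap > intron containment >
intergenic, so the partition is total and the three retained codes are
mutually exclusive.
"""

from __future__ import annotations

import enum
import logging

import pandas as pd

from .io_formats import Annotation, TranscriptModel

logger = logging.getLogger("lncscape")

__all__ = [
    "ClassCode",
    "ClassificationError",
    "exonic_overlap_bp",
    "intron_containment",
    "assign_class_code",
    "classify_transcripts",
]


class ClassCode(enum.Enum):
    SENSE_OVERLAP = "sense"   # excluded downstream
    X_ANTISENSE = "x"
    I_INTRONIC = "i"
    U_INTERGENIC = "u"

    @property
    def letter(self) -> str:
        return self.value


#: codes that proceed to lncRNA candidacy
CANDIDATE_CODES = {ClassCode.U_INTERGENIC, ClassCode.I_INTRONIC, ClassCode.X_ANTISENSE}


class ClassificationError(ValueError):
    pass


def exonic_overlap_bp(a: TranscriptModel, b: TranscriptModel) -> int:
    """Total base pairs shared between any exon of ``a`` and any exon of
    ``b``; 0 when the transcripts sit on different chromosomes or share
    only intronic sequence."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def intron_containment(t: TranscriptModel, ref: TranscriptModel) -> bool:
    """True iff ``t``'s span lies entirely within a single intron of
    ``ref``.  Single-exon references have no introns and return False."""
    if t.chrom != ref.chrom:
        return False
    ts, te = t.span
    return any(s <= ts and te <= e for s, e in ref.introns)


def assign_class_code(novel: TranscriptModel, reference: Annotation) -> ClassCode:
    """Assign the genomic-context code of ``novel`` against ``reference``.

    Raises :class:`ClassificationError` for unstranded transcripts (the
    codes are strand-defined).
    """
    if novel.strand not in {"+", "-"}:
        raise ClassificationError(
            f"{novel.transcript_id}: unresolved strand {novel.strand!r}"
        )
    hits = reference.overlapping(novel.chrom, novel.start, novel.end)
    antisense = False
    for ref in hits:
        if exonic_overlap_bp(novel, ref) > 0:
            if ref.strand == novel.strand:
                return ClassCode.SENSE_OVERLAP
            antisense = True
    if antisense:
        return ClassCode.X_ANTISENSE
    # intron containment tested against either strand after exonic overlap
    # has been excluded, so it cannot collide with 'x'
    if any(intron_containment(novel, ref) for ref in hits):
        return ClassCode.I_INTRONIC
    return ClassCode.U_INTERGENIC


def classify_transcripts(novel: Annotation, reference: Annotation) -> pd.DataFrame:
    """Classify every stranded transcript in ``novel``.

    Returns a DataFrame indexed by transcript_id with a ``code`` column
    (ClassCode values).  Unstranded transcripts are excluded and logged.
    """
    rows = {}
    excluded = []
    for t in novel:
        try:
            rows[t.transcript_id] = assign_class_code(t, reference)
        except ClassificationError:
            excluded.append(t.transcript_id)
    if excluded:
        logger.warning(
            "classify_transcripts: excluded %d unstranded transcripts: %s",
            len(excluded), ", ".join(excluded[:10]),
        )
    df = pd.DataFrame({"code": pd.Series(rows, dtype=object)})
    df.index.name = "transcript_id"
    return df
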