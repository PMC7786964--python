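"""Neighbour-pair analysis: lncRNA-PCG (and PCG-PCG control) pairs within
10 kb, expression correlation, cis-candidate calling and GO enrichment of
partner genes.

A pair is emitted when the gap between the two feature spans is <= 10 kb
(inclusive) or the spans intersect; overlapping pairs carry distance 0 and
an orientation stratum (same / opposite transcription direction).  Pearson
correlation uses replicate-averaged group-mean RPKM over all groups; a
|PCC| strictly greater than 0.5 flags a cis-regulatory candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats as st

from .io_formats import GOAnnotation
from .expression_specificity import ExpressionProfile
from .stat_tests import TestResult, bh_adjust, wilcoxon_rank_sum

__all__ = [
    "GenePair",
    "find_neighbors",
    "pearson_pair",
    "correlate_pairs",
    "call_cis_candidates",
    "compare_strata",
    "go_enrichment",
    "STRATA",
]

STRATA = ("all", "overlapping", "non-overlapping",
          "overlapping-same", "overlapping-opposite")


@dataclass
class GenePair:
    anchor_id: str
    partner_id: str
    distance: int          # span gap in bp; 0 if overlapping
    overlapping: bool
    orientation: str       # "same" | "opposite"
    pcc: float = float("nan")
    pcc_p: float = float("nan")

    def in_stratum(self, stratum: str) -> bool:
        if stratum == "all":
            return True
        if stratum == "overlapping":
            return self.overlapping
        if stratum == "non-overlapping":
            return not self.overlapping
        if stratum == "overlapping-same":
            return self.overlapping and self.orientation == "same"
        if stratum == "overlapping-opposite":
            return self.overlapping and self.orientation == "opposite"
        raise ValueError(f"unknown stratum {stratum!r}")


def find_neighbors(
    anchors: pd.DataFrame,
    pcgs: pd.DataFrame,
    max_dist: int = 10_000,
) -> list[GenePair]:
    """All (anchor, PCG) pairs with span gap <= ``max_dist`` or overlap.

    ``anchors`` and ``pcgs`` are gene-span tables indexed by feature id
    with columns chrom, start, end, strand (as from
    :meth:`Annotation.gene_spans`).  Self-pairs (same id) are excluded so
    PCG-PCG control runs can reuse the function.
    """
    pairs: list[GenePair] = []
    by_chrom = {c: df.sort_values("start") for c, df in pcgs.groupby("chrom")}
    for anchor_id, arow in anchors.iterrows():
        chrom_pcgs = by_chrom.get(arow["chrom"])
        if chrom_pcgs is None:
            continue
        a_start, a_end = int(arow["start"]), int(arow["end"])
        # window prefilter on sorted starts: nothing starting before
        # a_start - max_dist - longest gene can reach the anchor
        starts = chrom_pcgs["start"].to_numpy()
        ends = chrom_pcgs["end"].to_numpy()
        max_len = int((ends - starts).max()) + 1
        lo = int(np.searchsorted(starts, a_start - max_dist - max_len))
        for partner_id, prow in chrom_pcgs.iloc[lo:].iterrows():
            g_start, g_end = int(prow["start"]), int(prow["end"])
            if g_start > a_end + max_dist + 1:
                break
            if partner_id == anchor_id:
                continue
            overlap = g_start <= a_end and a_start <= g_end
            # distance = intervening bases between the two spans
            gap = 0 if overlap else max(g_start - a_end, a_start - g_end) - 1
            if gap > max_dist:
                continue
            pairs.append(GenePair(
                anchor_id=str(anchor_id),
                partner_id=str(partner_id),
                distance=gap,
                overlapping=overlap,
                orientation="same" if arow["strand"] == prow["strand"]
                else "opposite",
            ))
    return pairs


def pearson_pair(x, y) -> tuple[float, float]:
    """Product-moment correlation of two expression vectors with two-sided
    p from the t distribution (n-2 df); (NaN, NaN) when either vector has
    zero variance (the pair is then excluded from distributions)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_pair: need equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_pairs(
    pairs: Iterable[GenePair], profile: ExpressionProfile
) -> list[GenePair]:
    """Fill pcc/pcc_p for every pair whose two features are in the profile;
    pairs missing a feature keep NaN."""
    values = profile.values
    for pair in pairs:
        if pair.anchor_id in values.index and pair.partner_id in values.index:
            pair.pcc, pair.pcc_p = pearson_pair(
                values.loc[pair.anchor_id], values.loc[pair.partner_id]
            )
    return list(pairs)


def call_cis_candidates(
    pairs: Iterable[GenePair], threshold: float = 0.5
) -> tuple[list[GenePair], int, int]:
    """Pairs with |PCC| strictly > threshold, plus positive/negative sign
    tallies."""
    candidates = [
        p for p in pairs if not np.isnan(p.pcc) and abs(p.pcc) > threshold
    ]
    n_pos = sum(1 for p in candidates if p.pcc > 0)
    n_neg = sum(1 for p in candidates if p.pcc < 0)
    return candidates, n_pos, n_neg


def compare_strata(
    lnc_pairs: Iterable[GenePair],
    pcg_pairs: Iterable[GenePair],
    strata: Iterable[str] = STRATA,
) -> dict[str, TestResult]:
    """Two-tailed Wilcoxon rank-sum of lncRNA-coding vs coding-coding PCC
    distributions per stratum; empty strata are skipped."""
    lnc_pairs = list(lnc_pairs)
    pcg_pairs = list(pcg_pairs)
    out: dict[str, TestResult] = {}
    for stratum in strata:
        x = [p.pcc for p in lnc_pairs
             if p.in_stratum(stratum) and not np.isnan(p.pcc)]
        y = [p.pcc for p in pcg_pairs
             if p.in_stratum(stratum) and not np.isnan(p.pcc)]
        if not x or not y:
            continue
        out[stratum] = wilcoxon_rank_sum(x, y)
    return out


def go_enrichment(
    query_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: GOAnnotation,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation per GO term with BH correction.

    For a term carried by K of N background genes and k of n query genes,
    p = sum_{j>=k} C(K,j) C(N-K, n-j) / C(N,n).  Terms absent from the
    background are skipped; q < ``q_cutoff`` marks significance.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    term_background: dict[str, set[str]] = {}
    for gene in background:
        for term in annotations.gene_terms.get(gene, ()):
            term_background.setdefault(term, set()).add(gene)
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for term, carriers in sorted(term_background.items()):
        k = len(query & carriers)
        K = len(carriers)
        p = float(st.hypergeom.sf(k - 1, n_bg, K, n_query))
        name, namespace = annotations.term_info.get(term, ("", ""))
        rows.append({
            "term": term, "name": name, "namespace": namespace,
            "k": k, "n": n_query, "K": K, "N": n_bg, "p": min(p, 1.0),
        })
    result = pd.DataFrame(
        rows, columns=["term", "name", "namespace", "k", "n", "K", "N", "p"]
    )
    if not result.empty:
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] < q_cutoff
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    return result
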