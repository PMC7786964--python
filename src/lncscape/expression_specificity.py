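"""Expression normalisation and tissue-specificity scoring.

RPKM = 1e9 * C / (N * L).  Replicates are averaged within their group and
specificity is scored on the resulting gene x group matrix of mean RPKM:

* JS specificity score: the gene's profile is normalised to a probability
  vector p; for each group t, JSD(p, delta_t) is the Jensen-Shannon
  divergence (base-2 entropy) between p and the one-hot indicator of t;
  the score is max_t [1 - sqrt(JSD(p, delta_t))], in [0, 1], 1 for
  single-group expression.
* tau index: with x_i normalised to the profile maximum,
  tau = sum_i (1 - x_i/max) / (n - 1); 0 for uniform, 1 for one-hot.

Both are computed on linear mean RPKM by default (``log_transform`` applies
log2(x+1) first, an option the tau benchmark literature often uses).
Expression tiers follow RPKM_max: low < 5.0 <= moderate < 50.0 <= high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable
from .stat_tests import TestResult, ks_two_sample

__all__ = [
    "ExpressionProfile",
    "rpkm",
    "average_replicates",
    "js_specificity",
    "tau",
    "assign_tiers",
    "score_profiles",
    "compare_specificity",
    "call_highly_specific",
    "TIER_MODERATE_RPKM",
    "TIER_HIGH_RPKM",
]

TIER_MODERATE_RPKM = 5.0
TIER_HIGH_RPKM = 50.0


@dataclass
class ExpressionProfile:
    """Gene x group matrix of replicate-averaged RPKM with a fixed group
    order."""

    values: pd.DataFrame  # gene x group, mean RPKM

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative mean RPKM")

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def rpkm(count: float, library_size: float, exon_length: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if library_size <= 0 or exon_length <= 0:
        raise ValueError("library size and exon length must be positive")
    if count < 0:
        raise ValueError("negative read count")
    return 1e9 * count / (library_size * exon_length)


def average_replicates(
    table: ExpressionTable, group_order: list[str] | None = None
) -> ExpressionProfile:
    """Arithmetic mean of per-sample RPKM within each group.

    ``group_order`` fixes the column order; default is first appearance in
    the sample map.
    """
    rpkm_mat = table.rpkm_matrix()
    groups = pd.Series({s: table.sample_groups[s] for s in rpkm_mat.columns})
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    missing = [g for g in group_order if g not in set(groups)]
    if missing:
        raise ValueError(f"groups with zero samples: {missing}")
    means = rpkm_mat.T.groupby(groups).mean().T
    return ExpressionProfile(means[group_order])


def _entropy2(p: np.ndarray) -> float:
    """Base-2 Shannon entropy with 0 log 0 = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_specificity(profile_row) -> float:
    """max_t [1 - sqrt(JSD(p, delta_t))] over groups t; NaN on all-zero rows."""
    x = np.asarray(profile_row, dtype=float)
    total = x.sum()
    if total <= 0:
        return float("nan")
    p = x / total
    hp = _entropy2(p)
    best = -np.inf
    for t in range(x.size):
        m = p / 2.0
        m[t] += 0.5
        jsd = _entropy2(m) - hp / 2.0  # H(delta_t) = 0
        m[t] -= 0.5
        jsd = max(jsd, 0.0)  # guard tiny negative round-off
        best = max(best, 1.0 - np.sqrt(jsd))
    return float(best)


def tau(profile_row) -> float:
    """sum_i (1 - x_i/max) / (n-1); NaN on all-zero rows; needs n >= 2."""
    x = np.asarray(profile_row, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least two groups")
    m = x.max()
    if m <= 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def assign_tiers(rpkm_max: pd.Series) -> pd.Series:
    """low: RPKM_max < 5.0; moderate: 5.0 <= RPKM_max < 50.0; high: >= 50.0."""
    return pd.Series(
        np.where(rpkm_max >= TIER_HIGH_RPKM, "high",
                 np.where(rpkm_max >= TIER_MODERATE_RPKM, "moderate", "low")),
        index=rpkm_max.index,
    )


def score_profiles(
    profile: ExpressionProfile, log_transform: bool = False
) -> pd.DataFrame:
    """Per-gene js_score, tau, tissue_of_max, rpkm_max and tier.

    All-zero genes score NaN on both indices and are excluded from any
    downstream distribution comparison.
    """
    values = profile.values
    if values.shape[1] < 2:
        raise ValueError("specificity scoring needs at least two groups")
    scored = np.log2(values + 1.0) if log_transform else values
    js = scored.apply(js_specificity, axis=1, raw=True)
    taus = scored.apply(tau, axis=1, raw=True)
    rmax = values.max(axis=1)
    out = pd.DataFrame({
        "js_score": js,
        "tau": taus,
        "tissue_of_max": values.idxmax(axis=1).where(rmax > 0),
        "rpkm_max": rmax,
        "tier": assign_tiers(rmax),
    })
    out.index.name = "gene_id"
    return out


def compare_specificity(scores_a, scores_b) -> TestResult:
    """Two-sample two-sided KS test between two specificity-score vectors
    (NaN entries dropped)."""
    a = pd.Series(scores_a).dropna().to_numpy()
    b = pd.Series(scores_b).dropna().to_numpy()
    return ks_two_sample(a, b)


def call_highly_specific(
    scores: pd.DataFrame, js_threshold: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes with js_score >= threshold, plus a tissue x tier breakdown.

    Returns (subset of the score table, tally table with per-tissue counts
    split by expression tier).
    """
    hits = scores[scores["js_score"] >= js_threshold]
    tally = (
        hits.groupby(["tissue_of_max", "tier"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return hits, tally
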