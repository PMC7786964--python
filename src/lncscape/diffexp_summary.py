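"""Sex-bias calling on externally produced differential-expression tables.

A feature is differentially expressed when |log2 fold-change| >= 1.0 and
the adjusted p-value is < 0.05 (the inclusive fold-change boundary is the
default; ``strict_log2fc`` switches to a strict > comparison).  Rows whose
adjusted p is missing are excluded.  Orientation matters: ``up`` is biased
toward whichever level the comparison's numerator represents (testis, for
the testis-vs-ovary contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stat_tests import TestResult, fisher_exact_2x2

__all__ = ["BiasCallConfig", "call_biased", "sex_bias_fisher"]


@dataclass(frozen=True)
class BiasCallConfig:
    min_abs_log2fc: float = 1.0
    max_padj: float = 0.05
    strict_log2fc: bool = False  # Results-section "> 1" variant
    male_level: str = "numerator"  # which side of the contrast is "male"

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_padj <= 0:
            raise ValueError("thresholds must be positive")


def call_biased(
    de: pd.DataFrame, cfg: BiasCallConfig = BiasCallConfig()
) -> tuple[set[str], set[str]]:
    """(up set, down set) of feature_ids under the significance rule."""
    usable = de[de["padj"].notna()]
    sig = usable[usable["padj"] < cfg.max_padj]
    if cfg.strict_log2fc:
        up = sig[sig["log2fc"] > cfg.min_abs_log2fc]
        down = sig[sig["log2fc"] < -cfg.min_abs_log2fc]
    else:
        up = sig[sig["log2fc"] >= cfg.min_abs_log2fc]
        down = sig[sig["log2fc"] <= -cfg.min_abs_log2fc]
    return set(up["feature_id"]), set(down["feature_id"])


def sex_bias_fisher(
    pcg_male: int, pcg_female: int, lnc_male: int, lnc_female: int
) -> tuple[float, TestResult]:
    """Is the male:female ratio of biased lncRNAs enriched relative to PCGs?

    Conditional hypergeometric two-sided Fisher test on
    [[pcg_male, pcg_female], [lnc_male, lnc_female]]; zero margins give
    p = 1 by convention.  Returns (odds ratio ad/bc, TestResult).
    """
    counts = (pcg_male, pcg_female, lnc_male, lnc_female)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    result = fisher_exact_2x2(
        [[pcg_male, pcg_female], [lnc_male, lnc_female]]
    )
    return result.statistic, result
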