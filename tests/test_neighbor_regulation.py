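import math
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from lncscape.io_formats import GOAnnotation
from lncscape.expression_specificity import ExpressionProfile
from lncscape.neighbor_regulation import (
    GenePair,
    call_cis_candidates,
    compare_strata,
    correlate_pairs,
    find_neighbors,
    go_enrichment,
    pearson_pair,
)
from lncscape.stat_tests import bh_adjust
from lncscape.synthetic_data import simulate_correlated_profiles


def spans(rows):
    df = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])
    return df.set_index("id")


class TestFindNeighbors:
    def test_gap_boundaries_inclusive_at_max_dist(self):
        anchors = spans([("a", "c1", 1000, 2000, "+")])
        for gap, expected in [(9_999, True), (10_000, True), (10_001, False)]:
            pcgs = spans([("g", "c1", 2000 + gap + 1, 2000 + gap + 500, "+")])
            pairs = find_neighbors(anchors, pcgs)
            assert bool(pairs) is expected, gap
            if pairs:
                assert pairs[0].distance == gap

    def test_nested_features_overlap_distance_zero(self):
        anchors = spans([("a", "c1", 1000, 5000, "+")])
        pcgs = spans([("g", "c1", 2000, 3000, "-")])
        (pair,) = find_neighbors(anchors, pcgs)
        assert pair.overlapping and pair.distance == 0
        assert pair.orientation == "opposite"

    def test_self_pairing_excluded_for_controls(self):
        pcgs = spans([("g1", "c1", 1000, 2000, "+"),
                      ("g2", "c1", 3000, 4000, "+")])
        pairs = find_neighbors(pcgs, pcgs)
        assert {(p.anchor_id, p.partner_id) for p in pairs} == \
            {("g1", "g2"), ("g2", "g1")}

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(61)
        rows_a, rows_p = [], []
        for i in range(50):
            s = int(rng.integers(1, 200_000))
            rows_a.append((f"a{i}", f"c{rng.integers(1, 3)}", s,
                           s + int(rng.integers(100, 3000)),
                           "+" if rng.random() < 0.5 else "-"))
        for i in range(80):
            s = int(rng.integers(1, 200_000))
            rows_p.append((f"g{i}", f"c{rng.integers(1, 3)}", s,
                           s + int(rng.integers(100, 3000)),
                           "+" if rng.random() < 0.5 else "-"))
        anchors, pcgs = spans(rows_a), spans(rows_p)
        pairs = {(p.anchor_id, p.partner_id)
                 for p in find_neighbors(anchors, pcgs)}
        brute = set()
        for aid, a in anchors.iterrows():
            for gid, g in pcgs.iterrows():
                if a["chrom"] != g["chrom"]:
                    continue
                overlap = g["start"] <= a["end"] and a["start"] <= g["end"]
                gap = 0 if overlap else max(g["start"] - a["end"],
                                            a["start"] - g["end"]) - 1
                if gap <= 10_000:
                    brute.add((aid, gid))
        assert pairs == brute


class TestPearsonPair:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_pair(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_pair(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_toy_matches_covariance_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        r, _ = pearson_pair(x, y)
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / math.sqrt(((x - x.mean()) ** 2).sum()
                                * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(r_oracle)

    def test_zero_variance_gives_missing(self):
        r, p = pearson_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)


class TestCisCandidates:
    def _pairs(self, pccs):
        return [GenePair(f"a{i}", f"g{i}", 0, False, "same", pcc=c)
                for i, c in enumerate(pccs)]

    def test_threshold_is_strict(self):
        cands, n_pos, n_neg = call_cis_candidates(
            self._pairs([0.5, 0.51, -0.61, float("nan")])
        )
        assert len(cands) == 2
        assert (n_pos, n_neg) == (1, 1)

    def test_counts_match_scan_oracle(self):
        rng = np.random.default_rng(67)
        pccs = rng.uniform(-1, 1, size=200)
        cands, n_pos, n_neg = call_cis_candidates(self._pairs(pccs))
        assert len(cands) == int((np.abs(pccs) > 0.5).sum())
        assert n_pos == int((pccs > 0.5).sum())
        assert n_neg == int((pccs < -0.5).sum())


class TestCompareStrata:
    def _pairs(self, pccs, overlapping=False, orientation="same"):
        return [GenePair(f"a{i}", f"g{i}", 0, overlapping, orientation, pcc=c)
                for i, c in enumerate(pccs)]

    def test_identical_distributions_p_one(self):
        res = compare_strata(self._pairs([0.2, 0.4]), self._pairs([0.2, 0.4]))
        assert res["all"].p_value == pytest.approx(1.0)

    def test_exact_toy_enumeration(self):
        res = compare_strata(self._pairs([0.1, 0.2]), self._pairs([0.3, 0.4]))
        assert res["all"].p_value == pytest.approx(1 / 3)

    def test_empty_stratum_skipped(self):
        res = compare_strata(
            self._pairs([0.1, 0.2], overlapping=False),
            self._pairs([0.3, 0.4], overlapping=False),
        )
        assert "overlapping" not in res
        assert "non-overlapping" in res

    def test_strata_are_filters_on_overlap_and_orientation(self):
        lnc = (self._pairs([0.9, 0.8], True, "opposite")
               + self._pairs([0.0, 0.1], True, "same"))
        pcg = (self._pairs([0.1, 0.2], True, "opposite")
               + self._pairs([0.0, 0.1], True, "same"))
        res = compare_strata(lnc, pcg)
        assert set(res) >= {"all", "overlapping", "overlapping-same",
                            "overlapping-opposite"}
        # the opposite-direction stratum carries the planted difference
        assert res["overlapping-opposite"].p_value <= \
            res["overlapping-same"].p_value


class TestCorrelatePairs:
    def test_fills_pcc_from_group_means(self):
        values = pd.DataFrame(
            {"g1": [1.0, 2.0], "g2": [2.0, 4.0], "g3": [3.0, 6.0]},
            index=["a", "b"],
        )
        pairs = [GenePair("a", "b", 100, False, "same")]
        correlate_pairs(pairs, ExpressionProfile(values))
        assert pairs[0].pcc == pytest.approx(1.0)

    def test_missing_feature_keeps_nan(self):
        values = pd.DataFrame({"g1": [1.0]}, index=["a"])
        pairs = [GenePair("a", "zzz", 100, False, "same")]
        correlate_pairs(pairs, ExpressionProfile(values))
        assert math.isnan(pairs[0].pcc)


class TestGoEnrichment:
    def _annotation(self, carriers, background):
        gene_terms = {g: {"GO:1"} if g in carriers else {"GO:2"}
                      for g in background}
        return GOAnnotation(gene_terms, {"GO:1": ("term one", "BP"),
                                         "GO:2": ("term two", "BP")})

    def test_perfect_concentration_hypergeometric_p(self):
        background = [f"g{i}" for i in range(100)]
        carriers = set(background[:5])
        ann = self._annotation(carriers, background)
        res = go_enrichment(sorted(carriers), background, ann)
        p1 = res.set_index("term").loc["GO:1", "p"]
        assert p1 == pytest.approx(1 / comb(100, 5))

    def test_query_equals_background_every_p_one(self):
        background = [f"g{i}" for i in range(30)]
        ann = self._annotation(set(background[:10]), background)
        res = go_enrichment(background, background, ann)
        assert np.allclose(res["p"], 1.0)

    def test_single_tested_term_q_equals_p(self):
        background = [f"g{i}" for i in range(20)]
        ann = GOAnnotation({g: {"GO:1"} for g in background}, {})
        res = go_enrichment(background[:5], background, ann)
        assert res.loc[0, "q"] == pytest.approx(res.loc[0, "p"])

    def test_query_outside_background_rejected(self):
        ann = GOAnnotation({"g1": {"GO:1"}}, {})
        with pytest.raises(ValueError, match="subset"):
            go_enrichment(["alien"], ["g1"], ann)

    def test_bh_q_values_respect_step_up(self):
        background = [f"g{i}" for i in range(60)]
        rng = np.random.default_rng(71)
        gene_terms = {g: {f"GO:{rng.integers(0, 8)}"} for g in background}
        ann = GOAnnotation(gene_terms, {})
        res = go_enrichment(background[:15], background, ann)
        assert (res["q"] >= res["p"] - 1e-12).all()
        # q is non-decreasing in p-rank order
        ordered = res.sort_values("p")["q"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_planted_term_ranks_first_on_fixture(self, bundle):
        truth = bundle.truth
        background = sorted(bundle.go.gene_terms)
        res = go_enrichment(sorted(truth.designated_go_genes), background,
                            bundle.go)
        assert res.iloc[0]["term"] == truth.planted_go_term
        assert res.iloc[0]["significant"]


class TestPlantedCorrelationRecovery:
    def test_rho_08_pairs_recovered_and_independent_pairs_rejected(self):
        corr = simulate_correlated_profiles(200, 0.8, seed=3)
        rate = np.mean([abs(pearson_pair(x, y)[0]) > 0.5 for x, y in corr])
        assert rate >= 0.8
        indep = simulate_correlated_profiles(200, 0.0, seed=4)
        false_rate = np.mean(
            [abs(pearson_pair(x, y)[0]) > 0.5 for x, y in indep])
        assert false_rate <= 0.1

    def test_bundle_level_pairs_recovered(self, bundle, pipeline_results):
        truth = bundle.truth
        cis = {(p.anchor_id, p.partner_id)
               for p in pipeline_results["neighbors"]["cis"]}
        planted = {k for k, rho in truth.pair_rho.items() if rho > 0}
        indep = {k for k, rho in truth.pair_rho.items() if rho == 0}
        # the fixture plants only a handful of genome-level pairs and adds
        # count noise on top of the profiles, so the integration bar is
        # looser than the 200-pair profile-level recovery above
        assert len(cis & planted) / len(planted) >= 0.75
        assert len(cis & indep) / len(indep) <= 0.25
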