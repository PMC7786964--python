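import numpy as np
import pandas as pd
import pytest

from lncscape.conservation_synteny import (
    Neighborhood,
    build_families,
    build_neighborhood,
    find_synteny_families,
    relative_decrease,
    summarize_blast,
    syntenic_pair,
)
from lncscape.io_formats import Annotation
from conftest import tx


def hits_frame(rows):
    df = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue"])
    for col in ["pident", "length", "mismatch", "gapopen", "qstart", "qend",
                "sstart", "send", "bitscore"]:
        df[col] = 0
    return df


class TestSummarizeBlast:
    def test_query_with_many_hits_counts_once(self):
        hits = hits_frame([("q1", "s1", 1e-5), ("q1", "s2", 1e-7),
                           ("q1", "s3", 1e-9)])
        s = summarize_blast(hits, 1e-3)
        assert s.n_query_with_hit == 1
        assert s.n_target_hit == 3

    def test_all_hits_above_cutoff_counts_zero(self):
        hits = hits_frame([("q1", "s1", 1e-2)])
        assert summarize_blast(hits, 1e-3).n_query_with_hit == 0

    def test_mixed_table_matches_set_oracle(self):
        rng = np.random.default_rng(43)
        rows = [(f"q{rng.integers(0, 20)}", f"s{rng.integers(0, 15)}",
                 float(10.0 ** -rng.integers(0, 14))) for _ in range(200)]
        hits = hits_frame(rows)
        for cutoff in (1e-3, 1e-10):
            s = summarize_blast(hits, cutoff)
            assert s.n_query_with_hit == len(
                {q for q, _s, e in rows if e <= cutoff})
            assert s.n_target_hit == len(
                {t for _q, t, e in rows if e <= cutoff})

    def test_strict_counts_never_exceed_loose(self):
        rng = np.random.default_rng(47)
        rows = [(f"q{i}", f"s{i % 5}", float(10.0 ** -rng.integers(0, 14)))
                for i in range(80)]
        hits = hits_frame(rows)
        loose, strict = summarize_blast(hits, 1e-3), summarize_blast(hits, 1e-10)
        assert strict.n_query_with_hit <= loose.n_query_with_hit
        assert strict.n_target_hit <= loose.n_target_hit

    def test_unknown_query_warned_and_counted(self, caplog):
        hits = hits_frame([("mystery", "s1", 1e-6)])
        with caplog.at_level("WARNING", logger="lncscape"):
            s = summarize_blast(hits, 1e-3, query_ids={"q1"})
        assert s.n_query_with_hit == 1
        assert "not in the query set" in caplog.text


class TestRelativeDecrease:
    @pytest.mark.parametrize("loose,strict,expected", [
        (15, 11, 26.67),   # D. melanogaster genome-hit column
        (74, 58, 21.62),   # B. mori lncRNA-hit column
        (8, 0, 100.00),
        (7, 7, 0.00),
    ])
    def test_published_style_values(self, loose, strict, expected):
        assert relative_decrease(loose, strict) == expected

    def test_zero_loose_is_missing(self):
        assert relative_decrease(0, 0) is None

    def test_increase_rejected(self):
        with pytest.raises(ValueError):
            relative_decrease(5, 6)


def _chain_annotation(gene_ids, chrom="c1", pitch=1000):
    transcripts = []
    for i, gid in enumerate(gene_ids):
        start = 1000 + i * pitch
        transcripts.append(tx(f"{gid}.t", gene=gid, chrom=chrom,
                              exons=[(start, start + 400)]))
    return Annotation(transcripts)


class TestBuildNeighborhood:
    def test_three_nearest_each_side_nearest_first(self):
        ann = _chain_annotation([f"g{i}" for i in range(1, 7)])
        # locus between g3 (starts 3000) and g4 (starts 4000)
        n = build_neighborhood("L", "c1", 3500, 3600, ann, k=3)
        assert n.left == ["g3", "g2", "g1"]
        assert n.right == ["g4", "g5", "g6"]

    def test_before_first_gene_left_empty(self):
        ann = _chain_annotation(["g1", "g2"])
        n = build_neighborhood("L", "c1", 10, 50, ann)
        assert n.left == [] and n.right == ["g1", "g2"]

    def test_overlapping_gene_assigned_by_midpoint(self):
        ann = _chain_annotation(["g1", "g2", "g3"])
        # locus overlapping g2 (span 2000-2400), locus midpoint right of g2's
        n = build_neighborhood("L", "c1", 2300, 3000, ann, k=3)
        assert "g2" in n.left
        n2 = build_neighborhood("L", "c1", 1500, 2100, ann, k=3)
        assert "g2" in n2.right

    def test_absent_chromosome_empty(self):
        ann = _chain_annotation(["g1"])
        n = build_neighborhood("L", "cX", 10, 20, ann)
        assert n.left == [] and n.right == []


def one_to_one(genes_a, genes_b):
    m_a = {g: f"OG{i}" for i, g in enumerate(genes_a)}
    m_b = {g: f"OG{i}" for i, g in enumerate(genes_b)}
    return m_a, m_b


class TestSyntenicPair:
    def test_identical_flanking_order_accepted_with_six_shared(self):
        na = Neighborhood("a", "c", ["a3", "a2", "a1"], ["a4", "a5", "a6"])
        nb = Neighborhood("b", "c", ["b3", "b2", "b1"], ["b4", "b5", "b6"])
        ga, gb = one_to_one(["a1", "a2", "a3", "a4", "a5", "a6"],
                            ["b1", "b2", "b3", "b4", "b5", "b6"])
        ok, shared, _ = syntenic_pair(na, nb, ga, gb)
        assert ok and len(shared) == 6

    def test_two_orthologous_flankers_rejected(self):
        na = Neighborhood("a", "c", ["a1"], ["a2"])
        nb = Neighborhood("b", "c", ["b1"], ["b2"])
        ga, gb = one_to_one(["a1", "a2"], ["b1", "b2"])
        ok, shared, _ = syntenic_pair(na, nb, ga, gb)
        assert not ok and len(shared) == 2

    def test_three_shared_all_on_one_side_rejected(self):
        na = Neighborhood("a", "c", ["a1", "a2", "a3"], ["a4"])
        nb = Neighborhood("b", "c", ["b1", "b2", "b3"], ["b9"])
        ga, gb = one_to_one(["a1", "a2", "a3"], ["b1", "b2", "b3"])
        ok, shared, _ = syntenic_pair(na, nb, ga, gb)
        assert not ok and len(shared) == 3

    def test_tandem_duplication_counted_once(self):
        # two left genes of A in the same ortholog group
        na = Neighborhood("a", "c", ["a1", "a1b"], ["a2", "a3"])
        nb = Neighborhood("b", "c", ["b1"], ["b2", "b3"])
        ga = {"a1": "OG1", "a1b": "OG1", "a2": "OG2", "a3": "OG3"}
        gb = {"b1": "OG1", "b2": "OG2", "b3": "OG3"}
        ok, shared, _ = syntenic_pair(na, nb, ga, gb)
        assert ok and len(shared) == 3

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            ga = {f"a{i}": f"OG{rng.integers(0, 8)}" for i in range(6)}
            gb = {f"b{i}": f"OG{rng.integers(0, 8)}" for i in range(6)}
            na = Neighborhood("a", "c", ["a0", "a1", "a2"], ["a3", "a4", "a5"])
            nb = Neighborhood("b", "c", ["b0", "b1", "b2"], ["b3", "b4", "b5"])
            fwd = syntenic_pair(na, nb, ga, gb)
            rev = syntenic_pair(nb, na, gb, ga)
            assert fwd[0] == rev[0] and fwd[1] == rev[1]

    def test_inversion_relaxation_flag(self):
        # all shared flankers on one side of B: strict rejects, the
        # inversion relaxation (side support in one species) accepts
        na = Neighborhood("a", "c", ["a1", "a2"], ["a3", "a4"])
        nb = Neighborhood("b", "c", ["b1", "b2", "b3"], [])
        ga, gb = one_to_one(["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"])
        ok_strict, shared, _ = syntenic_pair(na, nb, ga, gb)
        ok_inv, _, _ = syntenic_pair(na, nb, ga, gb, allow_inversion=True)
        assert len(shared) == 3
        assert not ok_strict and ok_inv


class TestBuildFamilies:
    def test_shared_locus_merges_family(self):
        pairs = [(("A", "A1"), ("B", "B1"), {"OG1", "OG2", "OG3"}),
                 (("A", "A2"), ("B", "B1"), {"OG1", "OG2", "OG4"})]
        families = build_families(pairs)
        assert len(families) == 1
        assert families[0].members == {"A": {"A1", "A2"}, "B": {"B1"}}
        assert families[0].supporting_groups == {"OG1", "OG2", "OG3", "OG4"}

    def test_disjoint_pairs_two_families(self):
        pairs = [(("A", "A1"), ("B", "B1"), set()),
                 (("A", "A2"), ("B", "B2"), set())]
        assert len(build_families(pairs)) == 2

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(59)
        for _ in range(10):
            edges = [((("A", f"A{rng.integers(0, 12)}"),
                       ("B", f"B{rng.integers(0, 12)}"), set()))
                     for _ in range(15)]
            families = build_families(edges)
            # brute-force transitive closure
            parent = {}

            def find(x):
                parent.setdefault(x, x)
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v, _s in edges:
                parent[find(u)] = find(v)
            comps = {}
            for u, v, _s in edges:
                for node in (u, v):
                    comps.setdefault(find(node), set()).add(node)
            got = {frozenset(sp + ":" + l for sp, ls in f.members.items()
                             for l in ls) for f in families}
            want = {frozenset(f"{sp}:{l}" for sp, l in comp)
                    for comp in comps.values()}
            assert got == want


class TestPlantedSynteny:
    def test_families_recovered_exactly_on_fixture(self, bundle):
        truth = bundle.truth
        loci_a = {}
        for tid, ok in truth.passes_cascade.items():
            if not ok:
                continue
            t = bundle.candidates[tid]
            loci_a[t.gene_id] = (t.chrom, t.start, t.end)
        families, pairs = find_synteny_families(
            loci_a, bundle.lnc_b_loci, bundle.ref_a, bundle.ref_b,
            bundle.orthologs,
        )
        recovered = {(a, b) for a, b in
                     zip(pairs["locus_a"], pairs["locus_b"])}
        assert recovered == set(truth.family_pairs)
        assert len(families) == len(truth.family_pairs)

    def test_rearranged_and_b_only_loci_form_no_family(self, bundle):
        truth = bundle.truth
        loci_a = {}
        for tid in truth.rearranged_lnc:
            t = bundle.candidates[tid]
            loci_a[t.gene_id] = (t.chrom, t.start, t.end)
        families, _ = find_synteny_families(
            loci_a, bundle.lnc_b_loci, bundle.ref_a, bundle.ref_b,
            bundle.orthologs,
        )
        assert families == []
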