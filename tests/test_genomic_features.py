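import math

import numpy as np
import pytest

from lncscape.genomic_features import (
    chromosome_distribution,
    gc_content,
    size_stats,
    splice_site_context,
    te_class_composition,
    te_overlap,
)
from lncscape.io_formats import Annotation, IntervalTrack
from conftest import tx

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


class TestSizeStats:
    def test_two_exon_transcript(self):
        stats = size_stats([tx(exons=[(1, 100), (201, 400)])])
        assert stats.transcript_lengths.tolist() == [300]
        assert stats.exon_counts.tolist() == [2]
        assert stats.intron_lengths.tolist() == [100]
        assert stats.medians()["transcript_length"] == 300

    def test_pooled_medians_match_sorted_oracle(self):
        rng = np.random.default_rng(31)
        transcripts = []
        all_exons, all_introns = [], []
        pos = 1
        for i in range(40):
            n = int(rng.integers(1, 5))
            exons = []
            for _ in range(n):
                length = int(rng.integers(50, 400))
                exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(50, 300))
            transcripts.append(tx(f"t{i}", exons=exons))
            all_exons += [e - s + 1 for s, e in exons]
            all_introns += [b - a - 1 for (_, a), (b, _)
                            in zip(exons, exons[1:])]
        stats = size_stats(transcripts)
        assert stats.medians()["exon_length"] == \
            sorted(all_exons)[len(all_exons) // 2] \
            if len(all_exons) % 2 else np.median(sorted(all_exons))
        assert np.median(sorted(all_introns)) == \
            stats.medians()["intron_length"]

    def test_intron_count_is_exon_count_minus_one(self):
        stats = size_stats([tx(exons=[(1, 10), (21, 30), (41, 50)])])
        assert stats.intron_lengths.size == stats.exon_counts[0] - 1


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", 50.0), ("GGCC", 100.0), ("NNAT", 0.0), ("acgt", 50.0),
        ("NGC", 100.0),
    ])
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_no_unambiguous_bases_is_missing(self):
        assert math.isnan(gc_content("NNNN"))


class TestSpliceSiteContext:
    def _genome_with_intron(self, intron_seq, strand="+"):
        # exon1 (20 bp) | intron | exon2 (20 bp)
        exon1, exon2 = "A" * 20, "C" * 20
        if strand == "-":
            seq = exon1 + revcomp(intron_seq) + exon2
        else:
            seq = exon1 + intron_seq + exon2
        t = tx("t", strand=strand, exons=[
            (1, 20), (21 + len(intron_seq), 40 + len(intron_seq)),
        ])
        return {"c1": seq}, t

    def test_canonical_intron_on_plus_strand(self):
        genome, t = self._genome_with_intron("GT" + "A" * 26 + "AG")
        donor, acceptor, frac = splice_site_context([t], genome, flank=5)
        assert frac == 1.0
        # first two intronic donor positions are G then T
        assert donor.loc[0, "G"] == 1.0
        assert donor.loc[1, "T"] == 1.0
        assert acceptor.loc[-2, "A"] == 1.0
        assert acceptor.loc[-1, "G"] == 1.0

    def test_minus_strand_intron_reverse_complemented(self):
        genome, t = self._genome_with_intron("GT" + "A" * 26 + "AG",
                                             strand="-")
        donor, acceptor, frac = splice_site_context([t], genome, flank=5)
        assert frac == 1.0
        assert donor.loc[0, "G"] == 1.0 and donor.loc[1, "T"] == 1.0
        assert acceptor.loc[-2, "A"] == 1.0 and acceptor.loc[-1, "G"] == 1.0

    def test_noncanonical_intron_counts_in_fraction(self):
        genome, t = self._genome_with_intron("CT" + "A" * 26 + "AC")
        _, _, frac = splice_site_context([t], genome, flank=5)
        assert frac == 0.0

    def test_frequencies_sum_to_one_per_position(self, bundle):
        transcripts = [t for t in bundle.ref_a][:40]
        donor, acceptor, frac = splice_site_context(
            transcripts, bundle.genome_a, flank=10
        )
        assert np.allclose(donor.sum(axis=1), 1.0)
        assert np.allclose(acceptor.sum(axis=1), 1.0)
        assert frac == 1.0  # planted introns are all canonical

    def test_strand_flip_invariance(self):
        """Reverse-complementing the genome and flipping strands and
        coordinates leaves donor/acceptor matrices unchanged."""
        intron = "GT" + "ACGTTGCA" * 3 + "AG"
        genome, t = self._genome_with_intron(intron)
        n = len(genome["c1"])
        flipped_genome = {"c1": revcomp(genome["c1"])}
        flipped_t = tx("t", strand="-", exons=[
            (n - e + 1, n - s + 1) for s, e in reversed(t.exons)
        ])
        d1, a1, f1 = splice_site_context([t], genome, flank=5)
        d2, a2, f2 = splice_site_context([flipped_t], flipped_genome, flank=5)
        assert np.allclose(d1.values, d2.values)
        assert np.allclose(a1.values, a2.values)
        assert f1 == f2


class TestTeOverlap:
    def test_exon_te_intersection_flags(self):
        lnc = [tx("l1", exons=[(100, 200)])]
        pcg = [tx("p1", exons=[(300, 350), (500, 600)])]
        te = IntervalTrack([("c1", 149, 160, "LINE"),   # inside l1 exon
                            ("c1", 360, 450, "DNA")])   # p1 intron only
        flags_l, flags_p, table, fisher = te_overlap(lnc, te, pcg)
        assert flags_l["l1"] and not flags_p["p1"]
        assert table.tolist() == [[1, 0], [0, 1]]
        assert fisher is not None

    def test_span_mode_counts_intronic_te(self):
        pcg = [tx("p1", exons=[(300, 350), (500, 600)])]
        te = IntervalTrack([("c1", 360, 450, "DNA")])
        _, flags, _, _ = te_overlap([], te, pcg, mode="span")
        assert flags["p1"]

    def test_empty_track_skips_test(self):
        flags_l, flags_p, table, fisher = te_overlap(
            [tx("l1")], IntervalTrack([]), [tx("p1")]
        )
        assert not flags_l.any() and not flags_p.any()
        assert fisher is None

    def test_flags_match_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(37)
        features = []
        for i in range(60):
            start = int(rng.integers(1, 4000))
            features.append(tx(f"f{i}", exons=[
                (start, start + 50), (start + 150, start + 220),
            ]))
        records = []
        for _ in range(40):
            s = int(rng.integers(0, 4200))
            records.append(("c1", s, s + int(rng.integers(5, 120)), "LINE"))
        te = IntervalTrack(records)
        flags, _, _, _ = te_overlap(features, te, [])
        for f in features:
            expect = any(
                s0 + 1 <= e and s <= e0
                for s, e in f.exons
                for _c, s0, e0, _l in te.records
            )
            assert flags[f.transcript_id] == expect

    def test_planted_fractions_recovered_exactly(self, bundle):
        lnc = [bundle.candidates[t]
               for t, ok in bundle.truth.passes_cascade.items() if ok]
        pcg = list(bundle.ref_a)
        flags_l, flags_p, _, fisher = te_overlap(lnc, bundle.te_track, pcg)
        assert flags_l.mean() == pytest.approx(bundle.truth.te_lnc_fraction)
        # PCG flags are per transcript = per gene in the fixture
        assert flags_p.mean() == pytest.approx(bundle.truth.te_pcg_fraction)


class TestTeComposition:
    def test_single_class_is_total(self):
        feats = [tx("f1", exons=[(100, 300)])]
        te = IntervalTrack([("c1", 120, 140, "LINE"), ("c1", 200, 230, "LINE")])
        comp = te_class_composition(feats, te)
        assert comp.loc["LINE", "count"] == 2
        assert comp.loc["LINE", "pct"] == 100.0

    def test_counts_te_records_not_features(self):
        feats = [tx("f1", exons=[(100, 300)])]
        te = IntervalTrack([("c1", 120, 140, "LINE"), ("c1", 200, 230, "DNA")])
        comp = te_class_composition(feats, te)
        assert comp["count"].sum() == 2
        assert comp["pct"].sum() == pytest.approx(100.0, abs=0.02)

    def test_empty_overlaps_give_empty_table(self):
        assert te_class_composition([tx("f1")], IntervalTrack([])).empty


class TestChromosomeDistribution:
    def _reference(self, sizes, pcg_counts):
        transcripts = []
        for chrom, n in pcg_counts.items():
            for i in range(n):
                start = 100 + i * 500
                transcripts.append(tx(f"{chrom}_g{i}", gene=f"{chrom}_g{i}",
                                      chrom=chrom, exons=[(start, start + 99)]))
        return Annotation(transcripts, chrom_sizes=sizes)

    def test_proportional_counts_give_r_of_one(self):
        sizes = {f"c{i}": 1000 * (i + 1) for i in range(5)}
        ref = self._reference(sizes, {c: 2 for c in sizes})
        lnc = []
        for i, c in enumerate(sorted(sizes)):
            for j in range(i + 1):
                lnc.append(tx(f"l{c}_{j}", chrom=c, exons=[(1, 50)]))
        _, corr = chromosome_distribution(lnc, ref)
        assert corr["vs_chrom_size"][0] == pytest.approx(1.0)

    def test_r_matches_covariance_formula_on_toy(self):
        sizes = {"c1": 1000, "c2": 3000, "c3": 2000, "c4": 5000, "c5": 2500}
        ref = self._reference(sizes, {c: 1 for c in sizes})
        counts = {"c1": 2, "c2": 5, "c3": 1, "c4": 9, "c5": 4}
        lnc = [tx(f"l{c}_{j}", chrom=c, exons=[(1, 50)])
               for c in sizes for j in range(counts[c])]
        table, corr = chromosome_distribution(lnc, ref)
        x = np.array([counts[c] for c in sorted(sizes)], dtype=float)
        y = np.array([sizes[c] for c in sorted(sizes)], dtype=float)
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert corr["vs_chrom_size"][0] == pytest.approx(r_oracle)

    def test_too_few_chromosomes_skips_correlations(self):
        ref = self._reference({"c1": 1000, "c2": 2000}, {"c1": 1, "c2": 1})
        _, corr = chromosome_distribution([tx("l1", chrom="c1")], ref)
        assert corr == {}
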