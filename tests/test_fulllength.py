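"""Three-stage full-length classification, family clustering, uniqueness."""

import pandas as pd
import pytest

from orfeome import synthetic
from orfeome.align import AlignmentHit
from orfeome.fulllength import (
    FlThresholds,
    FullLengthCall,
    analysis_one,
    analysis_three,
    analysis_two,
    cluster_families,
    mean_cds_length,
    unique_fulllength,
)
from orfeome.orf import OrfCall
from orfeome.synthetic import ContigProfile


def _ann(rows):
    return pd.DataFrame(rows, columns=["gene_id", "species", "utr5_len", "cds_len", "utr3_len"])


def _hit(q, s, pid=100.0, qs=1, qe=100, ss=1, se=100, bits=200.0, ev=1e-50):
    alen = qe - qs + 1
    return AlignmentHit(q, s, pid, alen, 0, 0, qs, qe, ss, se, ev, bits)


TH = FlThresholds(species_order=("spA", "spB"))


class TestMeanCds:
    def test_two_genes(self):
        ann = _ann([("g1", "spA", 0, 900, 0), ("g2", "spA", 0, 1200, 0)])
        assert mean_cds_length(ann) == 1050.0

    def test_single_gene(self):
        assert mean_cds_length(_ann([("g1", "spA", 0, 1031, 0)])) == 1031.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_cds_length(_ann([]))

    def test_matches_annotation_table_reaverage(self, small_refset):
        ann = synthetic.annotation_table(small_refset)
        assert mean_cds_length(small_refset) == pytest.approx(ann["cds_len"].mean())


class TestAnalysisOne:
    # one gene: 100 bp 5'UTR, 300 bp CDS (span 101-400), 100 bp 3'UTR
    ANN = _ann([("g1", "spA", 100, 300, 100)])

    def test_noiseless_full_cover_called(self):
        hits = [_hit("c1", "g1", qs=1, qe=500, ss=1, se=500)]
        calls, used_c, used_g = analysis_one(hits, self.ANN, {"c1": 500}, TH)
        assert len(calls) == 1
        assert calls[0].analysis == "I" and calls[0].contig_ids == ("c1",)
        assert used_c == {"c1"} and used_g == {"g1"}

    def test_94_percent_cds_coverage_not_called(self):
        # covers CDS bases 101..382 = 282/300 = 94%
        hits = [_hit("c1", "g1", qs=1, qe=382, ss=1, se=382)]
        calls, _, _ = analysis_one(hits, self.ANN, {"c1": 400}, TH)
        assert calls == []

    def test_low_identity_or_contig_coverage_rejected(self):
        h = _hit("c1", "g1", pid=79.9, qs=1, qe=500, ss=1, se=500)
        assert analysis_one([h], self.ANN, {"c1": 500}, TH)[0] == []
        # only 500 of 1200 contig bases aligned: 41.7% < 50%
        h2 = _hit("c2", "g1", qs=1, qe=500, ss=1, se=500)
        assert analysis_one([h2], self.ANN, {"c2": 1200}, TH)[0] == []

    def test_evalue_gate(self):
        h = _hit("c1", "g1", qs=1, qe=500, ss=1, se=500, ev=1e-10)
        assert analysis_one([h], self.ANN, {"c1": 500}, TH)[0] == []

    def test_strongest_contig_claims_gene(self):
        hits = [
            _hit("weak", "g1", pid=90.0, qs=1, qe=500, ss=1, se=500, bits=900.0),
            _hit("strong", "g1", qs=1, qe=500, ss=1, se=500, bits=1000.0),
        ]
        calls, used_c, _ = analysis_one(hits, self.ANN, {"weak": 500, "strong": 500}, TH)
        assert len(calls) == 1 and calls[0].contig_ids == ("strong",)
        assert used_c == {"strong"}

    def test_toy_table_matches_rule_enumeration(self):
        ann = _ann([("g1", "spA", 0, 300, 0), ("g2", "spA", 0, 300, 0), ("g3", "spB", 0, 300, 0)])
        lens = {f"c{i}": 300 for i in range(1, 6)}
        hits = [
            _hit("c1", "g1", qs=1, qe=300, ss=1, se=300, bits=600),   # qualifies g1
            _hit("c2", "g1", qs=1, qe=300, ss=1, se=300, bits=500),   # g1 taken by c1
            _hit("c2", "g2", qs=1, qe=300, ss=1, se=290, bits=400),   # 96.7% cov, qualifies
            _hit("c3", "g3", qs=1, qe=300, ss=1, se=300, bits=600),   # spB qualifies
            _hit("c4", "g2", qs=1, qe=150, ss=1, se=150, bits=300),   # 50% CDS cov only
            _hit("c5", "g3", pid=75.0, qs=1, qe=300, ss=1, se=300, bits=200),  # low identity
        ]
        calls, used_c, used_g = analysis_one(hits, ann, lens, TH)
        got = {(c.contig_ids[0], c.gene_id) for c in calls}
        # by hand: in spA, c1's first hit is g1 (claimed, best bits); c2's
        # first hit is also g1, already claimed, so c2 is not called — it
        # does not fall back to g2.  In spB, c3->g3.  c4 fails gene
        # coverage, c5 fails identity.
        assert got == {("c1", "g1"), ("c3", "g3")}
        assert used_g == {"g1", "g3"}
        assert used_c == {"c1", "c3"}


class TestAnalysisTwo:
    ANN = _ann([("g1", "spA", 100, 300, 100)])

    def test_three_nonoverlapping_pieces_called(self):
        hits = [
            _hit("p1", "g1", qs=1, qe=180, ss=1, se=180),
            _hit("p2", "g1", qs=1, qe=180, ss=181, se=360),
            _hit("p3", "g1", qs=1, qe=140, ss=361, se=500),
        ]
        lens = {"p1": 180, "p2": 180, "p3": 140}
        calls, used_c, used_g = analysis_two(hits, self.ANN, lens, thresholds=TH)
        assert len(calls) == 1
        call = calls[0]
        assert call.analysis == "II" and set(call.contig_ids) == {"p1", "p2", "p3"}
        assert call.coverage_fraction == 1.0

    def test_union_60_percent_not_called(self):
        # CDS is 101..400 (300 bp); pieces cover CDS units [1,150] and [118,180]
        hits = [
            _hit("p1", "g1", qs=1, qe=150, ss=101, se=250),
            _hit("p2", "g1", qs=1, qe=63, ss=218, se=280),
        ]
        calls, _, _ = analysis_two(hits, self.ANN, {"p1": 150, "p2": 63}, thresholds=TH)
        assert calls == []

    def test_single_contig_not_enough(self):
        hits = [_hit("p1", "g1", qs=1, qe=500, ss=1, se=500)]
        calls, _, _ = analysis_two(hits, self.ANN, {"p1": 500}, thresholds=TH)
        assert calls == []

    def test_consumed_inputs_excluded(self):
        hits = [
            _hit("p1", "g1", qs=1, qe=250, ss=1, se=250),
            _hit("p2", "g1", qs=1, qe=250, ss=251, se=500),
        ]
        lens = {"p1": 250, "p2": 250}
        calls, _, _ = analysis_two(hits, self.ANN, lens, consumed_genes={"g1"}, thresholds=TH)
        assert calls == []
        calls, _, _ = analysis_two(hits, self.ANN, lens, consumed_contigs={"p2"}, thresholds=TH)
        assert calls == []

    def test_planted_fragment_recovery_with_contig_mean(self, small_refset):
        profile = ContigProfile(substitution_rate=0.0)
        contigs, truth = synthetic.generate_contigs(small_refset, profile, seed=13)
        fwd, _ = synthetic.emit_truth_hit_tables(small_refset, contigs, truth)
        ann = synthetic.annotation_table(small_refset)
        lens = {c: len(s) for c, s in contigs.items()}
        order = tuple(ann["species"].unique())
        th = FlThresholds(species_order=order)
        calls1, used_c, used_g = analysis_one(fwd, ann, lens, th)
        calls2, _, _ = analysis_two(fwd, ann, lens, used_c, used_g, th)
        frag_truth: dict[str, set] = {}
        for t in truth:
            if t.truth_class.startswith("fragment"):
                frag_truth.setdefault(t.origin_gene, set()).add(t.contig_id)
        assert {c.gene_id for c in calls2} == set(frag_truth)
        for c in calls2:
            assert set(c.contig_ids) == frag_truth[c.gene_id]
        got_mean = sum(len(c.contig_ids) for c in calls2) / len(calls2)
        true_mean = sum(len(v) for v in frag_truth.values()) / len(frag_truth)
        assert got_mean == pytest.approx(true_mean)


class TestAnalysisThree:
    def _call(self, n, start=True, stop=True):
        return OrfCall("c", "+", 0, 1, n, start, stop, 10.0, "M" * (n // 3 - 1))

    def test_strictly_greater_than_mean(self):
        calls = analysis_three(["c"], {"c": self._call(1031)}, 1031.0)
        assert calls == []
        (call,) = analysis_three(["c"], {"c": self._call(1200)}, 1030.85)
        assert call.analysis == "III" and call.gene_id is None

    def test_incomplete_orf_rejected(self):
        assert analysis_three(["c"], {"c": self._call(2000, stop=False)}, 1030.85) == []
        assert analysis_three(["c"], {"c": self._call(2000, start=False)}, 1030.85) == []
        assert analysis_three(["c"], {"c": None}, 1030.85) == []


class TestClusterFamilies:
    def test_identical_proteins_one_cluster(self):
        clusters = cluster_families({"a": "MKLV" * 50, "b": "MKLV" * 50})
        assert len(clusters) == 1
        assert set(clusters[0].members) == {"a", "b"}

    def test_unrelated_proteins_stay_separate(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=200))
        b = "".join(rng.choice(aas, size=200))
        clusters = cluster_families({"a": a, "b": b})
        assert len(clusters) == 2

    def test_representative_is_longest_member(self):
        base = "MKLVANQRST" * 30
        clusters = cluster_families({"short": base[:250], "long": base})
        (cl,) = clusters
        assert cl.representative == "long"

    def test_deterministic_under_permutation(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        prots = {f"p{i}": "".join(rng.choice(aas, size=150)) for i in range(6)}
        prots["p0b"] = prots["p0"]
        a = cluster_families(prots)
        b = cluster_families(dict(reversed(list(prots.items()))))
        assert [c.members for c in a] == [c.members for c in b]

    def test_planted_variant_groups_recovered(self, small_refset):
        from orfeome.orf import translate

        profile = ContigProfile(
            frac_fulllength=0.0, frac_fragmented=0.0, frac_specific=0.0,
            frac_variant=0.5, n_variants_per_gene=3, variant_rate=0.02,
        )
        contigs, truth = synthetic.generate_contigs(small_refset, profile, seed=55)
        by_gene = {g.gene_id: g for g in small_refset}
        proteins = {}
        for t in truth:
            g = by_gene[t.origin_gene]
            lo, hi = g.cds_interval
            cds = contigs[t.contig_id][lo - 1 : hi]
            # variant proteins via direct translation of the planted CDS window
            proteins[t.contig_id] = translate(cds).replace("*", "K")
        clusters = cluster_families(proteins)
        planted_genes = {t.origin_gene for t in truth}
        assert len(clusters) == len(planted_genes)


class TestUniqueFulllength:
    def _cluster(self, cid, members):
        from orfeome.fulllength import FamilyCluster

        return FamilyCluster(cid, tuple(members), members[0])

    def test_three_calls_one_cluster(self):
        calls = [FullLengthCall("I", (f"c{i}",), f"g{i}", "spA", 1.0, 100.0) for i in range(3)]
        clusters = [self._cluster("k", ["c0", "c1", "c2"])]
        s = unique_fulllength(calls, clusters)
        assert s["total_unique"] == 1
        assert s["unique"] == {"I": 1, "II": 0, "III": 0}

    def test_disjoint_singletons(self):
        calls = [FullLengthCall("III", (f"c{i}",), None, None, 1.0, 100.0) for i in range(4)]
        clusters = [self._cluster(f"k{i}", [f"c{i}"]) for i in range(4)]
        assert unique_fulllength(calls, clusters)["total_unique"] == 4

    def test_total_is_sum_of_per_analysis_uniques(self):
        # the published-scale arithmetic: 9,410 + 3,952 + 4,201 = 17,563
        assert 9410 + 3952 + 4201 == 17563
        calls = (
            [FullLengthCall("I", (f"a{i}",), f"gI{i}", "spA", 1.0, 100.0) for i in range(3)]
            + [FullLengthCall("II", (f"b{i}", f"b{i}x"), f"gII{i}", "spA", 1.0, 100.0)
               for i in range(2)]
            + [FullLengthCall("III", (f"d{i}",), None, None, 1.0, 100.0) for i in range(2)]
        )
        clusters = [self._cluster(f"ka{i}", [f"a{i}"]) for i in range(3)]
        clusters += [self._cluster(f"kb{i}", [f"gII{i}"]) for i in range(2)]
        # one Analysis-III contig collapses into an Analysis-I family
        clusters += [self._cluster("kd0", ["d0"])]
        clusters[0] = self._cluster("ka0", ["a0", "d1"])
        s = unique_fulllength(calls, clusters)
        assert s["unique"] == {"I": 3, "II": 2, "III": 1}
        assert s["total_unique"] == 6
        assert s["raw_calls"]["III"] == 2  # raw count exceeds collapsed count

    def test_unclustered_protein_rejected(self):
        calls = [FullLengthCall("I", ("c0",), "g0", "spA", 1.0, 100.0)]
        with pytest.raises(ValueError):
            unique_fulllength(calls, [self._cluster("k", ["other"])])


class TestDisjointness:
    def test_contigs_and_genes_appear_once_across_analyses(self, small_refset):
        contigs, truth = synthetic.generate_contigs(
            small_refset, ContigProfile(substitution_rate=0.0), seed=77
        )
        fwd, _ = synthetic.emit_truth_hit_tables(small_refset, contigs, truth)
        ann = synthetic.annotation_table(small_refset)
        lens = {c: len(s) for c, s in contigs.items()}
        th = FlThresholds(species_order=tuple(ann["species"].unique()))
        calls1, used_c, used_g = analysis_one(fwd, ann, lens, th)
        calls2, used_c2, used_g2 = analysis_two(fwd, ann, lens, used_c, used_g, th)
        seen_contigs: set = set()
        for c in calls1 + calls2:
            assert not (set(c.contig_ids) & seen_contigs)
            seen_contigs.update(c.contig_ids)
        genes1 = {c.gene_id for c in calls1}
        genes2 = {c.gene_id for c in calls2}
        assert not genes1 & genes2
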