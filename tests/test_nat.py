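"""Antisense classification, PA score arithmetic, normalisation/clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from orfeome.nat import (
    ANTISENSE,
    IGNORED,
    SENSE,
    PathwayActivityMatrix,
    ReadAlignmentRecord,
    antisense_counts,
    antisense_coverage,
    classify_orientation,
    fulllength_nat_overlap,
    normalize_cluster,
    pathway_activity,
)


def _rec(read="r1", sample="s1", target="t1", strand="-", start=1, end=150):
    return ReadAlignmentRecord(read, sample, target, strand, start, end, end - start + 1)


class TestClassifyOrientation:
    def test_opposite_strand_long_alignment_is_antisense(self):
        assert classify_orientation(_rec(strand="-"), "+") == ANTISENSE
        assert classify_orientation(_rec(strand="+"), "+") == SENSE
        assert classify_orientation(_rec(strand="+"), "-") == ANTISENSE

    def test_99bp_alignment_ignored(self):
        assert classify_orientation(_rec(end=99), "+") == IGNORED
        assert classify_orientation(_rec(end=100), "+") == ANTISENSE

    def test_invalid_reference_strand(self):
        with pytest.raises(ValueError):
            classify_orientation(_rec(), "x")

    def test_global_strand_flip_swaps_totals_exactly(self, rng):
        records = [
            _rec(read=f"r{i}", target=f"t{i % 4}",
                 strand="+" if rng.random() < 0.7 else "-",
                 start=1, end=int(rng.integers(80, 300)))
            for i in range(500)
        ]
        strands = {f"t{i}": "+" for i in range(4)}
        counts, frac = antisense_counts(records, strands)
        flipped = [
            ReadAlignmentRecord(r.read_id, r.sample_id, r.target_id,
                                "+" if r.strand == "-" else "-", r.t_start, r.t_end, r.aln_len)
            for r in records
        ]
        fcounts, ffrac = antisense_counts(flipped, strands)
        assert counts["sense"].sum() == fcounts["antisense"].sum()
        assert counts["antisense"].sum() == fcounts["sense"].sum()
        total = counts.values.sum()
        assert frac * total + ffrac * total == pytest.approx(total)


class TestAntisenseCounts:
    def test_zero_records(self):
        counts, frac = antisense_counts([], {"t1": "+"})
        assert counts.empty and frac == 0.0

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            antisense_counts([_rec(target="nope")], {"t1": "+"})

    def test_published_scale_fraction_arithmetic(self):
        # 1,700,000 antisense of 29,260,184 mapped reads is 5.8%
        assert round(100 * 1_700_000 / 29_260_184, 1) == 5.8


class TestAntisenseCoverage:
    STRANDS = {"t1": "+"}

    def test_single_read_fraction(self):
        cov = antisense_coverage([_rec(start=1, end=100)], self.STRANDS, {"t1": 1000})
        assert cov["t1"] == pytest.approx(10.0)

    def test_overlapping_reads_union(self):
        recs = [_rec(read="a", start=1, end=100), _rec(read="b", start=51, end=150)]
        cov = antisense_coverage(recs, self.STRANDS, {"t1": 1000})
        assert cov["t1"] == pytest.approx(15.0)

    def test_no_antisense_reads(self):
        cov = antisense_coverage([_rec(strand="+")], self.STRANDS, {"t1": 1000})
        assert cov["t1"] == 0.0

    def test_span_outside_target_rejected(self):
        with pytest.raises(ValueError):
            antisense_coverage([_rec(start=950, end=1100)], self.STRANDS, {"t1": 1000})


class TestPathwayActivity:
    def test_complete_detection_is_plain_sum(self):
        intensities = pd.DataFrame({"s1": [2.0, 2.0]}, index=["gA", "gB"])
        pam = pathway_activity(intensities, {"P": {"gA", "gB"}})
        assert pam.scores.loc["P", "s1"] == pytest.approx(4.0)
        assert pam.n_detected.loc["P", "s1"] == 2 and pam.m_total["P"] == 2

    def test_partial_detection_normalised_up(self):
        intensities = pd.DataFrame({"s1": [8.0, 0.0, 0.0, 0.0]},
                                   index=["g1", "g2", "g3", "g4"])
        pam = pathway_activity(intensities, {"P": {"g1", "g2", "g3", "g4"}})
        assert pam.scores.loc["P", "s1"] == pytest.approx(8.0 / (1 / 4))

    def test_linear_in_intensities(self, rng):
        intensities = pd.DataFrame(
            rng.random((6, 3)) * (rng.random((6, 3)) > 0.3),
            index=[f"g{i}" for i in range(6)], columns=list("abc"),
        )
        membership = {"P1": {"g0", "g1", "g2"}, "P2": {"g3", "g4", "g5"}}
        a = pathway_activity(intensities, membership).scores
        b = pathway_activity(intensities * 2, membership).scores
        pd.testing.assert_frame_equal(b, a * 2)

    def test_no_detection_unscored(self):
        intensities = pd.DataFrame({"s1": [0.0]}, index=["g1"])
        pam = pathway_activity(intensities, {"P": {"g1"}})
        assert np.isnan(pam.scores.loc["P", "s1"])

    def test_empty_pathway_rejected(self):
        intensities = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            pathway_activity(intensities, {"P": set()})

    def test_negative_intensity_rejected(self):
        intensities = pd.DataFrame({"s1": [-1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            pathway_activity(intensities, {"P": {"g1"}})


def _pam(values, pathways, samples):
    df = pd.DataFrame(values, index=pathways, columns=samples, dtype=float)
    return PathwayActivityMatrix(
        scores=df, state="raw",
        n_detected=pd.DataFrame(1, index=pathways, columns=samples),
        m_total=pd.Series(1, index=pathways),
    )


def _brute_force_best_k(X):
    """Exhaustively score all 2-partitions against the silhouette index."""
    from sklearn.metrics import silhouette_score

    n = len(X)
    best = (None, -np.inf)
    for mask in range(1, 2 ** (n - 1)):
        labels = [(mask >> i) & 1 for i in range(n)]
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best[1]:
            best = (labels, s)
    return best


class TestNormalizeCluster:
    def test_constant_matrix_centres_to_zero(self):
        pam = _pam(np.full((3, 4), 7.0), list("PQR"), list("abcd"))
        out = normalize_cluster(pam)
        assert (out["matrix"].to_numpy() == 0).all()

    def test_centred_row_medians_zero_and_idempotent(self, rng):
        pam = _pam(rng.random((5, 4)) * 50, [f"p{i}" for i in range(5)], list("abcd"))
        out = normalize_cluster(pam)
        med = out["matrix"].median(axis=1)
        assert np.allclose(med, 0.0)
        recentred = out["matrix"].sub(out["matrix"].median(axis=1), axis=0)
        pd.testing.assert_frame_equal(recentred, out["matrix"])

    def test_identical_pair_coclusters_with_k2(self):
        rows = np.array(
            [[1.0, 2.0, 3.0, 4.0],
             [1.0, 2.0, 3.0, 4.0],
             [40.0, 10.0, 90.0, 5.0]]
        )
        pam = _pam(rows, ["p1", "p2", "far"], list("abcd"))
        out = normalize_cluster(pam)
        assert out["k"] == 2
        labels = out["pathway_clusters"]
        assert labels["p1"] == labels["p2"] != labels["far"]
        # optimum agrees with exhaustive partition scoring
        X = out["matrix"].loc[["p1", "p2", "far"]].to_numpy()
        best_labels, _ = _brute_force_best_k(X)
        grouping = [frozenset(i for i, l in enumerate(best_labels) if l == v)
                    for v in set(best_labels)]
        assert frozenset({0, 1}) in grouping

    def test_dendrograms_invariant_to_row_permutation(self, rng):
        vals = rng.random((6, 4)) * 30
        paths = [f"p{i}" for i in range(6)]
        out1 = normalize_cluster(_pam(vals, paths, list("abcd")))
        perm = rng.permutation(6)
        out2 = normalize_cluster(_pam(vals[perm], [paths[i] for i in perm], list("abcd")))
        import re

        def leafset_distances(newick):
            return sorted(re.findall(r"([A-Za-z0-9_]+):", newick))

        assert leafset_distances(out1["pathway_newick"]) == leafset_distances(out2["pathway_newick"])
        assert out1["k"] == out2["k"]

    def test_single_pathway_skips_clustering(self):
        pam = _pam([[1.0, 2.0]], ["p"], ["a", "b"])
        with pytest.warns(UserWarning):
            out = normalize_cluster(pam)
        assert out["k"] is None


class TestFulllengthNatOverlap:
    def test_full_overlap_included_boundary_excluded(self):
        cov = {"c1": 100.0, "c2": 99.9, "c3": 0.0}
        assert fulllength_nat_overlap(["c1", "c2", "c3"], cov) == ["c1"]

    def test_planted_fully_overlapped_recovered(self):
        # tile a 300 bp contig completely with antisense reads
        recs = [
            _rec(read=f"r{i}", target="c1", start=1 + 100 * i, end=100 * (i + 1))
            for i in range(3)
        ]
        recs.append(_rec(read="partial", target="c2", start=1, end=150))
        cov = antisense_coverage(recs, {"c1": "+", "c2": "+"}, {"c1": 300, "c2": 300})
        assert fulllength_nat_overlap(["c1", "c2"], cov) == ["c1"]
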