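"""Evaluation statistics against hand counts and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from aakmer.evaluate import (
    accuracy_and_coverage,
    agreement,
    keyword_homogeneity,
    multimap_resolution,
    per_cluster_concordance,
    roc_threshold,
)


def assignments_frame(rows):
    """rows: (read_id, cluster_id, score, classified)"""
    return pd.DataFrame(
        [(r, c, s, cl, "") for r, c, s, cl in rows],
        columns=["read_id", "cluster_id", "score", "classified", "annotation"],
    )


def hits_frame(rows):
    """rows: (qseqid, sseqid, pident)"""
    return pd.DataFrame(
        [(q, s, p, 1e-10) for q, s, p in rows],
        columns=["qseqid", "sseqid", "pident", "evalue"],
    )


class TestAccuracyAndCoverage:
    def test_basic_arithmetic(self):
        rows = [(f"r{i}", "C1", 5.0, True) for i in range(8)]
        rows += [(f"r{i}", None, 1.0, False) for i in range(8, 10)]
        truth = pd.DataFrame({"read_id": [f"r{i}" for i in range(10)],
                              "true_cluster": ["C1"] * 10})
        report = accuracy_and_coverage(assignments_frame(rows), truth)
        assert report.accuracy_classified == 1.0
        assert report.coverage == 0.8
        assert report.n_classified == 8

    def test_zero_classified_is_null_accuracy(self):
        rows = [("r0", None, 0.0, False)]
        truth = pd.DataFrame({"read_id": ["r0"], "true_cluster": ["C1"]})
        report = accuracy_and_coverage(assignments_frame(rows), truth)
        assert report.accuracy_classified is None
        assert report.coverage == 0.0

    def test_partial_correctness(self):
        rows = [("r0", "C1", 5.0, True), ("r1", "C2", 5.0, True),
                ("r2", "C1", 5.0, True), ("r3", None, 0.0, False)]
        truth = pd.DataFrame({"read_id": ["r0", "r1", "r2", "r3"],
                              "true_cluster": ["C1", "C1", "C1", "C1"]})
        report = accuracy_and_coverage(assignments_frame(rows), truth)
        assert report.accuracy_classified == pytest.approx(2 / 3)
        assert report.coverage == 0.75

    def test_missing_truth_raises_with_ids(self):
        rows = [("r0", "C1", 5.0, True), ("missing_read", "C1", 5.0, True)]
        truth = pd.DataFrame({"read_id": ["r0"], "true_cluster": ["C1"]})
        with pytest.raises(ValueError, match="missing_read"):
            accuracy_and_coverage(assignments_frame(rows), truth)


class TestMultimapResolution:
    P2C = {"p1": "C1", "p2": "C1", "p3": "C2", "p4": "C2"}

    def test_same_cluster_resolved(self):
        hits = hits_frame([("r1", "p1", 90.0), ("r1", "p2", 85.0)])
        result = multimap_resolution(hits, self.P2C)
        assert result.fraction == 1.0
        assert result.per_read == {"r1": True}

    def test_cross_cluster_unresolved(self):
        hits = hits_frame([("r1", "p1", 90.0), ("r1", "p3", 85.0)])
        assert multimap_resolution(hits, self.P2C).fraction == 0.0

    def test_single_hit_reads_excluded(self):
        hits = hits_frame([("r1", "p1", 90.0), ("r2", "p1", 90.0), ("r2", "p2", 80.0)])
        result = multimap_resolution(hits, self.P2C)
        assert result.n_multi == 1 and "r1" not in result.per_read

    def test_within_cluster_table_fully_resolved(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            cluster = ["p1", "p2"] if i % 2 else ["p3", "p4"]
            for p in cluster:
                rows.append((f"r{i}", p, float(rng.uniform(50, 100))))
        assert multimap_resolution(hits_frame(rows), self.P2C).fraction == 1.0

    def test_nine_of_ten(self):
        rows = []
        for i in range(9):
            rows += [(f"r{i}", "p1", 90.0), (f"r{i}", "p2", 88.0)]
        rows += [("r9", "p1", 90.0), ("r9", "p3", 88.0)]
        assert multimap_resolution(hits_frame(rows), self.P2C).fraction == 0.9

    def test_unmapped_protein_named(self):
        hits = hits_frame([("r1", "p1", 90.0), ("r1", "pX", 85.0)])
        with pytest.raises(ValueError, match="pX"):
            multimap_resolution(hits, self.P2C)


class TestAgreement:
    P2C = {"p1": "C1", "p2": "C1", "p3": "C2"}

    def test_all_agree(self):
        assigns = assignments_frame([("r1", "C1", 9.0, True), ("r2", "C2", 8.0, True)])
        hits = hits_frame([("r1", "p1", 90.0), ("r2", "p3", 90.0)])
        result = agreement(assigns, hits, self.P2C)
        assert result.agreement == 1.0
        assert result.sensitivity == 1.0

    def test_identity_floor_removes_read_from_denominator(self):
        assigns = assignments_frame([("r1", "C1", 9.0, True), ("r2", "C2", 8.0, True)])
        hits = hits_frame([("r1", "p1", 90.0), ("r2", "p3", 40.0)])
        result = agreement(assigns, hits, self.P2C, identity_floor=66.6)
        assert result.n_agree + result.n_disagree == 1
        assert result.agreement == 1.0
        assert result.n_hit_reads == 1

    def test_hand_built_five_read_table(self):
        # r1 agrees (p1 in C1); r2 disagrees (hits only C2); r3 not classified;
        # r4 agrees via second hit; r5 classified but no hits at all.
        assigns = assignments_frame([
            ("r1", "C1", 9.0, True),
            ("r2", "C1", 9.0, True),
            ("r3", None, 1.0, False),
            ("r4", "C2", 7.0, True),
            ("r5", "C1", 6.0, True),
        ])
        hits = hits_frame([
            ("r1", "p1", 90.0),
            ("r2", "p3", 90.0),
            ("r3", "p1", 90.0),
            ("r4", "p1", 90.0), ("r4", "p3", 85.0),
        ])
        result = agreement(assigns, hits, self.P2C)
        # by hand: denominators are r1, r2, r4 -> agree r1, r4
        assert result.n_agree == 2 and result.n_disagree == 1
        assert result.agreement == pytest.approx(2 / 3)
        # hit reads: r1..r4; recovered (classified): r1, r2, r4
        assert result.sensitivity == pytest.approx(3 / 4)

    def test_unmapped_hit_protein_raises(self):
        assigns = assignments_frame([("r1", "C1", 9.0, True)])
        hits = hits_frame([("r1", "pZ", 90.0)])
        with pytest.raises(ValueError, match="pZ"):
            agreement(assigns, hits, self.P2C)


class TestPerClusterConcordance:
    P2C = {"p1": "C1", "p2": "C2"}

    def test_ratio(self):
        assigns = assignments_frame(
            [(f"r{i}", "C1", 9.0, True) for i in range(4)]
        )
        hits = hits_frame([("r0", "p1", 90.0), ("r1", "p1", 90.0),
                           ("r2", "p1", 90.0), ("r3", "p2", 90.0)])
        result = per_cluster_concordance(assigns, hits, self.P2C)
        assert result["C1"] == (4, 0.75)

    def test_all_agreeing(self):
        assigns = assignments_frame([("r0", "C1", 9.0, True), ("r1", "C1", 9.0, True)])
        hits = hits_frame([("r0", "p1", 90.0), ("r1", "p1", 90.0)])
        assert per_cluster_concordance(assigns, hits, self.P2C)["C1"] == (2, 1.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        clusters = [f"C{i}" for i in range(5)]
        p2c = {f"p{i}": clusters[i % 5] for i in range(20)}
        assigns = assignments_frame([
            (f"r{i}", clusters[int(rng.integers(5))], 9.0, True) for i in range(200)
        ])
        hit_rows = []
        for i in range(200):
            for _ in range(int(rng.integers(1, 4))):
                hit_rows.append((f"r{i}", f"p{int(rng.integers(20))}", 90.0))
        hits = hits_frame(hit_rows)
        result = per_cluster_concordance(assigns, hits, p2c)

        # independent recount via plain dict groupby
        hit_clusters = {}
        for q, s, _p in hit_rows:
            hit_clusters.setdefault(q, set()).add(p2c[s])
        by_cluster = {}
        for row in assigns.itertuples(index=False):
            by_cluster.setdefault(row.cluster_id, []).append(
                row.cluster_id in hit_clusters.get(row.read_id, set())
            )
        for cid, flags in by_cluster.items():
            assert result[cid] == (len(flags), sum(flags) / len(flags))


class TestKeywordHomogeneity:
    def test_uniform_names(self):
        results, skipped = keyword_homogeneity({"C1": ["ABC transporter X"] * 4})
        assert skipped == 0
        assert results["C1"].fraction == 1.0

    def test_no_shared_tokens(self):
        results, _ = keyword_homogeneity({"C1": ["alpha kinase", "beta hydrolase"]})
        assert results["C1"].fraction == 0.5

    def test_tie_breaks_lexicographically(self):
        results, _ = keyword_homogeneity({"C1": ["zeta kinase", "zeta kinase"]})
        assert results["C1"].keyword == "kinase"  # kinase < zeta

    def test_stopwords_removed(self):
        results, _ = keyword_homogeneity(
            {"C1": ["hypothetical protein", "hypothetical protein", "kinase protein"]}
        )
        assert results["C1"].keyword not in {"protein", "hypothetical"}

    def test_all_stopword_cluster_skipped(self):
        results, skipped = keyword_homogeneity({"C1": ["protein", "bacteria protein"]})
        assert skipped == 1 and "C1" not in results

    def test_case_and_punctuation_insensitive(self):
        results, _ = keyword_homogeneity({"C1": ["ABC-Transporter.", "abc transporter"]})
        assert results["C1"].fraction == 1.0


def brute_force_auroc(scores, labels):
    """All-pairs comparison with 0.5 credit for ties (independent oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocThreshold:
    def test_perfect_separation(self):
        result = roc_threshold([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert result.auroc == 1.0
        assert result.threshold == 10.0
        assert result.tpr == 1.0

    def test_four_point_worked_case(self):
        result = roc_threshold([1, 2, 3, 4], [0, 1, 0, 1], fpr_cap=0.05)
        assert result.auroc == pytest.approx(0.75)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            n = int(rng.integers(20, 200))
            scores = rng.integers(0, 15, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            result = roc_threshold(scores, labels)
            assert result.auroc == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_null_distribution(self):
        rng = np.random.default_rng(99)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, size=10_000)
        result = roc_threshold(scores, labels)
        assert abs(result.auroc - 0.5) < 0.02

    def test_threshold_respects_fpr_cap(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(0, 1, 500), rng.normal(2, 1, 500)])
        labels = np.concatenate([np.zeros(500, int), np.ones(500, int)])
        result = roc_threshold(scores, labels, fpr_cap=0.05)
        neg = scores[labels == 0]
        assert (neg >= result.threshold).mean() <= 0.05
        # one step down the sorted unique scores would violate the cap
        uniq = np.unique(scores)
        below = uniq[uniq < result.threshold]
        if below.size:
            assert (neg >= below[-1]).mean() > 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold([1.0, 2.0], [1, 1])
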