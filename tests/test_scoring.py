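import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annoclust.clustering import HitCluster, group_by_de, link_by_go
from annoclust.de_processing import ProcessedDe
from annoclust.errors import ConfigurationError
from annoclust.scoring import final_score, rank, sentence_score, word_score

from conftest import make_hit


def pair(sid, bit, de_text):
    return (make_hit(sid, bit, de=de_text), ProcessedDe(tuple(de_text.split()), sid))


def cluster_of(*pairs):
    return HitCluster(members=list(pairs), de_texts=tuple({d.text for _, d in pairs}))


@pytest.fixture
def toy():
    """Two hits 'dna gyrase' (bits 100+50) in one cluster; one other hit (50)."""
    a = pair("S1", 100.0, "dna gyrase")
    b = pair("S2", 50.0, "dna gyrase")
    c = pair("S3", 50.0, "rna ligase")
    return cluster_of(a, b), cluster_of(c), [a[0], b[0], c[0]]


class TestWordAndSentenceScores:
    def test_hand_worked_word_score(self, toy):
        cj, _, all_hits = toy
        assert word_score("dna", cj, all_hits) == pytest.approx(150 / 200)

    def test_absent_word_scores_zero(self, toy):
        cj, _, all_hits = toy
        assert word_score("ligase", cj, all_hits) == 0.0

    def test_single_hit_scores_one(self):
        p = pair("S1", 77.0, "dna gyrase")
        c = cluster_of(p)
        assert word_score("dna", c, [p[0]]) == 1.0
        assert sentence_score("dna gyrase", c, [p[0]]) == 1.0
        assert final_score("dna gyrase", c, [p[0]]) == 1.0

    def test_hand_worked_sentence_score(self, toy):
        cj, _, all_hits = toy
        assert sentence_score("dna gyrase", cj, all_hits) == pytest.approx(0.75)

    def test_empty_hit_list_is_an_error(self, toy):
        cj, _, _ = toy
        with pytest.raises(ConfigurationError):
            word_score("dna", cj, [])


class TestFinalScore:
    def test_hand_worked_two_term_mean(self, toy):
        cj, _, all_hits = toy
        assert final_score("dna gyrase", cj, all_hits) == pytest.approx(0.75)

    def test_shared_word_changes_split(self):
        # equal bits, DEs "a b" and "a c" in one merged cluster:
        # w(a)=1.0, w(b)=0.5, S=0.5 -> final (0.75+0.5)/2 = 0.625
        p1, p2 = pair("S1", 100.0, "a b"), pair("S2", 100.0, "a c")
        c = cluster_of(p1, p2)
        hits = [p1[0], p2[0]]
        assert final_score("a b", c, hits) == pytest.approx(0.625)

    def test_flat_variant(self):
        p1, p2 = pair("S1", 100.0, "a b"), pair("S2", 100.0, "a c")
        c = cluster_of(p1, p2)
        hits = [p1[0], p2[0]]
        # (w(a)+w(b)+S)/3 = (1.0+0.5+0.5)/3
        assert final_score("a b", c, hits, variant="flat") == pytest.approx(2.0 / 3)


class TestRank:
    def test_cluster_order_by_best_description(self, toy):
        cj, ck, all_hits = toy
        report = rank([ck, cj], all_hits, query_id="Q1")
        assert report.best.de_text == "dna gyrase"
        assert [c.best.de_text for c in report.clusters] == ["dna gyrase", "rna ligase"]
        assert report.clusters[0].best.frequency == 2
        assert report.clusters[0].best.bit_sum == pytest.approx(150.0)
        assert report.clusters[0].best.best_hit_id == "S1"

    def test_empty_means_no_prediction(self):
        report = rank([], [], query_id="Q1")
        assert report.no_prediction and report.best is None


def _scored_query(bits, des):
    pairs = [pair(f"S{i}", b, d) for i, (b, d) in enumerate(zip(bits, des))]
    clusters = link_by_go(group_by_de(pairs), {})
    hits = [h for h, _ in pairs]
    return rank(clusters, hits), hits


class TestInvariants:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=40.0, max_value=500.0),
                st.sampled_from(["dna gyrase", "rna ligase", "dna ligase", "gyrase"]),
            ),
            min_size=1,
            max_size=9,
        )
    )
    def test_sentence_scores_sum_to_one_and_finals_in_unit_interval(self, rows):
        bits, des = zip(*rows)
        report, _ = _scored_query(bits, des)
        total_s = sum(d.sentence_score for c in report.clusters for d in c.descriptions)
        assert total_s == pytest.approx(1.0, abs=1e-12)
        for c in report.clusters:
            for d in c.descriptions:
                assert 0.0 < d.final_score <= 1.0

    def test_scores_invariant_under_uniform_bit_rescaling(self):
        bits = [120.0, 90.0, 60.0, 55.0]
        des = ["dna gyrase", "dna gyrase", "rna ligase", "gyrase"]
        base, _ = _scored_query(bits, des)
        scaled, _ = _scored_query([b * 7.5 for b in bits], des)
        for cb, cs in zip(base.clusters, scaled.clusters):
            for db, ds in zip(cb.descriptions, cs.descriptions):
                assert db.final_score == pytest.approx(ds.final_score)

    def test_boosting_a_supporting_hit_never_hurts(self):
        bits = [120.0, 90.0, 60.0]
        des = ["dna gyrase", "rna ligase", "dna gyrase"]
        before, _ = _scored_query(bits, des)

        def score_of(report, text):
            return next(
                d.final_score
                for c in report.clusters
                for d in c.descriptions
                if d.de_text == text
            )

        after, _ = _scored_query([120.0, 90.0, 120.0], des)
        assert score_of(after, "dna gyrase") >= score_of(before, "dna gyrase")

    def test_final_score_one_iff_unanimous(self):
        report, _ = _scored_query([100.0, 50.0], ["dna gyrase", "dna gyrase"])
        assert report.best.final_score == 1.0
        report2, _ = _scored_query([100.0, 50.0], ["dna gyrase", "rna ligase"])
        for c in report2.clusters:
            for d in c.descriptions:
                assert d.final_score < 1.0
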