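import datetime as dt

import numpy as np
import pytest

from annoclust.clustering import group_by_de, link_by_go
from annoclust.de_processing import process_query_hits
from annoclust.errors import ConfigurationError
from annoclust.evaluation import (
    GoldRecord,
    evaluate_methods,
    go_restrict,
    optimal_fractions,
    predict,
    read_gold,
    remove_circular,
    sweep,
    zscore,
)
from annoclust.mld_metric import mld_distance
from annoclust.ontology import GoAnnotation

from conftest import make_hit


def ann(sid, terms):
    return GoAnnotation(sid, frozenset(terms), True)


class TestRemoveCircular:
    def test_date_rule(self):
        cutoff = dt.date(2008, 1, 1)
        same = make_hit("S1", 100, subject_creation_date=cutoff)
        older = make_hit("S2", 100, subject_creation_date=cutoff - dt.timedelta(days=1))
        newer = make_hit("S3", 100, subject_creation_date=cutoff + dt.timedelta(days=9))
        undated = make_hit("S4", 100)
        out = remove_circular([same, older, newer, undated], cutoff)
        assert [h.subject_id for h in out] == ["S2", "S4"]


class TestPredict:
    def test_top_hit_takes_max_bit(self):
        hits = [make_hit("S1", 120, de="a"), make_hit("S2", 90, de="b")]
        assert predict(hits, "top_hit") == "a"

    def test_top_informative_skips_stop_word_descriptions(self):
        hits = [
            make_hit("S1", 120, de="hypothetical protein"),
            make_hit("S2", 90, de="dna gyrase"),
        ]
        assert predict(hits, "top_informative") == "dna gyrase"
        # partial uninformativeness also disqualifies
        hits2 = [
            make_hit("S1", 120, de="putative dna gyrase"),
            make_hit("S2", 90, de="rna ligase"),
        ]
        assert predict(hits2, "top_informative") == "rna ligase"

    def test_most_common(self):
        hits = [
            make_hit("S1", 50, de="a"),
            make_hit("S2", 60, de="a"),
            make_hit("S3", 300, de="b"),
        ]
        assert predict(hits, "most_common") == "a"

    def test_max_bitsum(self):
        hits = [
            make_hit("S1", 50, de="a"),
            make_hit("S2", 60, de="a"),
            make_hit("S3", 300, de="b"),
        ]
        assert predict(hits, "max_bitsum") == "b"

    def test_no_hits_gives_none(self):
        assert predict([], "top_hit") is None

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            predict([make_hit("S1", 100)], "oracle")

    def test_tie_break_reproducible_under_seed(self):
        hits = [make_hit("S1", 100, de="a"), make_hit("S2", 100, de="b")]
        picks = {predict(hits, "top_hit", rng=5) for _ in range(5)}
        assert len(picks) == 1

    def test_word_score_pools_shared_words(self):
        # 'dna gyrase' and 'dna ligase' share 'dna'; per-DE frequency ties,
        # but word pooling favours the higher-bit wording
        hits = [
            make_hit("S1", 100, de="dna gyrase"),
            make_hit("S2", 100, de="dna gyrase"),
            make_hit("S3", 110, de="dna ligase"),
        ]
        assert predict(hits, "word_score") == "dna gyrase"


class TestGoRestrict:
    def test_largest_group_wins_at_min_size(self):
        hits = [make_hit(f"S{i}", 100) for i in range(9)]
        annotations = {f"S{i}": ann(f"S{i}", {"a", "b", "c"}) for i in range(6)}
        annotations.update(
            {f"S{i}": ann(f"S{i}", {"a", "b", "d"}) for i in range(6, 9)}
        )
        out = go_restrict(hits, annotations)
        assert sorted(h.subject_id for h in out) == [f"S{i}" for i in range(6)]

    def test_small_largest_group_returns_all(self):
        hits = [make_hit(f"S{i}", 100) for i in range(7)]
        annotations = {f"S{i}": ann(f"S{i}", {"a", "b", "c"}) for i in range(4)}
        annotations.update(
            {f"S{i}": ann(f"S{i}", {"a", "b", "d"}) for i in range(4, 7)}
        )
        assert go_restrict(hits, annotations) == hits

    def test_uniform_annotation_unchanged(self):
        hits = [make_hit(f"S{i}", 100) for i in range(6)]
        annotations = {f"S{i}": ann(f"S{i}", {"a", "b", "c"}) for i in range(6)}
        assert sorted(h.subject_id for h in go_restrict(hits, annotations)) == [
            h.subject_id for h in hits
        ]


class TestZscore:
    def test_hand_worked_value(self):
        # mu 0.5, population sd 0.15 around it
        vals = [0.35, 0.65, 0.35, 0.65]
        assert zscore(0.2, vals) == pytest.approx(2.0)

    def test_at_the_mean_is_zero(self):
        assert zscore(0.5, [0.3, 0.7]) == pytest.approx(0.0)

    def test_degenerate_sigma_excluded(self):
        assert zscore(0.2, [0.5, 0.5, 0.5]) is None


class TestOptimalFractions:
    def _setup(self):
        gold = GoldRecord("Q1", "dna gyrase", None, frozenset({"x", "y", "r"}))
        hits = [
            make_hit("S1", 100, de="dna gyrase"),        # DE optimal
            make_hit("S2", 90, de="gyrase dna"),         # DE optimal (word order)
            make_hit("S3", 80, de="rna ligase"),         # neither
            make_hit("S4", 70, de="helicase"),           # GO optimal only
        ]
        annotations = {"S4": ann("S4", {"x", "y", "r"}), "S3": ann("S3", {"x", "z", "r"})}
        pairs = process_query_hits(hits)
        clusters = link_by_go(group_by_de(pairs), annotations)
        return hits, gold, annotations, clusters

    def test_fraction_arithmetic(self):
        hits, gold, annotations, clusters = self._setup()
        fr = optimal_fractions(hits, gold, annotations, clusters)
        assert fr["de"] == pytest.approx(0.5)
        assert fr["go"] == pytest.approx(0.25)
        assert fr["de_or_go"] == pytest.approx(0.75)
        assert fr["de_and_go"] == 0.0

    def test_no_match_all_zero(self):
        gold = GoldRecord("Q1", "flagellar motor", None, frozenset({"q", "w", "e"}))
        hits = [make_hit("S1", 100, de="rna ligase")]
        fr = optimal_fractions(hits, gold, {}, [])
        assert set(fr.values()) == {0.0}

    def test_cluster_fraction_bounded_by_union_when_premise_holds(self, scenario_data):
        # when every optimally annotated hit lands in one cluster, the
        # clustering criterion extracts at least the DE-or-GO set
        from annoclust.blast_io import filter_hits

        data = scenario_data("synonym-rescue", seed=5)
        for qid, hits in data["by_query"].items():
            kept = filter_hits(hits)
            pairs = process_query_hits(kept)
            clusters = link_by_go(group_by_de(pairs), data["annotations"])
            fr = optimal_fractions(kept, data["gold"][qid], data["annotations"], clusters)
            best = max((len(c.members) for c in clusters), default=0)
            if best and fr["de_or_go"] > 0:
                # premise: the rescued cluster holds all optimal hits
                assert fr["cluster_group"] >= fr["de_or_go"] - 1e-9


class TestSweep:
    def test_structure_and_unfiltered_cell(self, scenario_data):
        data = scenario_data("baseline", n_queries=8)
        df = sweep(data["by_query"], data["gold"])
        assert len(df) == 36
        base = df[(df.identity == 0) & (df.coverage == 0)].iloc[0]
        assert base.n_queries == len(data["by_query"])
        # coverage monotone non-increasing along each threshold axis
        for ti in sorted(df.identity.unique()):
            col = df[df.identity == ti].sort_values("coverage")["n_queries"].tolist()
            assert col == sorted(col, reverse=True)
        for tc in sorted(df.coverage.unique()):
            row = df[df.coverage == tc].sort_values("identity")["n_queries"].tolist()
            assert row == sorted(row, reverse=True)

    def test_zero_cell_matches_manual_statistics(self, scenario_data):
        data = scenario_data("baseline", n_queries=8)
        df = sweep(data["by_query"], data["gold"])
        base = df[(df.identity == 0) & (df.coverage == 0)].iloc[0]
        mins = []
        for qid, hits in data["by_query"].items():
            gold = data["gold"][qid]
            mins.append(min(mld_distance(gold.correct_de, h.raw_de) for h in hits))
        assert base.min_mean == pytest.approx(np.mean(mins))


class TestEvaluateMethods:
    def test_six_method_rows_and_determinism(self, scenario_data, tmp_path):
        data = scenario_data("baseline", n_queries=6)
        kw = dict(
            gold_by_query=data["gold"], annotations=data["annotations"], seed=3
        )
        df1 = evaluate_methods(data["by_query"], **kw)
        df2 = evaluate_methods(data["by_query"], **kw)
        assert len(df1) == 6
        assert df1.equals(df2)
        assert df1.mld_mean.between(0, 1).all()

    def test_predictions_bounded_by_hit_list_extremes(self, scenario_data):
        data = scenario_data("baseline", n_queries=6)
        for qid, hits in data["by_query"].items():
            gold = data["gold"][qid]
            hit_ds = [mld_distance(gold.correct_de, h.raw_de) for h in hits]
            for method in ("top_hit", "most_common", "max_bitsum"):
                de = predict(hits, method, rng=1)
                if de is None:
                    continue
                d = mld_distance(gold.correct_de, de)
                # predictions from processed DEs can only match or degrade
                # relative to the best raw hit DE, and never exceed 1
                assert min(hit_ds) - 1e-9 <= d <= 1.0


class TestReadGold:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "gold.tsv"
        p.write_text(
            "query_id\tcorrect_de\tannotation_date\tgo_terms\n"
            "Q1\tdna gyrase\t2008-01-01\tGO:1|GO:2\n"
            "Q2\trna ligase\t\t\n"
        )
        recs = read_gold(p)
        assert recs[0].correct_go == {"GO:1", "GO:2"}
        assert recs[0].annotation_date == dt.date(2008, 1, 1)
        assert recs[1].correct_go is None and recs[1].annotation_date is None
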