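"""Weighted engagement scoring, summaries, rankings, and prediction."""

import math

import pytest

from pagepulse import (
    Corpus,
    DEFAULT_WEIGHTS,
    EngagementWeights,
    GeneratorConfig,
    classify_corpus,
    generate_corpus,
    predict_engagement,
    rank_categories,
    score_corpus,
    score_post,
    summarize,
    table1_fixture,
    weighted_engagement,
)
from pagepulse._text import round_half_up

from conftest import make_post


class TestScorePost:
    def test_published_solidarity_row_means(self):
        # category means treated as a pseudo-post: 0.05·524 + 0.2·346.9 + 0.75·21.4
        score = weighted_engagement(524, 346.9, 21.4)
        assert round_half_up(score) == 111.6

    def test_single_post_small_counts(self):
        post = make_post("p", reactions=20, shares=1, comments=2)
        assert round_half_up(score_post(post).engagement) == 2.7

    def test_all_zero_counts(self):
        s = score_post(make_post("z"))
        assert s.engagement == 0.0 and s.engagement_rate is None

    def test_clicks_add_linearly_when_present(self):
        post = make_post("c", reactions=20, shares=1, comments=2, clicks=10)
        assert score_post(post).engagement == pytest.approx(12.7)
        public = EngagementWeights(include_clicks=False)
        assert score_post(post, public).engagement == pytest.approx(2.7)

    def test_rate_defined_only_with_positive_reach(self):
        with_reach = make_post("r", reactions=20, shares=1, comments=2, reach=100)
        assert score_post(with_reach).engagement_rate == pytest.approx(0.027)
        zero_reach = make_post("z", reactions=20, shares=1, comments=2, reach=0)
        assert score_post(zero_reach).engagement_rate is None

    def test_zero_weights_and_no_clicks_score_zero(self):
        weights = EngagementWeights(0, 0, 0, include_clicks=False)
        post = make_post("p", reactions=99, shares=99, comments=99, clicks=5)
        assert score_post(post, weights).engagement == 0.0

    def test_scale_equivariance(self):
        a = make_post("a", reactions=7, shares=3, comments=2)
        b = make_post("b", reactions=14, shares=6, comments=4)
        assert score_post(b).engagement == pytest.approx(2 * score_post(a).engagement)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            EngagementWeights(-0.1, 0.2, 0.75)


class TestSummarize:
    def test_category_share_percentages(self, demo_dictionary):
        posts = [
            make_post(f"s{i}", "pesquisa científica" if i < 129 else "doe sangue")
            for i in range(261)
        ]
        corpus = Corpus(posts=posts)
        assignments = classify_corpus(corpus, demo_dictionary)
        rows = {s.category: s for s in summarize(corpus, assignments)}
        science = rows["science_and_health"]
        assert science.n_posts == 129
        assert round_half_up(science.pct_posts) == 49.4

    def test_single_post_group_means_equal_counts(self, demo_dictionary):
        corpus = Corpus(posts=[make_post("one", "evento hoje", reactions=12, shares=3, comments=1)])
        rows = summarize(corpus, classify_corpus(corpus, demo_dictionary))
        [row] = rows
        assert (row.mean_reactions, row.mean_shares, row.mean_comments) == (12, 3, 1)
        assert row.pct_posts == 100.0

    def test_empty_category_reported_as_absent(self, demo_dictionary):
        corpus = Corpus(posts=[make_post("one", "evento hoje")])
        rows = summarize(
            corpus,
            classify_corpus(corpus, demo_dictionary),
            categories=["events", "beauty"],
        )
        beauty = next(s for s in rows if s.category == "beauty")
        assert beauty.n_posts == 0 and beauty.mean_reactions is None
        assert beauty.weighted_avg_engagement is None

    def test_linearity_mean_of_scores_equals_score_of_means(self, demo_dictionary):
        corpus, _ = generate_corpus(GeneratorConfig(n_posts=300, seed=5))
        assignments = classify_corpus(corpus, demo_dictionary)
        weights = DEFAULT_WEIGHTS.public_only()
        scores = {s.post_id: s.engagement for s in score_corpus(corpus, weights)}
        for row in summarize(corpus, assignments, weights):
            if row.n_posts == 0:
                continue
            members = [
                scores[p.post_id]
                for p, a in zip(corpus, assignments)
                if p.group == row.group and a.assigned_category == row.category
            ]
            mean_of_scores = sum(members) / len(members)
            assert math.isclose(mean_of_scores, row.weighted_avg_engagement, rel_tol=1e-9)

    def test_uncovered_post_rejected(self, small_corpus, demo_dictionary):
        assignments = classify_corpus(small_corpus, demo_dictionary)[:-1]
        with pytest.raises(ValueError, match="cover"):
            summarize(small_corpus, assignments)


class TestRankCategories:
    def test_published_informative_group_ordering(self):
        informative = [s for s in table1_fixture() if s.group == "informative"]
        ranked = rank_categories(informative, "weighted_avg_engagement")
        order = [s.category for s in ranked]
        assert order[0] == "anniversaries"
        assert order[1] == "testimonies_or_real_life_stories"
        assert order.index("science_and_health") == 5  # 6th place

    def test_absent_values_rank_last_and_ties_alphabetical(self):
        rows = [s for s in table1_fixture() if s.group == "ngo"]
        ranked = rank_categories(rows, "weighted_avg_engagement")
        assert [s.category for s in ranked[-2:]] == ["risk_factors", "science_and_health"]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            rank_categories(table1_fixture(), "sentiment")


class TestPredictEngagement:
    def history(self, specs):
        posts = [
            make_post(f"h{i}", text, reactions=int(eng / 0.05))
            for i, (text, eng) in enumerate(specs)
        ]
        return Corpus(posts=posts)

    def test_single_keyword_history_mean(self, demo_dictionary):
        # keyword appears in two past posts with engagement 10 and 20 -> 15
        history = self.history([("palestra zyba", 10.0), ("palestra zyco", 20.0), ("zydu", 99.0)])
        result = predict_engagement("venha à palestra", history, demo_dictionary)
        assert result.prediction == pytest.approx(15.0)
        assert result.contributions == {"palestra": pytest.approx(15.0)}
        assert not result.fallback

    def test_two_keywords_average_their_means(self, demo_dictionary):
        history = self.history([("palestra", 10.0), ("doador", 30.0)])
        result = predict_engagement("palestra com doador", history, demo_dictionary)
        assert result.prediction == pytest.approx(20.0)

    def test_no_dictionary_words_falls_back_to_corpus_mean(self, demo_dictionary):
        history = self.history([("zyba", 40.0), ("zyco", 44.0)])
        result = predict_engagement("texto sem palavras do dicionário aqui", history, demo_dictionary)
        assert result.fallback
        assert result.prediction == pytest.approx(42.0)

    def test_translation_consistency(self, demo_dictionary):
        base = [("palestra zyba", 10.0), ("doador zyco", 30.0), ("zydu", 5.0)]
        shifted = [(t, e + 100.0) for t, e in base]
        for text in ["palestra", "palestra doador", "zyba zyxx"]:
            p0 = predict_engagement(text, self.history(base), demo_dictionary).prediction
            p1 = predict_engagement(text, self.history(shifted), demo_dictionary).prediction
            assert p1 == pytest.approx(p0 + 100.0)

    def test_empty_history_rejected(self, demo_dictionary):
        with pytest.raises(ValueError, match="empty"):
            predict_engagement("palestra", Corpus(posts=[]), demo_dictionary)
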