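"""Feedback and resource-based query expansion, including the relevance model."""

import pytest

from bioir import (UNORDERED, ExpandedQuery, FeedbackConfig, MFTConfig,
                   QueryTopic, ResourceConfig, build_index,
                   mft_expand, relevance_model_expand, resource_expand,
                   run_expanded, search)
from bioir.expansion import load_candidate_texts, relevance_model_probabilities


def q(topic_id, terms):
    return QueryTopic(topic_id, " ".join(terms), tuple((t, 1.0) for t in terms))


@pytest.fixture(scope="module")
def fb_index(plain_config):
    # hand-traceable feedback corpus: |f1|=3, |f2|=4, |f3|=2
    return build_index([
        ("f1", "alpha alpha beta"),
        ("f2", "alpha gamma gamma gamma"),
        ("f3", "delta delta"),
    ], plain_config)


@pytest.fixture(scope="module")
def fb_run(fb_index):
    return search(q("t", ["alpha"]), fb_index, run_id="init")  # ranks f1, f2


class TestMFT:
    def test_zero_term_count_is_identity(self, fb_run, fb_index):
        query = q("t", ["alpha"])
        expanded = mft_expand(fb_run, fb_index, query, MFTConfig(2, 0))
        assert expanded.expansion == ()
        assert expanded.original == query.terms

    def test_hand_counted_top_terms(self, fb_run, fb_index):
        # over f1+f2, excluding "alpha": gamma tf 3, beta tf 1
        expanded = mft_expand(fb_run, fb_index, q("t", ["alpha"]), MFTConfig(2, 2))
        assert [t for t, _ in expanded.expansion] == ["gamma", "beta"]
        assert all(w == 1.0 for _, w in expanded.expansion)

    def test_original_terms_never_selected(self, fb_run, fb_index):
        expanded = mft_expand(fb_run, fb_index, q("t", ["alpha", "gamma", "beta"]),
                              MFTConfig(2, 5))
        assert expanded.expansion == ()

    def test_ties_break_alphabetically(self, plain_config):
        index = build_index([("d1", "query zebra apple"), ("d2", "other stuff")],
                            plain_config)
        run = search(q("t", ["query"]), index)
        expanded = mft_expand(run, index, q("t", ["query"]), MFTConfig(1, 2))
        assert [t for t, _ in expanded.expansion] == ["apple", "zebra"]

    def test_short_run_uses_available_docs(self, fb_run, fb_index):
        expanded = mft_expand(fb_run, fb_index, q("t", ["alpha"]), MFTConfig(50, 2))
        assert len(expanded.expansion) == 2

    def test_missing_topic_rejected(self, fb_run, fb_index):
        with pytest.raises(ValueError, match="no results"):
            mft_expand(fb_run, fb_index, q("other", ["alpha"]), MFTConfig(1, 1))


class TestRelevanceModel:
    def test_distribution_sums_to_one(self, fb_run, fb_index):
        for mu in (0.0, 100.0, 2500.0):
            probs = relevance_model_probabilities(
                fb_index, ["f1", "f2"], q("t", ["alpha"]), mu)
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_doc_mu_zero_is_ml_model(self, fb_run, fb_index):
        probs = relevance_model_probabilities(fb_index, ["f1"], q("t", ["alpha"]), 0.0)
        assert probs["alpha"] == pytest.approx(2 / 3)
        assert probs["beta"] == pytest.approx(1 / 3)
        assert probs.get("gamma", 0.0) == 0.0

    def test_two_doc_mixture_hand_computation(self, fb_run, fb_index):
        # omega: softmax of query likelihood, mu=0 -> P(alpha|f1)=2/3,
        # P(alpha|f2)=1/4 -> omega = (8/11, 3/11)
        probs = relevance_model_probabilities(
            fb_index, ["f1", "f2"], q("t", ["alpha"]), 0.0)
        assert probs["alpha"] == pytest.approx(73 / 132)
        assert probs["beta"] == pytest.approx(8 / 33)
        assert probs["gamma"] == pytest.approx(9 / 44)

    def test_expansion_weights_and_mass_split(self, fb_run, fb_index):
        config = FeedbackConfig(fb_docs=2, fb_terms=2, fb_orig_weight=0.3, mu=0.0)
        expanded = relevance_model_expand(fb_run, fb_index, q("t", ["alpha"]), config)
        assert sum(w for _, w in expanded.original) == pytest.approx(0.3)
        assert sum(w for _, w in expanded.expansion) == pytest.approx(0.7, abs=1e-9)
        # candidates: beta 8/33 > gamma 9/44; weights proportional to P(w|R)
        weights = dict(expanded.expansion)
        assert weights["beta"] / weights["gamma"] == pytest.approx((8 / 33) / (9 / 44))

    def test_full_original_weight_reproduces_ranking(self, fb_run, fb_index):
        query = q("t", ["alpha"])
        expanded = relevance_model_expand(
            fb_run, fb_index, query, FeedbackConfig(2, 2, fb_orig_weight=1.0))
        assert expanded.expansion == ()
        base = [e.doc_id for e in search(query, fb_index).for_topic("t")]
        got = [e.doc_id for e in run_expanded(expanded, fb_index).for_topic("t")]
        assert got == base

    def test_scores_affine_in_orig_weight(self, fb_run, fb_index):
        """With fixed term sets, fused query scores are affine in fbOrigWeight."""
        query = q("t", ["alpha"])

        def scores(w):
            expanded = relevance_model_expand(
                fb_run, fb_index, query, FeedbackConfig(2, 2, w, mu=0.0))
            return {e.doc_id: e.score
                    for e in run_expanded(expanded, fb_index).for_topic("t")}

        s1, s5, s9 = scores(0.1), scores(0.5), scores(0.9)
        for doc in s5:
            assert s5[doc] == pytest.approx((s1.get(doc, 0) + s9.get(doc, 0)) / 2)

    def test_invalid_orig_weight_rejected(self):
        with pytest.raises(ValueError):
            FeedbackConfig(fb_orig_weight=1.5)


class TestResourceExpansion:
    def test_empty_candidate_text(self, plain_config):
        config = ResourceConfig(candidate_texts={"t": ""}, term_count=5)
        expanded = resource_expand(q("t", ["alpha"]), config, plain_config)
        assert expanded.expansion == ()

    def test_unordered_mode_returns_all_when_few(self, plain_config):
        # three distinct eligible terms -> exactly three expansion terms
        config = ResourceConfig(candidate_texts={"t": "beta gamma delta beta"},
                                term_count=UNORDERED)
        expanded = resource_expand(q("t", ["alpha"]), config, plain_config)
        assert sorted(t for t, _ in expanded.expansion) == ["beta", "delta", "gamma"]

    def test_unordered_mode_caps_at_ten(self, plain_config):
        text = " ".join(f"w{i:02d}" for i in range(15))
        config = ResourceConfig(candidate_texts={"t": text}, term_count=UNORDERED)
        expanded = resource_expand(q("t", ["alpha"]), config, plain_config)
        assert len(expanded.expansion) == 10

    def test_fixed_mode_top_terms_by_count(self, plain_config):
        config = ResourceConfig(
            candidate_texts={"t": "beta beta gamma gamma delta alpha alpha alpha"},
            term_count=2)
        expanded = resource_expand(q("t", ["alpha"]), config, plain_config)
        # alpha excluded as original; beta/gamma tie at 2 -> alphabetical
        assert [t for t, _ in expanded.expansion] == ["beta", "gamma"]

    def test_missing_topic_names_it(self, plain_config):
        config = ResourceConfig(candidate_texts={}, term_count=3)
        with pytest.raises(KeyError, match="t99"):
            resource_expand(q("t99", ["alpha"]), config, plain_config)

    def test_candidate_texts_loaders(self, tmp_path):
        d = tmp_path / "cands"
        d.mkdir()
        (d / "200.txt").write_text("gene stuff", encoding="utf-8")
        assert load_candidate_texts(d) == {"200": "gene stuff"}
        tsv = tmp_path / "cands.tsv"
        tsv.write_text("200\tgene stuff\n", encoding="utf-8")
        assert load_candidate_texts(tsv) == {"200": "gene stuff"}


class TestRunExpanded:
    def test_no_expansion_terms_identical_run(self, fb_run, fb_index):
        query = q("t", ["alpha"])
        expanded = ExpandedQuery("t", query.terms, (), "mft")
        base = search(query, fb_index).for_topic("t")
        got = run_expanded(expanded, fb_index).for_topic("t")
        assert [(e.doc_id, e.score) for e in got] == [(e.doc_id, e.score) for e in base]

    def test_unindexed_expansion_term_contributes_nothing(self, fb_run, fb_index):
        query = q("t", ["alpha"])
        with_unknown = ExpandedQuery("t", query.terms, (("zzz", 1.0),), "mft")
        base = search(query, fb_index).for_topic("t")
        got = run_expanded(with_unknown, fb_index).for_topic("t")
        assert [(e.doc_id, e.score) for e in got] == [(e.doc_id, e.score) for e in base]

    def test_matches_exhaustive_scoring(self, fb_run, fb_index):
        expanded = ExpandedQuery("t", (("alpha", 0.5),), (("gamma", 0.5),), "mft")
        from bioir import score_document
        query = expanded.as_query()
        oracle = sorted(((d, score_document(query, d, fb_index))
                        for d in ("f1", "f2", "f3")), key=lambda kv: (-kv[1], kv[0]))
        oracle = [(d, s) for d, s in oracle if s > 0]
        got = [(e.doc_id, e.score) for e in run_expanded(expanded, fb_index).for_topic("t")]
        assert [d for d, _ in got] == [d for d, _ in oracle]


def test_expanded_query_invariants():
    with pytest.raises(ValueError, match="disjoint"):
        ExpandedQuery("t", (("a", 1.0),), (("a", 1.0),), "mft")
    with pytest.raises(ValueError, match="positive"):
        ExpandedQuery("t", (("a", 0.0),), (), "mft")
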