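import itertools

import numpy as np
import pytest

from beelit.synth import PlantedTopic, SynthConfig, generate_corpus
from beelit.topics import (
    Document,
    build_documents,
    coherence_cv,
    coherence_cv_topics,
    select_k,
    topic_top_words,
    topic_word_network,
    train_lda,
)
from beelit.conet import global_transitivity
from conftest import make_corpus, three_disjoint_topics


def docs_from(token_lists):
    return [Document(id=f"d{i}", period="", tokens=list(t))
            for i, t in enumerate(token_lists)]


class TestBuildDocuments:
    def test_cleaning_removes_notation_numbers_and_stopwords(self):
        corpus = make_corpus([(2000, [], "RNA-seq of Apis mellifera (n=10, p<0.05)")])
        docs = build_documents(corpus)
        assert docs[0].tokens == ["rna", "seq", "api", "mellifera"]

    def test_title_keywords_abstract_all_contribute(self):
        corpus = make_corpus([(2000, ["varroa destructor"], "Mite biology", "")])
        docs = build_documents(corpus)
        assert docs[0].tokens == ["mite", "biologi", "varroa", "destructor"]

    def test_tokens_contain_no_digits_or_empties(self):
        corpus = make_corpus([(2000, ["50% sucrose"], "3 colonies, 2 apiaries!", "pH 7.4")])
        docs = build_documents(corpus)
        assert all(t and t.isalpha() for t in docs[0].tokens)

    def test_stopword_removal_is_optional(self):
        corpus = make_corpus([(2000, [], "the bees of the hive")])
        with_stop = build_documents(corpus, remove_stopwords=False)
        without = build_documents(corpus)
        assert "the" in with_stop[0].tokens
        assert "the" not in without[0].tokens


class TestTrainLda:
    def test_rows_normalized(self):
        docs = docs_from([["a", "b", "a"], ["c", "b"], ["a", "c", "c"]] * 5)
        model = train_lda(docs, k=2, seed=0, iterations=20)
        np.testing.assert_allclose(model.topic_word.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(model.doc_topic.sum(axis=1), 1.0, atol=1e-6)

    def test_single_topic_matches_unigram_frequencies(self):
        rng = np.random.default_rng(0)
        vocab = list("abcdefgh")
        probs = rng.dirichlet(np.ones(8) * 3)
        token_lists = [list(rng.choice(vocab, size=30, p=probs)) for _ in range(40)]
        model = train_lda(docs_from(token_lists), k=1, seed=0, iterations=50)
        counts = np.zeros(len(model.vocabulary))
        for t in token_lists:
            for tok in t:
                counts[model.vocabulary.index(tok)] += 1
        empirical = counts / counts.sum()
        tv = 0.5 * np.abs(model.topic_word[0] - empirical).sum()
        assert tv < 0.01

    def test_two_disjoint_topics_recovered(self):
        rng = np.random.default_rng(1)
        vocab_a = [f"a{i}" for i in range(12)]
        vocab_b = [f"b{i}" for i in range(12)]
        token_lists = []
        for _ in range(60):
            src = vocab_a if rng.random() < 0.5 else vocab_b
            token_lists.append(list(rng.choice(src, size=25)))
        model = train_lda(docs_from(token_lists), k=2, seed=0, iterations=60)
        for summary in topic_top_words(model, n=10):
            prefixes = {w[0] for w in summary.words}
            assert len(prefixes) == 1  # all top words from one generating vocabulary

    def test_deterministic_under_seed(self):
        docs = docs_from([["a", "b"], ["b", "c"], ["c", "a"]] * 10)
        m1 = train_lda(docs, k=2, seed=3, iterations=25)
        m2 = train_lda(docs, k=2, seed=3, iterations=25)
        np.testing.assert_array_equal(m1.topic_word, m2.topic_word)

    def test_k_larger_than_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            train_lda(docs_from([["a", "b"]]), k=5)


class TestTopWords:
    def two_topic_model(self):
        # topic 0 concentrates on 'shared' + exclusive a-words, topic 1 on
        # 'shared' + exclusive b-words; 'shared' is globally frequent
        rng = np.random.default_rng(2)
        token_lists = []
        for i in range(60):
            src = ["shared"] * 3 + ([f"a{j}" for j in range(5)] if i % 2 else
                                    [f"b{j}" for j in range(5)])
            token_lists.append(list(rng.choice(src, size=20)))
        return train_lda(docs_from(token_lists), k=2, seed=0, iterations=50)

    def test_lambda_one_ranks_by_probability(self):
        model = self.two_topic_model()
        for s in topic_top_words(model, n=3, lam=1.0):
            probs = model.topic_word[s.topic_id]
            ranked = sorted(
                range(len(model.vocabulary)),
                key=lambda i: (-probs[i], model.vocabulary[i]),
            )[:3]
            assert s.words == [model.vocabulary[i] for i in ranked]

    def test_lambda_zero_promotes_topic_exclusive_words(self):
        model = self.two_topic_model()
        plain = topic_top_words(model, n=3, lam=1.0)
        lift = topic_top_words(model, n=3, lam=0.0)
        # 'shared' dominates raw probability but has no lift
        assert any("shared" in s.words for s in plain)
        assert all("shared" not in s.words for s in lift)

    def test_scores_non_increasing(self):
        model = self.two_topic_model()
        for s in topic_top_words(model, n=8):
            assert all(a >= b for a, b in zip(s.scores, s.scores[1:]))

    def test_single_topic_top_words_are_corpus_modes(self):
        rng = np.random.default_rng(3)
        vocab = list("abcde")
        token_lists = [list(rng.choice(vocab, size=20, p=[0.4, 0.3, 0.15, 0.1, 0.05]))
                       for _ in range(30)]
        model = train_lda(docs_from(token_lists), k=1, seed=0, iterations=40)
        top = topic_top_words(model, n=2)[0].words
        counts = {w: sum(t.count(w) for t in token_lists) for w in vocab}
        expected = sorted(vocab, key=lambda w: -counts[w])[:2]
        assert top == expected


class TestCoherence:
    def test_cooccurring_words_score_higher_than_scattered(self):
        rng = np.random.default_rng(4)
        # words x,y,z always co-occur; u,v,w never share a document
        token_lists = [["x", "y", "z"] * 3 for _ in range(20)]
        token_lists += [[w] * 6 for w in ("u", "v", "w") for _ in range(7)]
        docs = docs_from(token_lists)
        coherent = coherence_cv_topics([["x", "y", "z"]], docs)
        incoherent = coherence_cv_topics([["u", "v", "w"]], docs)
        assert coherent > incoherent
        assert coherent > 0.9

    def test_score_within_unit_interval(self, small_synth):
        corpus, _ = small_synth
        docs = build_documents(corpus)[:150]
        model = train_lda(docs, k=4, seed=0, iterations=15)
        assert 0.0 <= coherence_cv(model, docs, top_n=5) <= 1.0

    def test_absent_word_smoothed_not_fatal(self):
        docs = docs_from([["x", "y"]] * 5)
        score = coherence_cv_topics([["x", "y", "ghost"]], docs)
        assert 0.0 <= score <= 1.0

    def test_top_n_below_two_rejected(self):
        docs = docs_from([["x", "y"]])
        model = train_lda(docs, k=1)
        with pytest.raises(ValueError):
            coherence_cv(model, docs, top_n=1)


class TestSelectK:
    def test_single_candidate_chosen_trivially(self):
        docs = docs_from([["a", "b", "c"]] * 10)
        table, k, models = select_k(docs, [2], seed=0, iterations=10)
        assert k == 2 and list(models) == [2]

    def test_override_takes_precedence(self):
        docs = docs_from([["a", "b", "c"], ["b", "c", "d"]] * 10)
        _, k, _ = select_k(docs, [2, 3], seed=0, iterations=10, chosen_k=3)
        assert k == 3


class TestTopicWordNetwork:
    def summaries(self, word_lists):
        from beelit.topics import TopicSummary

        return [
            TopicSummary(topic_id=i, words=list(w), scores=[0.0] * len(w))
            for i, w in enumerate(word_lists)
        ]

    def test_two_cliques_joined_at_shared_word(self):
        words_a = ["bee", "forag", "danc", "test", "model"]
        words_b = ["bee", "coloni", "hive", "dai", "group"]
        net = topic_word_network(self.summaries([words_a, words_b]), top_n=5)
        assert net.number_of_nodes() == 9
        assert net.number_of_edges() == 20
        assert net["forag"]["bee"]["weight"] == 1
        # the shared word bridges the two cliques
        assert net.degree["bee"] == 8

    def test_disjoint_topics_give_disconnected_cliques(self):
        import networkx as nx

        net = topic_word_network(
            self.summaries([["a1", "a2", "a3"], ["b1", "b2", "b3"]]), top_n=3
        )
        assert nx.number_connected_components(net) == 2

    def test_single_clique_transitivity_is_one(self):
        net = topic_word_network(self.summaries([["a", "b", "c", "d", "e"]]), top_n=5)
        assert global_transitivity(net) == pytest.approx(1.0)

    def test_node_count_bounded_by_k_times_topn(self):
        lists = [["a", "b", "c"], ["c", "d", "e"], ["f", "g", "h"]]
        net = topic_word_network(self.summaries(lists), top_n=3)
        assert net.number_of_nodes() <= 3 * 3
        assert net.number_of_nodes() == 8  # one shared word

    def test_shared_pair_weight_counts_topics(self):
        lists = [["a", "b", "c"], ["a", "b", "d"]]
        net = topic_word_network(self.summaries(lists), top_n=3)
        assert net["a"]["b"]["weight"] == 2


class TestPlantedTopicRecovery:
    def test_mean_best_match_overlap(self):
        cfg = SynthConfig(
            year_start=2000, year_end=2009, amplitude=15.0, rate=0.0, tau=2005,
            topics=three_disjoint_topics(),
            era_concentrations=([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            abstract_length=(40, 60), title_length=(5, 8), variant_rate=0.0,
            search_term_rate=0.0, seed=21,
        )
        corpus, truth = generate_corpus(cfg)
        docs = build_documents(corpus)
        model = train_lda(docs, k=3, seed=0, iterations=60)
        true_vocabs = [set(t.words) for t in cfg.topics]
        overlaps = []
        for s in topic_top_words(model, n=10):
            overlaps.append(max(
                len([w for w in s.words if w in v]) / 10 for v in true_vocabs
            ))
        assert np.mean(overlaps) >= 0.8
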