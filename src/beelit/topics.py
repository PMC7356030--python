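"""LDA topic modeling of title + keywords + abstract, with c_v model selection.

Documents are bags of cleaned, stemmed tokens.  Latent Dirichlet
allocation assumes each document mixes k topics and each topic is a
distribution over the vocabulary; models are fitted by batch variational
inference (scikit-learn), which is deterministic under a fixed seed.  The
number of topics is chosen on a grid by the c_v coherence of each model's
top words: boolean sliding-window (width 110) co-occurrence counts turned
into NPMI context vectors, compared by cosine similarity and averaged.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .corpus import Corpus
from .porter import stem

_NON_ALPHA = re.compile(r"[^a-z]+")


@dataclass
class Document:
    """A cleaned bag-of-words document derived from one publication."""

    id: str
    period: str
    tokens: list[str]


def build_documents(
    corpus: Corpus,
    period: str = "",
    remove_stopwords: bool = True,
) -> list[Document]:
    """Title + keywords + abstract -> cleaned, stemmed token lists.

    Cleaning: lowercase; strip everything non-alphabetic (this removes
    numbers, punctuation and scientific notation wholesale); drop
    single-letter residues and, by default, a standard English stop-word
    list; stem the remainder with Porter's algorithm.
    """
    docs = []
    for r in corpus.records:
        text = " ".join([r.title, " ".join(r.keywords), r.abstract]).lower()
        tokens = [t for t in _NON_ALPHA.split(text) if len(t) >= 2]
        if remove_stopwords:
            tokens = [t for t in tokens if t not in ENGLISH_STOP_WORDS]
        docs.append(Document(id=r.id, period=period, tokens=[stem(t) for t in tokens]))
    return docs


# ---------------------------------------------------------------------------
# model fitting

@dataclass
class TopicModel:
    """A fitted LDA model: distributions plus fitting metadata."""

    k: int
    vocabulary: list[str]
    topic_word: np.ndarray      # k x V, rows sum to 1
    doc_topic: np.ndarray       # D x k, rows sum to 1
    term_frequency: np.ndarray  # empirical corpus word distribution (V,)
    alpha: float
    eta: float
    seed: int
    iterations: int
    method: str = "variational-batch"


def _count_matrix(documents: list[Document]) -> tuple[csr_matrix, list[str]]:
    vocab = sorted({t for d in documents for t in d.tokens})
    index = {w: i for i, w in enumerate(vocab)}
    indptr, indices, data = [0], [], []
    for d in documents:
        row: dict[int, int] = {}
        for t in d.tokens:
            row[index[t]] = row.get(index[t], 0) + 1
        indices.extend(row.keys())
        data.extend(row.values())
        indptr.append(len(indices))
    X = csr_matrix((data, indices, indptr), shape=(len(documents), len(vocab)), dtype=np.int64)
    return X, vocab


def train_lda(
    documents: list[Document],
    k: int,
    seed: int = 0,
    iterations: int = 100,
    alpha: float | None = None,
    eta: float = 0.01,
) -> TopicModel:
    """Fit LDA with k topics; deterministic under the seed.

    Default hyperparameters: symmetric document-topic concentration 1/k,
    topic-word concentration 0.01.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, vocab = _count_matrix(documents)
    if not vocab:
        raise ValueError("empty vocabulary")
    if k > len(vocab):
        raise ValueError(f"k={k} exceeds vocabulary size {len(vocab)}")
    alpha = alpha if alpha is not None else 1.0 / k
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=alpha,
        topic_word_prior=eta,
        learning_method="batch",
        max_iter=iterations,
        random_state=seed,
    )
    doc_topic = lda.fit_transform(X)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    doc_topic = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    tf = np.asarray(X.sum(axis=0)).ravel().astype(float)
    return TopicModel(
        k=k, vocabulary=vocab, topic_word=topic_word, doc_topic=doc_topic,
        term_frequency=tf / tf.sum(), alpha=alpha, eta=eta, seed=seed,
        iterations=iterations,
    )


# ---------------------------------------------------------------------------
# topic summaries

@dataclass
class TopicSummary:
    """Ranked top words of one topic."""

    topic_id: int
    words: list[str]
    scores: list[float]
    label: str | None = None


def topic_top_words(model: TopicModel, n: int = 10, lam: float = 1.0) -> list[TopicSummary]:
    """Top-n words per topic under LDAvis-style relevance.

    relevance(w) = lam * log p(w|topic) + (1 - lam) * log[p(w|topic)/p(w)];
    lam = 1 ranks by plain within-topic probability, lam = 0 by lift.
    Ties break lexicographically.
    """
    if not 1 <= n <= len(model.vocabulary):
        raise ValueError("n out of range")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    eps = 1e-12
    logp = np.log(model.topic_word + eps)
    loglift = logp - np.log(model.term_frequency + eps)[None, :]
    relevance = lam * logp + (1.0 - lam) * loglift
    summaries = []
    for t in range(model.k):
        order = sorted(
            range(len(model.vocabulary)),
            key=lambda i: (-relevance[t, i], model.vocabulary[i]),
        )[:n]
        summaries.append(
            TopicSummary(
                topic_id=t,
                words=[model.vocabulary[i] for i in order],
                scores=[float(relevance[t, i]) for i in order],
            )
        )
    return summaries


def summaries_to_json(summaries: list[TopicSummary], path, extra: dict | None = None) -> None:
    payload = {
        "topics": [
            {"topic_id": s.topic_id, "words": s.words, "scores": s.scores,
             "label": s.label}
            for s in summaries
        ]
    }
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# c_v coherence

def _sliding_windows(tokens: list[str], width: int):
    if len(tokens) <= width:
        yield frozenset(tokens)
    else:
        for i in range(len(tokens) - width + 1):
            yield frozenset(tokens[i : i + width])


def _window_counts(documents: list[Document], words: set[str], width: int):
    """Boolean sliding-window occurrence and joint counts for tracked words."""
    singles = {w: 0 for w in words}
    pairs: dict[tuple[str, str], int] = {}
    n_windows = 0
    for d in documents:
        for window in _sliding_windows(d.tokens, width):
            n_windows += 1
            present = sorted(words & window)
            for w in present:
                singles[w] += 1
            for a, b in itertools.combinations(present, 2):
                pairs[(a, b)] = pairs.get((a, b), 0) + 1
    return singles, pairs, max(n_windows, 1)


def coherence_cv(
    model: TopicModel,
    documents: list[Document],
    top_n: int = 10,
    window: int = 110,
) -> float:
    """c_v coherence of a fitted model's top words, averaged over topics."""
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    summaries = topic_top_words(model, n=min(top_n, len(model.vocabulary)))
    return coherence_cv_topics([s.words for s in summaries], documents, window=window)


def coherence_cv_topics(
    topics: list[list[str]],
    documents: list[Document],
    window: int = 110,
) -> float:
    """c_v coherence of explicit top-word lists.

    Per topic: NPMI context vector for each top word (entries NPMI with
    every top word of that topic), topic score = mean cosine similarity
    over word pairs; model score = mean over topics, clipped to [0, 1].
    Words absent from every window get their count smoothed to 1.
    """
    tracked = {w for topic in topics for w in topic}
    singles, pairs, W = _window_counts(documents, tracked, window)
    eps = 1e-12

    def p_single(w: str) -> float:
        return max(singles[w], 1) / W  # +1 smoothing for unseen words

    def npmi(a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        p_ab = pairs.get(key, 0) / W
        val = np.log((p_ab + eps) / (p_single(a) * p_single(b)))
        return float(val / -np.log(p_ab + eps))

    topic_scores = []
    for topic in topics:
        words = list(dict.fromkeys(topic))
        if len(words) < 2:
            continue
        vectors = np.array([[npmi(wi, wj) for wj in words] for wi in words])
        sims = []
        for i, j in itertools.combinations(range(len(words)), 2):
            vi, vj = vectors[i], vectors[j]
            denom = np.linalg.norm(vi) * np.linalg.norm(vj)
            sims.append(float(vi @ vj / denom) if denom > 0 else 0.0)
        topic_scores.append(float(np.mean(sims)))
    if not topic_scores:
        raise ValueError("no topic with >= 2 distinct top words")
    return float(np.clip(np.mean(topic_scores), 0.0, 1.0))


# ---------------------------------------------------------------------------
# model selection

DEFAULT_K_GRID = [20, 50, 70, 90, 110, 140]


def select_k(
    documents: list[Document],
    candidate_ks: list[int] | None = None,
    seed: int = 0,
    iterations: int = 100,
    top_n: int = 10,
    chosen_k: int | None = None,
) -> tuple[pd.DataFrame, int, dict[int, TopicModel]]:
    """Train one model per candidate k and score each by c_v coherence.

    Returns (scores table, chosen k, fitted models).  By default the
    chosen k is the coherence argmax (smallest k wins ties); pass
    ``chosen_k`` to override, mirroring selection that blends coherence
    with manual inspection.
    """
    ks = list(candidate_ks) if candidate_ks else list(DEFAULT_K_GRID)
    if not ks:
        raise ValueError("candidate_ks must be non-empty")
    rows, models = [], {}
    for k in ks:
        model = train_lda(documents, k=k, seed=seed, iterations=iterations)
        score = coherence_cv(model, documents, top_n=top_n)
        models[k] = model
        rows.append({"k": k, "coherence_cv": score})
    table = pd.DataFrame(rows)
    best = int(table.sort_values(["coherence_cv", "k"], ascending=[False, True]).iloc[0]["k"])
    return table, (chosen_k if chosen_k is not None else best), models


# ---------------------------------------------------------------------------
# topic-word network

def topic_word_network(summaries: list[TopicSummary], top_n: int = 5) -> nx.Graph:
    """Clique-per-topic network over each topic's top-n words.

    Edge weight = number of topics in which the pair co-occurs; topics
    sharing a word join through that node.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    G = nx.Graph()
    for s in summaries:
        words = s.words[:top_n]
        G.add_nodes_from(words)
        for a, b in itertools.combinations(words, 2):
            if a == b:
                continue
            if G.has_edge(a, b):
                G[a][b]["weight"] += 1
            else:
                G.add_edge(a, b, weight=1)
    nx.set_node_attributes(G, dict(G.degree()), "degree")
    return G
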