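import numpy as np
import pytest

from beelit.corpus import Corpus, PublicationRecord
from beelit.synth import PlantedTopic, SynthConfig, generate_corpus


def make_corpus(rows):
    """rows: iterable of (year, keywords) or (year, keywords, title, abstract)."""
    records = []
    for i, row in enumerate(rows):
        year, keywords = row[0], list(row[1])
        title = row[2] if len(row) > 2 else ""
        abstract = row[3] if len(row) > 3 else ""
        records.append(
            PublicationRecord(id=f"p{i}", year=year, title=title,
                              abstract=abstract, keywords=keywords)
        )
    return Corpus(records=records)


@pytest.fixture(scope="session")
def small_synth():
    """A small era-structured corpus shared by the slower integration tests."""
    cfg = SynthConfig(
        year_start=1985, year_end=2010, amplitude=4.0, rate=0.08, tau=1998,
        abstract_length=(30, 60), title_length=(5, 9), seed=7,
    )
    return generate_corpus(cfg)


def three_disjoint_topics():
    """Three planted topics over disjoint 10-word vocabularies."""
    # suffix letters chosen so Porter stemming leaves every word unchanged
    words = [
        [f"alpha{c}" for c in "bcdfghjklm"],
        [f"beta{c}" for c in "bcdfghjklm"],
        [f"gamma{c}" for c in "bcdfghjklm"],
    ]
    return [PlantedTopic(f"t{i}", w) for i, w in enumerate(words)]


def random_keyword_corpus(rng, n_pubs, keywords, p=0.4):
    """Corpus with independent Bernoulli keyword membership (null model)."""
    rows = []
    for _ in range(n_pubs):
        kws = [kw for kw in keywords if rng.random() < p]
        rows.append((2000, kws))
    return make_corpus(rows)
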