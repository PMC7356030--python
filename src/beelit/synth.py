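"""Synthetic bibliographic corpora with known generative structure.

The generator emulates the statistical shape of a Scopus export for a
growing research field: exponentially increasing annual publication
counts, a set of planted topics whose prevalence shifts at a regime-change
year tau, per-publication author-keyword sets drawn from the active topic
mixture, bag-of-words titles/abstracts drawn from the same mixture, and
injected lexical keyword variants whose variant -> canonical pairs are
recorded so normalization can be tested against ground truth.

Defaults mirror a six-decade honey bee literature: amplitude 6.29 and
growth rate 0.087/yr over 1957-2017 (roughly 14k records doubling every
8 years), regime change at 1992, and eight domain topics whose balance
tilts from classical apiculture/behavior toward parasitology, genomics
and colony-health after the regime change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, PublicationRecord, write_publications
from .normalize import SynonymMap

SEARCH_TERM = "apis mellifera"
# lexical variants of the search term observed in real author keywords
SEARCH_TERM_VARIANTS = [
    "honey-bee (apis mellifera)",
    "honey-bee apis mellifera",
    "honey bee a. mellifera",
    "honey bee apis mellifera",
]


@dataclass
class PlantedTopic:
    """A named word distribution used for both keywords and running text."""

    name: str
    words: list[str]
    probs: list[float] | None = None  # None -> uniform

    def distribution(self) -> np.ndarray:
        if self.probs is None:
            return np.full(len(self.words), 1.0 / len(self.words))
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.words),) or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"topic {self.name!r}: probs must sum to 1 over its words")
        return p


def default_topics() -> list[PlantedTopic]:
    return [
        PlantedTopic("foraging-behavior", [
            "forage", "dance", "nectar", "flower", "communication", "waggle",
            "scout", "recruitment", "odor", "learning", "memory", "orientation",
            "navigation", "sucrose", "reward",
        ]),
        PlantedTopic("pollination", [
            "pollination", "crop", "orchard", "seed", "yield", "almond",
            "clover", "sunflower", "greenhouse", "pollinator", "bloom",
            "fruit", "cultivar", "agriculture",
        ]),
        PlantedTopic("physiology-taxonomy", [
            "caste", "morphology", "gland", "cuticle", "anatomy", "subspecies",
            "carnica", "ligustica", "hymenoptera", "drone", "worker",
            "metabolism", "hemolymph", "pheromone",
        ]),
        PlantedTopic("apiculture-products", [
            "honey", "wax", "propolis", "royal", "jelly", "venom", "hive",
            "beekeeping", "apiary", "colony", "swarm", "queen", "brood", "comb",
        ]),
        PlantedTopic("varroa-pathology", [
            "varroa", "destructor", "mite", "acaricide", "infestation",
            "nosema", "chalkbrood", "foulbrood", "tracheal", "resistance",
            "treatment", "parasite", "pathogen", "prevalence",
        ]),
        PlantedTopic("genomics", [
            "genome", "gene", "expression", "transcriptome", "sequencing",
            "microarray", "rna", "pcr", "methylation", "protein", "genetic",
            "marker", "microsatellite", "allele",
        ]),
        PlantedTopic("colony-health", [
            "virus", "deformed", "wing", "immunity", "pesticide",
            "neonicotinoid", "imidacloprid", "stress", "mortality", "collapse",
            "disorder", "infection", "decline", "overwintering",
        ]),
        PlantedTopic("neuroscience", [
            "brain", "neuron", "mushroom", "antennal", "lobe", "receptor",
            "octopamine", "dopamine", "olfactory", "vision", "synapse",
            "plasticity",
        ]),
    ]


def _default_era_concentrations(n_topics: int) -> tuple[list[float], list[float]]:
    half = n_topics // 2
    pre = [2.0] * half + [0.2] * (n_topics - half)
    post = [0.2] * half + [2.0] * (n_topics - half)
    return pre, post


@dataclass
class SynthConfig:
    """Generative parameters for a synthetic corpus."""

    year_start: int = 1957
    year_end: int = 2017
    amplitude: float = 6.29          # expected publications in year_start
    rate: float = 0.087              # exponential growth per year
    tau: int = 1992                  # regime-change year (starts the late era)
    topics: list[PlantedTopic] = field(default_factory=default_topics)
    era_concentrations: tuple[list[float], list[float]] | None = None
    keywords_per_pub: tuple[int, int] = (3, 8)
    title_length: tuple[int, int] = (6, 12)
    abstract_length: tuple[int, int] = (60, 120)
    variant_rate: float = 0.1        # chance a keyword is emitted as a variant
    search_term_rate: float = 0.6    # chance the search term appears as keyword
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not self.year_start <= self.tau <= self.year_end:
            raise ValueError("tau must lie inside the year range")
        if not 0.0 <= self.variant_rate <= 1.0:
            raise ValueError("variant_rate must be in [0, 1]")
        if self.era_concentrations is None:
            self.era_concentrations = _default_era_concentrations(len(self.topics))
        for conc in self.era_concentrations:
            if len(conc) != len(self.topics):
                raise ValueError("era concentration length must equal number of topics")


@dataclass
class GroundTruth:
    """The hidden structure behind a generated corpus."""

    doc_mixtures: dict[str, list[float]]
    keyword_topic: dict[str, int]
    annual_counts: dict[int, int]
    era_by_year: dict[int, str]
    synonym_map: SynonymMap

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "doc_mixtures": self.doc_mixtures,
                    "keyword_topic": self.keyword_topic,
                    "annual_counts": {str(y): c for y, c in self.annual_counts.items()},
                    "era_by_year": {str(y): e for y, e in self.era_by_year.items()},
                    "synonym_map": self.synonym_map.entries,
                },
                fh, indent=2,
            )


def expected_annual_counts(config: SynthConfig) -> dict[int, int]:
    """Deterministic annual counts: round(a * exp(b * (year - start)))."""
    return {
        year: int(round(config.amplitude * np.exp(config.rate * (year - config.year_start))))
        for year in range(config.year_start, config.year_end + 1)
    }


def _variants_for(keyword: str) -> list[str]:
    if keyword == SEARCH_TERM:
        return list(SEARCH_TERM_VARIANTS)
    return [f"honey bee {keyword}", f"honey-bee {keyword}"]


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus and its ground truth; fully deterministic under the seed."""
    counts = expected_annual_counts(config)
    if sum(counts.values()) == 0:
        raise ValueError("config generates an empty corpus")
    rng = np.random.default_rng(config.seed)

    topic_dists = [t.distribution() for t in config.topics]
    vocab = sorted({w for t in config.topics for w in t.words})
    vocab_index = {w: i for i, w in enumerate(vocab)}
    topic_word = np.zeros((len(config.topics), len(vocab)))
    for t_i, topic in enumerate(config.topics):
        for w, p in zip(topic.words, topic_dists[t_i]):
            topic_word[t_i, vocab_index[w]] += p
    keyword_topic = {
        w: t_i for t_i, topic in enumerate(config.topics) for w in topic.words
    }

    pre_conc, post_conc = config.era_concentrations
    records: list[PublicationRecord] = []
    mixtures: dict[str, list[float]] = {}
    used_variants: dict[str, str] = {}
    counter = 0
    kw_lo, kw_hi = config.keywords_per_pub
    ti_lo, ti_hi = config.title_length
    ab_lo, ab_hi = config.abstract_length
    vocab_arr = np.array(vocab)
    for year in range(config.year_start, config.year_end + 1):
        conc = post_conc if year >= config.tau else pre_conc
        for _ in range(counts[year]):
            pub_id = f"pub{counter:06d}"
            counter += 1
            theta = rng.dirichlet(conc)
            word_dist = theta @ topic_word

            n_kw = int(rng.integers(kw_lo, kw_hi + 1))
            kws: list[str] = []
            for w in rng.choice(vocab_arr, size=n_kw, p=word_dist):
                kws.append(str(w))
            if rng.random() < config.search_term_rate:
                kws.append(SEARCH_TERM)
            # dedupe, keep order, then maybe swap in a lexical variant
            kws = list(dict.fromkeys(kws))
            emitted = []
            for kw in kws:
                if config.variant_rate > 0 and rng.random() < config.variant_rate:
                    options = _variants_for(kw)
                    variant = options[int(rng.integers(0, len(options)))]
                    used_variants[variant] = kw
                    emitted.append(variant)
                else:
                    emitted.append(kw)

            n_title = int(rng.integers(ti_lo, ti_hi + 1))
            n_abstract = int(rng.integers(ab_lo, ab_hi + 1))
            title = " ".join(rng.choice(vocab_arr, size=n_title, p=word_dist))
            abstract = " ".join(rng.choice(vocab_arr, size=n_abstract, p=word_dist))

            records.append(
                PublicationRecord(
                    id=pub_id, year=year, title=title, abstract=abstract,
                    keywords=emitted,
                )
            )
            mixtures[pub_id] = [float(x) for x in theta]

    truth = GroundTruth(
        doc_mixtures=mixtures,
        keyword_topic=keyword_topic,
        annual_counts=counts,
        era_by_year={
            y: ("post" if y >= config.tau else "pre")
            for y in range(config.year_start, config.year_end + 1)
        },
        synonym_map=SynonymMap(entries=dict(used_variants)),
    )
    return Corpus(records=records), truth


def emit_fixture(config: SynthConfig, path) -> dict[str, Path]:
    """Write corpus CSV + synonym TSV + ground-truth JSON under ``path``."""
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus, truth = generate_corpus(config)
    files = {
        "corpus": outdir / "corpus.csv",
        "synonyms": outdir / "synonyms.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_publications(corpus, files["corpus"])
    truth.synonym_map.to_tsv(files["synonyms"])
    truth.to_json(files["ground_truth"])
    return files
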