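"""End-to-end orchestration of the literature-trend analysis.

One configuration drives: ingest -> year threshold filter -> keyword
normalization -> growth fit -> period split -> per-period keyword panels
-> year clustering with bootstrap stability and enrichment -> per-period
co-occurrence networks with transitivity CIs -> per-period LDA with
coherence-based k selection and topic-word networks -> cross-method
overlap reports.  All randomness derives from one global seed, fanned out
to per-stage seeds, so any stage can be re-run in isolation and two runs
with the same configuration are numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    KeywordYearMatrix, bootstrap_cluster_stability, build_matrix, enrichment,
    top_keywords, union_keywords, ward_cluster_years,
)
from .conet import (
    bootstrap_transitivity_ci, build_network, compute_cooccurrence,
    global_transitivity, write_network,
)
from .corpus import Corpus, filter_years_by_min_count, read_publications, split_by_period
from .netcompare import compare_networks
from .normalize import SynonymMap, normalize_corpus, stem_keyword
from .synth import SynthConfig, generate_corpus
from .topics import build_documents, select_k, topic_top_words, topic_word_network
from .trends import annual_counts, fit_exponential, keyword_proportion_series

log = logging.getLogger(__name__)

_STAGES = ["synth", "cluster_boot", "conet_pre", "conet_post", "lda_pre", "lda_post"]

# file names the run directory is expected to contain
DECLARED_OUTPUTS = [
    "annual_counts.tsv",
    "growth_fit.json",
    "keyword_proportions.tsv",
    "dendrogram.nwk",
    "merge_table.tsv",
    "heatmap_matrix.tsv",
    "cluster_stability.tsv",
    "enrichment.tsv",
    "keyword_network_pre.graphml",
    "keyword_network_post.graphml",
    "topic_network_pre.graphml",
    "topic_network_post.graphml",
    "topic_summaries.json",
    "comparison.json",
]


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults reproduce the study's stated choices."""

    corpus_csv: str | None = None
    synonym_tsv: str | None = None
    synth: SynthConfig | None = None
    boundary_year: int = 2006
    min_pubs_per_year: int = 5
    top_k: int = 50
    search_term: str = "apis mellifera"
    n_boot: int = 1000
    n_year_clusters: int = 6
    k_grid: list[int] = field(default_factory=lambda: [20, 50, 70, 90, 110, 140])
    chosen_k: int | None = 20     # None -> coherence argmax
    lda_iterations: int = 50
    top_words_summary: int = 10
    top_words_network: int = 5
    proportion_keywords: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str = "beelit_run"

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s % (2**31)) for name, s in zip(_STAGES, state)}


def _stage(name):
    log.info("pipeline stage: %s", name)


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the result bundle.

    Every stage failure is re-raised with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    bundle: dict = {"outdir": str(outdir)}

    stage = "ingest"
    try:
        _stage(stage)
        if config.synth is not None:
            synth_cfg = dataclasses.replace(config.synth, seed=seeds["synth"])
            corpus, truth = generate_corpus(synth_cfg)
            synmap = truth.synonym_map
            bundle["ground_truth"] = truth
        elif config.corpus_csv:
            corpus = read_publications(config.corpus_csv)
            synmap = (
                SynonymMap.from_tsv(config.synonym_tsv)
                if config.synonym_tsv else SynonymMap()
            )
        else:
            raise ValueError("config needs either corpus_csv or synth")

        stage = "filter"
        _stage(stage)
        filtered = filter_years_by_min_count(corpus, config.min_pubs_per_year)
        bundle["n_records"] = len(filtered)

        stage = "trends"
        _stage(stage)
        counts = annual_counts(filtered)
        fit = fit_exponential(counts)
        bundle["annual_counts"] = counts
        bundle["growth_fit"] = fit
        pd.DataFrame(
            {"year": list(counts), "count": [int(c) for c in counts.values()]}
        ).to_csv(outdir / "annual_counts.tsv", sep="\t", index=False)
        with open(outdir / "growth_fit.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(fit), fh, indent=2)

        stage = "normalize"
        _stage(stage)
        norm = normalize_corpus(filtered, synmap)
        stemmed_search = stem_keyword(config.search_term)
        exclude = {stemmed_search}

        prop_rows = []
        for kw in config.proportion_keywords:
            for year, p in keyword_proportion_series(norm, kw).items():
                prop_rows.append({"year": year, "keyword": kw, "proportion": p})
        pd.DataFrame(prop_rows, columns=["year", "keyword", "proportion"]).to_csv(
            outdir / "keyword_proportions.tsv", sep="\t", index=False
        )

        stage = "split"
        _stage(stage)
        pre, post = split_by_period(norm, config.boundary_year)
        bundle["n_pre"], bundle["n_post"] = len(pre), len(post)

        stage = "keyword-panels"
        _stage(stage)
        top_pre = top_keywords(pre, config.top_k, exclude)
        top_post = top_keywords(post, config.top_k, exclude)
        union = union_keywords(top_pre, top_post)
        bundle["top_pre"], bundle["top_post"], bundle["union"] = top_pre, top_post, union

        stage = "year-clustering"
        _stage(stage)
        matrix = build_matrix(norm, union)
        clustering = ward_cluster_years(matrix)
        stability = bootstrap_cluster_stability(
            matrix, n_boot=config.n_boot, n_clusters=config.n_year_clusters,
            seed=seeds["cluster_boot"],
        )
        clustering.stability = stability
        enrich = enrichment(matrix, clustering, config.n_year_clusters, top_n=3)
        bundle["matrix"] = matrix
        bundle["clustering"] = clustering
        bundle["enrichment"] = enrich
        _write_clustering(outdir, matrix, clustering, enrich, config.n_year_clusters)

        stage = "cooccurrence-networks"
        _stage(stage)
        networks, transitivity, cis = {}, {}, {}
        for label, part, panel in (("pre", pre, top_pre), ("post", post, top_post)):
            stats = compute_cooccurrence(part, panel)
            net = build_network(stats)
            networks[label] = net
            transitivity[label] = global_transitivity(net)
            cis[label] = bootstrap_transitivity_ci(
                part, panel, n_boot=config.n_boot, seed=seeds[f"conet_{label}"]
            )
            write_network(net, outdir / f"keyword_network_{label}.graphml")
        bundle["keyword_networks"] = networks
        bundle["keyword_transitivity"] = transitivity
        bundle["keyword_transitivity_ci"] = cis

        stage = "topic-models"
        _stage(stage)
        topic_nets, topic_payload, chosen = {}, {}, {}
        raw_pre, raw_post = split_by_period(filtered, config.boundary_year)
        for label, part in (("pre", raw_pre), ("post", raw_post)):
            docs = build_documents(part, period=label)
            table, k, models = select_k(
                docs, config.k_grid, seed=seeds[f"lda_{label}"],
                iterations=config.lda_iterations, chosen_k=config.chosen_k,
            )
            model = models[k]
            summaries = topic_top_words(model, n=config.top_words_summary)
            net = topic_word_network(
                topic_top_words(model, n=config.top_words_network),
                top_n=config.top_words_network,
            )
            topic_nets[label] = net
            chosen[label] = k
            topic_payload[label] = {
                "chosen_k": k,
                "coherence": table.to_dict(orient="records"),
                "topics": [
                    {"topic_id": s.topic_id, "words": s.words, "scores": s.scores}
                    for s in summaries
                ],
            }
            write_network(net, outdir / f"topic_network_{label}.graphml")
        with open(outdir / "topic_summaries.json", "w", encoding="utf-8") as fh:
            json.dump(topic_payload, fh, indent=2)
        bundle["topic_networks"] = topic_nets
        bundle["chosen_k"] = chosen
        bundle["topic_transitivity"] = {
            lab: global_transitivity(net) for lab, net in topic_nets.items()
        }

        stage = "network-comparison"
        _stage(stage)
        overlaps = {}
        for label in ("pre", "post"):
            overlaps[label] = compare_networks(topic_nets[label], networks[label])
        bundle["overlap"] = overlaps
        comparison = {
            "keyword_transitivity": transitivity,
            "keyword_transitivity_ci": {k: list(v) for k, v in cis.items()},
            "topic_transitivity": bundle["topic_transitivity"],
            "overlap": {
                lab: {
                    "node_overlap_fraction": rep.node_overlap_fraction,
                    "edge_overlap_fraction": rep.edge_overlap_fraction,
                }
                for lab, rep in overlaps.items()
            },
        }
        with open(outdir / "comparison.json", "w", encoding="utf-8") as fh:
            json.dump(comparison, fh, indent=2)

        stage = "manifest"
        _stage(stage)
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": _config_dict(config),
            "outputs": list(DECLARED_OUTPUTS),
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        bundle["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_clustering(outdir: Path, matrix, clustering, enrich, n_clusters: int) -> None:
    with open(outdir / "dendrogram.nwk", "w", encoding="utf-8") as fh:
        fh.write(clustering.to_newick() + "\n")
    clustering.merge_table().to_csv(outdir / "merge_table.tsv", sep="\t", index=False)
    # heatmap matrix with year columns ordered by cluster label then year
    labels = clustering.cut(n_clusters)
    order = sorted(matrix.years, key=lambda y: (labels[y], y))
    frame = matrix.to_frame()[order]
    frame.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    pd.DataFrame(
        [{"cluster": lab, "stability": s} for lab, s in sorted(clustering.stability.items())]
    ).to_csv(outdir / "cluster_stability.tsv", sep="\t", index=False)
    enrich.scores.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
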