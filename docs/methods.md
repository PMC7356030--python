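# Methods

This note documents the models and procedures implemented in `beelit`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where the
underlying methodology leaves room.

## Corpus model

A corpus is a list of publication records (id, 4-digit year, title,
abstract, author-keyword list) read from a Scopus-dialect CSV (UTF-8,
header row, keywords in one cell delimited by ";" with optional
whitespace). Rows with unparseable years are skipped and counted in a
load report rather than aborting the read: exports are messy, and a
handful of malformed rows should not block an analysis. Years with fewer
than `min_pubs_per_year` publications (default 5) are dropped before any
analysis; retained years need not be contiguous. Period splitting is a
strict year comparison (records with year ≥ boundary go to the late
period); no sub-year dates exist in the export.

## Keyword normalization

Normalization is synonym mapping **then** Porter stemming, per record,
with set-semantics deduplication afterwards. The order is fixed because
synonym tables are curated against surface forms, not stems. Synonym
matching is case-insensitive exact string matching — no fuzzy matching,
because a curated table encodes exactly the variants its curator saw.
Multi-word keywords are stemmed token-wise with function words inside
them preserved ("division of labor" → "divis of labor"), which keeps
normalized keywords recognizable in reports. The map is validated to be
idempotent (no canonical form may itself appear as a variant key).

The Porter stemmer is implemented in-package from the original five-step
rule table, with words of one or two letters returned unchanged. It is
pinned by a regression suite of frozen input/output pairs covering both
the domain vocabulary ("foraging" → "forag", "colonies" → "coloni") and
the canonical rule exercises ("generalization" → "gener",
"controlling" → "control").

## Publication growth

Annual counts are fitted as y = a·e^{b·x} by ordinary least squares of
ln y on x = year − x_origin (default: first retained year). The log-OLS
form is deterministic and matches how R² is conventionally reported for
such fits; a nonlinear fit would weight the (much larger) recent years
more heavily. Zero-count years are dropped with a warning rather than
offset: ln 0 is undefined and a pseudo-count would bias b. At least three
positive years are required. The doubling time is ln 2 / b (infinite for
b = 0) and is invariant to the choice of x_origin. For a constant series
the slope is set to exactly 0 (not float noise) so the doubling time is
cleanly infinite. The fitted year range is configurable rather than
hard-coded, since which years enter a published regression is often
under-documented.

## Year clustering

Years are feature vectors of per-year **relative** keyword frequencies
(proportion of that year's publications containing the keyword) over the
union of the two periods' top-k panels; relative frequencies rather than
raw counts, so that exponential growth does not dominate the geometry.
Distance is Euclidean, unstandardized — frequencies are already on a
common [0, 1] scale.

Agglomeration uses the classical **ward.D** convention: the
Lance–Williams recurrence with coefficients αᵢ = (nᵢ+nₖ)/(nᵢ+nⱼ+nₖ),
β = −nₖ/(nᵢ+nⱼ+nₖ), γ = 0 applied to the distance matrix *as given*
(unsquared). SciPy's `ward` implements the ward.D2 (squared-distance)
convention, so the recurrence is implemented directly; ward.D2 is
available behind a flag. Both variants are verified against R `hclust`
to 1e-9 on frozen and randomly generated instances. Ties in the minimum
inter-cluster distance break on the smallest active index pair, making
merge order deterministic; the merge table uses SciPy's linkage layout so
`scipy.cluster.hierarchy` cutting/plotting applies directly.

Cluster stability resamples the **years** (the clustered observations)
with replacement, re-clusters each resample, and credits each original
cluster with its best Jaccard match among the bootstrap clusters,
computed over the years present in the resample; the reported statistic
is the mean over replicates (clusters with no surviving years in a
replicate are skipped for that replicate). The number of clusters at
which stability and enrichment are reported is a configuration value —
dendrograms are read by eye in practice, and no automatic cut-height
rule is imposed.

Enrichment works on the **count** matrix: expectedᵢⱼ = (row sumᵢ ×
column sumⱼ) / grand total, ratio = observed/expected (defined as 0 where
expected is 0), and the per-cluster score of a keyword is the geometric
mean of (ratio + 0.001) over the cluster's years. The 0.001 is added to
each ratio *before* the geometric mean: that is the only placement that
prevents a single zero year from annihilating the product while leaving
nonzero ratios essentially unchanged. A consequence worth knowing when
reading the tables: a keyword absent in even a few of a cluster's years
is strongly penalized, so sparse early-year clusters may show no strongly
enriched terms at all.

## Co-occurrence networks

For a fixed keyword panel (top 50 per period by publication count, ties
lexicographic, the search term removed *after* ranking so a 50-panel
becomes 49), co-occurrence is counted over whole publications: a keyword
counts once per publication regardless of repetition. The observed
probability is O = nᵢⱼ/N — normalized by corpus size so that it is
commensurable with the independence expectation E = p(i)·p(j). An edge
exists iff O > E strictly, weighted by the (positive) excess O − E, so a
thicker edge always means more co-occurrence than chance. Isolated
keywords remain in the node set. No multiple-testing control is applied
to edges: the raw O > E criterion *is* the method being implemented.

Global transitivity is 3 × triangles / connected triplets (0 when no
triplets exist), ignoring weights. Its bootstrap CI resamples
**publications** with replacement, holding the keyword panel fixed —
re-selecting the panel each replicate would conflate panel-selection
noise with network noise. Intervals are percentile intervals at the
requested level (default 95%, default 1000 replicates; a warning is
logged below 100).

A property of this statistic worth stating: edges near the O ≈ E
knife-edge flip under resampling, and the spurious edges a resample adds
tend to create open triplets rather than triangles, so on weakly
structured corpora the bootstrap distribution can sit systematically
below the full-sample value. The CIs are therefore most meaningful — and
are tested — on corpora with clear co-occurrence structure, and are best
used as the original method uses them: to compare two periods, not as
exact coverage statements.

## Topic modeling

Documents are title + joined keywords + abstract, lowercased, stripped
of every non-alphabetic character (which removes numbers, punctuation
and scientific notation wholesale), filtered of single-letter residues
and — by default — of a standard English stop-word list, then Porter
stemmed. Stop-word removal is defaulted on because LDA on raw text is
otherwise dominated by function words; a flag preserves the literal
no-stop-word reading. Duplicate tokens arising from a term appearing in
both keywords and abstract are kept (no reweighting).

LDA is fitted by batch variational inference (scikit-learn), which is
deterministic under a fixed seed. Default hyperparameters: symmetric
document-topic concentration α = 1/k, topic-word concentration
η = 0.01, 50–100 iterations; all recorded in the model metadata. The
number of topics is chosen on a grid (default 20/50/70/90/110/140) by
the c_v coherence of each model's top-10 words; the pipeline default
pins k = 20 (selection in practice blends coherence with manual
inspection) while `chosen_k=None` takes the pure argmax, smaller k
winning ties.

c_v coherence: boolean sliding windows of width 110 tokens (documents
shorter than the window contribute one window) give occurrence and
joint-occurrence counts for the tracked top words; each top word gets an
NPMI context vector over its topic's top words (self-NPMI = 1, words
absent from all windows get their count smoothed to 1, and a small ε
guards the logs); a topic's score is the mean cosine similarity over
word pairs and the model score is the mean over topics, clipped into
[0, 1].

Top words are ranked by LDAvis-style relevance
λ·log p(w|t) + (1−λ)·log[p(w|t)/p(w)] with λ = 1 by default (plain
within-topic probability); λ = 0 ranks by lift and promotes
topic-exclusive words. The topic-word network makes each topic's top-5
words a clique; edge weight counts the topics in which a pair co-occurs,
so topics sharing a word fuse into larger components.

## Network comparison

Topic-network nodes are single stems; keyword-network nodes may be
multi-word. A subject node matches a reference node on equality or
contiguous substring containment in either direction, requiring the
contained name to be ≥ 3 characters (1–2 letter stems would match
promiscuously; the exact-match path is exempt). Edges match when their
endpoint pairs can be aligned so both endpoints match (case 1: both
exact; 2: one exact, one substring; 3: both substring), greedy
first-match over lexicographically sorted reference edges, each subject
edge counted once. Fractions are computed over the subject (topic)
network; no one-to-one node correspondence is enforced. Overlap is
therefore monotone in the reference network.

## Synthetic-data generator

The generator emulates the statistical skeleton of a retrieved
literature: annual counts round(a·e^{b·(year−start)}) (defaults a = 6.29,
b = 0.087 over 1957–2017 — about 14k records doubling every 8 years); a
regime-change year τ (default 1992) switching the Dirichlet
concentration of document-topic mixtures between eras; eight planted
honey bee domain topics (foraging/behavior, pollination,
physiology/taxonomy, apiculture products, varroa/pathology, genomics,
colony health, neuroscience) over mostly disjoint vocabularies;
keyword sets (3–8 per publication) drawn topic-first from the mixture,
with the search term "apis mellifera" attached to 60% of publications;
titles (6–12 tokens) and abstracts (60–120 tokens) drawn i.i.d. from the
same mixture distribution, so keyword networks and topic networks live
on comparable vocabularies. With probability `variant_rate` (default
0.1) a keyword is emitted as a registered lexical variant ("honey bee
X", "honey-bee X", or the four observed search-term spellings), and the
variant → canonical pair is recorded in the emitted synonym map — making
normalization exactly invertible and therefore testable, which manual
curation of real data never is.

What the generator deliberately does **not** emulate: natural-language
syntax (titles/abstracts are bags of words), correlated keyword styles
across authors or journals, citation structure, indexing noise beyond
the registered variants, and vocabulary drift within an era. Passing
recovery tests therefore demonstrate that the pipeline's inferential
steps work when their generative assumptions hold, not that real
literatures satisfy those assumptions.

Test and script problem sizes are scaled-down versions of the default
conditions (hundreds to ~1.4k records, 200–500 bootstrap replicates,
small k-grids); the library defaults keep the full-scale settings (1000
bootstrap replicates, the six-value k-grid). Recovery tests with
near-pure documents use era concentrations around 0.1 — coherence-based
model selection discriminates the true topic count only when documents
are mostly about one topic, which is itself a property of the metric
worth knowing.

## Pipeline and reproducibility

One global seed is expanded through `numpy.random.SeedSequence` into
per-stage seeds (generator, cluster bootstrap, per-period network
bootstraps, per-period LDA), each below 2³¹, so stages can be re-run in
isolation and a full re-run with the same configuration is numerically
identical. Every run writes 14 declared outputs (growth tables and fit,
dendrogram in Newick plus merge table, cluster-ordered heatmap matrix,
stability and enrichment tables, per-period keyword and topic networks
as GraphML, topic summaries with the coherence table, and a combined
transitivity/overlap comparison) plus a manifest recording versions,
seeds and configuration. Networks can also be exported as GEXF or plain
edge-list TSV.

## Known limitations

- ward.D on unsquared Euclidean distances is not variance-minimizing in
  the strict Ward sense (that is ward.D2); it is provided because it is
  the convention named by the method being reproduced, and both are
  available.
- The O > E edge rule has no significance control; near-threshold edges
  are noisy, with the bootstrap consequences described above.
- c_v coherence is computed over each topic's own top words only;
  corpus-level ceiling effects can compress differences between models
  on very homogeneous corpora.
- Exact reproduction of a published topic model requires its seeds and
  hyperparameters; when those are unreported, only structural properties
  (coherence-optimal k, recovery on planted corpora) are checkable.
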