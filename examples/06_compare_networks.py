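"""Compare a topic-word network against the keyword co-occurrence network.

Node names come from different processes (single stems vs multi-word
author keywords), so matching admits substring containment; the report
says what fraction of topic-network nodes and edges the keyword network
also contains.
"""

from beelit import (
    build_documents, build_network, compare_networks, compute_cooccurrence,
    normalize_corpus, stem_keyword, top_keywords, topic_top_words,
    topic_word_network, train_lda,
)
from beelit.synth import SEARCH_TERM, SynthConfig, generate_corpus

cfg = SynthConfig(year_start=1995, year_end=2010, amplitude=8.0, rate=0.05,
                  tau=2003, seed=5)
corpus, truth = generate_corpus(cfg)
norm = normalize_corpus(corpus, truth.synonym_map)

panel = top_keywords(norm, 50, exclude={stem_keyword(SEARCH_TERM)})
keyword_net = build_network(compute_cooccurrence(norm, panel))

model = train_lda(build_documents(corpus), k=8, seed=0, iterations=30)
topic_net = topic_word_network(topic_top_words(model, n=5), top_n=5)

report = compare_networks(topic_net, keyword_net)
print(f"node overlap: {report.node_overlap_fraction:.1%}")
print(f"edge overlap: {report.edge_overlap_fraction:.1%}")
for m in report.edge_matches[:5]:
    print(" matched edge", m["subject"], "~", m["reference"], f"(case {m['case']})")
# Node overlap typically exceeds edge overlap: the two methods agree on
# the important terms more than on which terms belong together.
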