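"""Collapse lexical keyword variants via a synonym map plus Porter stemming.

Four observed spellings of the search term map to one canonical form, and
inflectional variants ("foraging"/"forage") stem to a common root.
"""

from beelit import SynonymMap, normalize_corpus
from beelit.corpus import Corpus, PublicationRecord

synmap = SynonymMap(entries={
    "honey-bee (apis mellifera)": "apis mellifera",
    "honey-bee apis mellifera": "apis mellifera",
    "honey bee a. mellifera": "apis mellifera",
    "honey bee apis mellifera": "apis mellifera",
})

corpus = Corpus(records=[
    PublicationRecord(id="p1", year=2001,
                      keywords=["Honey-Bee Apis Mellifera", "Foraging"]),
    PublicationRecord(id="p2", year=2002,
                      keywords=["honey bee a. mellifera", "forage", "Colonies"]),
])

for rec in normalize_corpus(corpus, synmap).records:
    print(rec.id, "->", rec.keywords)
# Both records now carry the single normalized form "api mellifera", and
# "Foraging"/"forage" have collapsed to the stem "forag".
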