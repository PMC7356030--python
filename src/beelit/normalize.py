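"""Keyword normalization: synonym mapping followed by Porter stemming.

Author-assigned keywords vary lexically ("honey-bee apis mellifera",
"honey bee a. mellifera", ...).  A manually curated synonym table maps
such variants to one canonical surface form; stemming then collapses
inflectional variants.  The order is fixed — synonyms first, stemming
second — because the curated table is written against surface forms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .corpus import Corpus, PublicationRecord
from .porter import stem


@dataclass
class SynonymMap:
    """Variant -> canonical keyword mapping (case-insensitive, idempotent)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cleaned: dict[str, str] = {}
        for variant, canonical in self.entries.items():
            v, c = variant.strip().lower(), canonical.strip().lower()
            if not v or not c:
                raise ValueError("synonym map keys and values must be non-empty")
            cleaned[v] = c
        canonicals = set(cleaned.values())
        offenders = canonicals & {k for k, v in cleaned.items() if k != v}
        if offenders:
            raise ValueError(
                f"canonical forms also appear as variants (map not idempotent): {sorted(offenders)}"
            )
        self.entries = cleaned

    def get(self, keyword: str) -> str:
        kw = keyword.strip().lower()
        return self.entries.get(kw, kw)

    @classmethod
    def from_tsv(cls, path) -> "SynonymMap":
        """Read a two-column TSV (variant TAB canonical); '#' lines are comments."""
        entries = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
                entries[parts[0]] = parts[1]
        return cls(entries=entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# variant\tcanonical\n")
            for variant in sorted(self.entries):
                fh.write(f"{variant}\t{self.entries[variant]}\n")


# A normalized corpus is a Corpus whose records carry deduplicated,
# canonicalized, stemmed keyword lists (lowercase).
NormalizedCorpus = Corpus


def repeated_keywords(corpus: Corpus) -> set[str]:
    """Lowercased keywords occurring more than once across the whole corpus.

    This is the scope on which manual synonym curation operates: singleton
    keywords are left alone.
    """
    counts = Counter(
        kw.strip().lower() for r in corpus.records for kw in r.keywords if kw.strip()
    )
    return {kw for kw, c in counts.items() if c > 1}


def apply_synonyms(keywords: list[str], synonym_map: SynonymMap) -> list[str]:
    """Lowercase each keyword and replace mapped variants; order preserved."""
    return [synonym_map.get(kw) for kw in keywords]


def stem_keyword(term: str) -> str:
    """Stem a (possibly multi-word) keyword token-wise with Porter's algorithm."""
    term = term.strip().lower()
    if not term:
        raise ValueError("cannot stem an empty keyword")
    return " ".join(stem(tok) for tok in term.split())


def normalize_keywords(keywords: list[str], synonym_map: SynonymMap) -> list[str]:
    """lowercase -> synonym map -> stem -> deduplicate (first occurrence kept)."""
    seen: dict[str, None] = {}
    for kw in apply_synonyms(keywords, synonym_map):
        if not kw:
            continue
        seen.setdefault(stem_keyword(kw), None)
    return list(seen)


def normalize_corpus(corpus: Corpus, synonym_map: SynonymMap) -> NormalizedCorpus:
    """Normalize every record's keyword list; record order is unchanged."""
    records = [
        PublicationRecord(
            id=r.id,
            year=r.year,
            title=r.title,
            abstract=r.abstract,
            keywords=normalize_keywords(r.keywords, synonym_map),
        )
        for r in corpus.records
    ]
    return Corpus(records=records, year_range=corpus.year_range)
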