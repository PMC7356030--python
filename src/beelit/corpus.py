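"""Reading, filtering and period-splitting of bibliographic exports.

The on-disk format is the Scopus CSV dialect: one row per publication,
UTF-8 with a header row, author keywords in a single cell delimited by
"; ".  Column names are configurable; the defaults match a raw Scopus
export ("Title", "Year", "Abstract", "Author Keywords").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_COLUMNS = {
    "title": "Title",
    "year": "Year",
    "abstract": "Abstract",
    "keywords": "Author Keywords",
}

_KEYWORD_SPLIT = re.compile(r"\s*;\s*")


@dataclass
class PublicationRecord:
    """One bibliographic record."""

    id: str
    year: int
    title: str = ""
    abstract: str = ""
    keywords: list[str] = field(default_factory=list)


@dataclass
class LoadReport:
    rows_read: int = 0
    rows_parsed: int = 0
    rows_skipped: int = 0


@dataclass
class Corpus:
    """A set of publication records with the retained year range."""

    records: list[PublicationRecord]
    year_range: tuple[int, int] | None = None
    load_report: LoadReport | None = None

    def __post_init__(self):
        if self.year_range is None and self.records:
            years = [r.year for r in self.records]
            self.year_range = (min(years), max(years))

    def __len__(self) -> int:
        return len(self.records)

    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})


class SchemaError(ValueError):
    """A required column is absent from the export."""


def split_keyword_cell(cell: str) -> list[str]:
    """Split a Scopus keyword cell on ';' (with optional whitespace)."""
    if not cell or not cell.strip():
        return []
    return [tok.strip() for tok in _KEYWORD_SPLIT.split(cell.strip()) if tok.strip()]


def read_publications(
    path,
    dialect: str = "scopus-csv",
    columns: dict[str, str] | None = None,
) -> Corpus:
    """Read a Scopus-style CSV export into a :class:`Corpus`.

    Rows whose year cell cannot be parsed as a 4-digit integer are skipped
    and counted in the load report (attached to the corpus and logged).
    A missing required column raises :class:`SchemaError`.
    """
    if dialect != "scopus-csv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    for role in ("title", "year"):
        if cols[role] not in df.columns:
            raise SchemaError(f"required column {cols[role]!r} missing from {path}")

    report = LoadReport(rows_read=len(df))
    records: list[PublicationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        year_cell = str(row.get(cols["year"], "")).strip()
        try:
            year = int(float(year_cell))
            if not 1000 <= year <= 9999:
                raise ValueError
        except ValueError:
            report.rows_skipped += 1
            continue
        records.append(
            PublicationRecord(
                id=f"row{i}",
                year=year,
                title=str(row.get(cols["title"], "")),
                abstract=str(row.get(cols.get("abstract", ""), "")),
                keywords=split_keyword_cell(str(row.get(cols.get("keywords", ""), ""))),
            )
        )
    report.rows_parsed = len(records)
    log.info(
        "read %s: %d rows read, %d parsed, %d skipped",
        path, report.rows_read, report.rows_parsed, report.rows_skipped,
    )
    corpus = Corpus(records=records)
    corpus.load_report = report
    return corpus


def write_publications(corpus: Corpus, path, columns: dict[str, str] | None = None) -> None:
    """Write a corpus back to the Scopus CSV dialect (round-trip safe)."""
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.DataFrame(
        {
            cols["title"]: [r.title for r in corpus.records],
            cols["year"]: [r.year for r in corpus.records],
            cols["abstract"]: [r.abstract for r in corpus.records],
            cols["keywords"]: ["; ".join(r.keywords) for r in corpus.records],
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def annual_record_counts(corpus: Corpus) -> dict[int, int]:
    counts: dict[int, int] = {}
    for r in corpus.records:
        counts[r.year] = counts.get(r.year, 0) + 1
    return counts


def filter_years_by_min_count(corpus: Corpus, min_count: int) -> Corpus:
    """Retain only years with at least ``min_count`` publications.

    Mirrors the inclusion threshold used when assembling the study corpus;
    retained years need not be contiguous.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not corpus.records:
        return Corpus(records=[], year_range=None)
    counts = annual_record_counts(corpus)
    kept_years = {y for y, c in counts.items() if c >= min_count}
    records = [r for r in corpus.records if r.year in kept_years]
    if not records:
        return Corpus(records=[], year_range=None)
    return Corpus(records=records, year_range=(min(kept_years), max(kept_years)))


def split_by_period(corpus: Corpus, boundary_year: int) -> tuple[Corpus, Corpus]:
    """Partition into records before vs. from ``boundary_year`` (strict <)."""
    early = [r for r in corpus.records if r.year < boundary_year]
    late = [r for r in corpus.records if r.year >= boundary_year]
    return (
        Corpus(records=early, year_range=None),
        Corpus(records=late, year_range=None),
    )
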