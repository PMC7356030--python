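"""Publication-growth fitting and per-keyword temporal prevalence.

Annual publication counts in a growing field are well described by
y(x) = a * exp(b * x) with x counted in years from a fixed origin; the
doubling time is ln(2)/b.  The fit is ordinary least squares of ln(count)
on x — deterministic, with R^2 reported on the log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, annual_record_counts
from .normalize import NormalizedCorpus

log = logging.getLogger(__name__)

YearSeries = dict[int, float]


@dataclass
class GrowthFit:
    """Exponential growth fit y = a * exp(b * (year - x_origin))."""

    a: float
    b: float
    r_squared: float
    n: int
    doubling_time: float
    x_origin: int

    def predict(self, year: int | np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * (np.asarray(year) - self.x_origin))


def doubling_time(b: float) -> float:
    """Years for the annual count to double at growth rate ``b`` per year."""
    if b == 0:
        return math.inf
    return math.log(2.0) / b


def annual_counts(corpus: Corpus) -> YearSeries:
    """Publications per year; years with no records are omitted."""
    return {y: float(c) for y, c in sorted(annual_record_counts(corpus).items())}


def fit_exponential(series: YearSeries, x_origin: int | None = None) -> GrowthFit:
    """Log-linear OLS fit of an annual count series.

    Zero-count years are dropped (ln undefined) with a logged warning;
    at least three positive points are required.
    """
    positive = {y: v for y, v in series.items() if v > 0}
    dropped = len(series) - len(positive)
    if dropped:
        log.warning("fit_exponential: dropped %d non-positive years", dropped)
    if len(positive) < 3:
        raise ValueError("need at least 3 positive-count years to fit")
    years = np.array(sorted(positive), dtype=float)
    if x_origin is None:
        x_origin = int(years[0])
    x = years - x_origin
    logy = np.log(np.array([positive[int(y)] for y in years], dtype=float))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    if ss_tot == 0.0:
        # constant series: slope exactly zero, not float noise
        slope, intercept = 0.0, float(logy.mean())
        r2 = 1.0
    else:
        slope, intercept = np.polyfit(x, logy, 1)
        resid = logy - (intercept + slope * x)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return GrowthFit(
        a=float(np.exp(intercept)),
        b=float(slope),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n=len(positive),
        doubling_time=doubling_time(float(slope)),
        x_origin=x_origin,
    )


def keyword_proportion_series(corpus: NormalizedCorpus, keyword: str) -> YearSeries:
    """Fraction of each year's publications containing ``keyword``.

    The keyword must already be in normalized (synonymized + stemmed) form.
    """
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for r in corpus.records:
        totals[r.year] = totals.get(r.year, 0) + 1
        if keyword in r.keywords:
            hits[r.year] = hits.get(r.year, 0) + 1
    return {y: hits.get(y, 0) / totals[y] for y in sorted(totals)}
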