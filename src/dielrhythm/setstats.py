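"""Set overlap and enrichment statistics for rhythm call tables.

Covers the reporting layer of the analysis: exact three-set Euler region
counts, hypergeometric over/under-representation of functional
categories, Pearson chi-square comparison of categorical distributions,
peak-time histograms, day/night phase fractions and the percentage
rounding used in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class EulerRegions:
    """Cardinalities of the 7 regions of three sets within a universe."""

    a_only: int
    b_only: int
    c_only: int
    ab: int
    ac: int
    bc: int
    abc: int
    universe_size: int

    @property
    def union_size(self) -> int:
        return (
            self.a_only + self.b_only + self.c_only
            + self.ab + self.ac + self.bc + self.abc
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "A": self.a_only, "B": self.b_only, "C": self.c_only,
            "AB": self.ab, "AC": self.ac, "BC": self.bc, "ABC": self.abc,
        }


def euler_regions(
    set_a: Iterable, set_b: Iterable, set_c: Iterable, universe: Iterable
) -> EulerRegions:
    """Exact region counts for a three-set Euler diagram."""
    a, b, c, u = set(set_a), set(set_b), set(set_c), set(universe)
    outside = (a | b | c) - u
    if outside:
        raise StatsError(f"elements outside the universe: {sorted(outside)[:3]}")
    abc = a & b & c
    return EulerRegions(
        a_only=len(a - b - c),
        b_only=len(b - a - c),
        c_only=len(c - a - b),
        ab=len((a & b) - abc),
        ac=len((a & c) - abc),
        bc=len((b & c) - abc),
        abc=len(abc),
        universe_size=len(u),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over/under-representation of one category.

    k of the n foreground elements carry the category; K of the N
    background elements do.  ``p_over`` is the upper tail P(X >= k),
    ``p_under`` the lower tail P(X <= k); the call follows the
    0.05/0.95 rule on the upper tail.
    """

    category: str
    k: int
    n: int
    K: int
    N: int
    p_over: float
    p_under: float
    call: str  # over | under | none


def hypergeom_over_under(
    k: int, n: int, K: int, N: int, category: str = ""
) -> EnrichmentResult:
    """Exact hypergeometric tails and the over/under call."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise StatsError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    dist = stats.hypergeom(N, K, n)
    p_over = float(dist.sf(k - 1))
    p_under = float(dist.cdf(k))
    if p_over < 0.05:
        call = "over"
    elif p_over > 0.95:
        call = "under"
    else:
        call = "none"
    return EnrichmentResult(category, k, n, K, N, p_over, p_under, call)


def enrichment_table(
    annotation: pd.DataFrame,
    foreground: Iterable,
    background: Iterable,
    unannotated_label: str = "unannotated",
) -> pd.DataFrame:
    """Per-category over/under-representation of a foreground set.

    ``annotation`` maps transcript_id -> category (one row per id).
    Transcripts labelled ``unannotated_label`` are kept in the universe
    sizes but not tested as a category.
    """
    cat = annotation.set_index("transcript_id")["category"]
    if cat.index.has_duplicates:
        raise StatsError("annotation has duplicate transcript ids")
    fg, bg = set(foreground), set(background)
    if not fg <= bg:
        raise StatsError("foreground must be a subset of the background")
    n, N = len(fg), len(bg)
    rows = []
    fg_cats = cat[cat.index.isin(fg)]
    bg_cats = cat[cat.index.isin(bg)]
    for category in sorted(set(bg_cats) - {unannotated_label}):
        K = int((bg_cats == category).sum())
        k = int((fg_cats == category).sum())
        res = hypergeom_over_under(k, n, K, N, category=category)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def chisq_compare(
    observed: Sequence[float], reference_props: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against reference proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(reference_props, dtype=float)
    if obs.shape != props.shape:
        raise StatsError("observed and reference lengths differ")
    if not np.isclose(props.sum(), 1.0):
        raise StatsError("reference proportions must sum to 1")
    total = obs.sum()
    if total <= 0:
        raise StatsError("observed total must be positive")
    expected = total * props
    if np.any(expected <= 0):
        raise StatsError(
            "zero expected count; pool categories before testing"
        )
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def phase_histogram(
    phases: Sequence[float], bin_h: float = 2.0, period_h: float = 24.0
) -> dict[str, int]:
    """Counts of peak times in half-open ZT bins [b, b+bin)."""
    n_bins = period_h / bin_h
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise StatsError("bin width must divide the period")
    n_bins = int(round(n_bins))

    def label(i: int) -> str:
        start = i * bin_h
        return f"ZT{int(start):02d}" if float(start).is_integer() else f"ZT{start:g}"

    counts = {label(i): 0 for i in range(n_bins)}
    for ph in phases:
        i = int(np.floor((ph % period_h) / bin_h)) % n_bins
        counts[label(i)] += 1
    return counts


def percent(count: int, total: int) -> float:
    """Percentage rounded to one decimal, half away from zero.

    Integer arithmetic keeps the rounding exact (e.g. 6705 of 9822 is
    68.3).
    """
    if total <= 0:
        raise StatsError("total must be positive")
    if not 0 <= count <= total:
        raise StatsError("count must lie in [0, total]")
    return ((2000 * count + total) // (2 * total)) / 10.0


def day_night_fraction(phases: Sequence[float], photoperiod_h: float) -> float:
    """Fraction of peaks falling in daytime (phase strictly < photoperiod)."""
    ph = np.asarray(list(phases), dtype=float)
    if ph.size == 0:
        raise StatsError("no phases given")
    return float(np.mean(ph < photoperiod_h))
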