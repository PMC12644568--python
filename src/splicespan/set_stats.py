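"""Shared set/overlap statistics: hypergeometric and Fisher tests, BH-FDR,
Jaccard/overlap coefficients, local gene-set enrichment, and the
interval-overlap (IDP-region) test."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from splicespan.io_formats import GenomicInterval


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d) with a = in-both."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def hypergeom_overlap_test(
    k: int, n_a: int, n_b: int, n_universe: int, alternative: str = "greater"
) -> float:
    """Exact tail probability for an overlap of k between a set of size n_a
    and a set of size n_b drawn from a universe of size n_universe.

    ``greater`` is P(X >= k); ``less`` is P(X <= k); ``two_sided`` doubles the
    smaller tail (capped at 1).
    """
    if n_a > n_universe or n_b > n_universe:
        raise ValueError("set larger than universe")
    if k > min(n_a, n_b) or k < max(0, n_a + n_b - n_universe):
        raise ValueError(f"overlap {k} inconsistent with margins")
    dist = stats.hypergeom(n_universe, n_a, n_b)
    if alternative == "greater":
        return float(dist.sf(k - 1))
    if alternative == "less":
        return float(dist.cdf(k))
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(dist.sf(k - 1), dist.cdf(k))))
    raise ValueError(f"unknown alternative {alternative!r}")


def fisher_2x2(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> tuple[float, float]:
    """Conditional exact test on a 2x2 table.

    Returns (p, odds_ratio) with the sample odds ratio a*d / (b*c); the odds
    ratio is ``inf`` when b*c = 0 (and a*d > 0), ``nan`` for 0/0.
    """
    alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[
        alternative
    ]
    res = stats.fisher_exact(table.as_array(), alternative=alt)
    p = float(res.pvalue)
    num, den = table.a * table.d, table.b * table.c
    if den > 0:
        oddsratio = num / den
    else:
        oddsratio = math.inf if num > 0 else math.nan
    return p, oddsratio


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    adjusted_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; NaN when both sets are empty."""
    union = len(a | b)
    return math.nan if union == 0 else len(a & b) / union


def overlap_coefficient(a: set, b: set) -> float:
    """|A∩B| / min(|A|, |B|); NaN when either set is empty."""
    denom = min(len(a), len(b))
    return math.nan if denom == 0 else len(a & b) / denom


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe: int
    odds_ratio: float
    p: float
    fdr: float = math.nan


def gene_set_enrichment(
    genes: set[str],
    background: set[str],
    collection: Mapping[str, set[str]],
    fdr_cutoff: float = 0.15,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of ``genes`` against each set in a GMT
    collection, restricted to ``background``; BH-FDR across sets.

    Returns a DataFrame sorted by p with a ``significant`` column at the
    given FDR cutoff.
    """
    if not background:
        raise ValueError("empty background")
    if not genes <= background:
        raise ValueError("query genes must be a subset of the background")
    n_universe = len(background)
    rows = []
    for set_id in sorted(collection):
        members = collection[set_id] & background
        k = len(genes & members)
        a = k
        b = len(genes) - k
        c = len(members) - k
        d = n_universe - len(genes) - len(members) + k
        p, oddsratio = fisher_2x2(ContingencyTable2x2(a, b, c, d), "greater")
        rows.append(
            EnrichmentResult(
                set_id=set_id,
                overlap=k,
                set_size=len(members),
                query_size=len(genes),
                universe=n_universe,
                odds_ratio=oddsratio,
                p=p,
            )
        )
    df = pd.DataFrame([vars(r) for r in rows]).set_index("set_id")
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["fdr"] < fdr_cutoff
    return df.sort_values("p")


def _any_overlap(
    intervals: Iterable[GenomicInterval], targets: Sequence[GenomicInterval]
) -> bool:
    return any(iv.overlaps(t) for iv in intervals for t in targets)


def region_overlap_test(
    event_regions: Mapping[str, Sequence[GenomicInterval]],
    idp_regions: Sequence[GenomicInterval],
    background_regions: Mapping[str, Sequence[GenomicInterval]],
    alternative: str = "greater",
) -> tuple[float, float, float]:
    """Fisher test of whether target events overlap IDP intervals more often
    than background events.

    An event overlaps when any of its defining intervals shares >= 1 nt with
    any IDP interval.  Returns (p, target_fraction, background_fraction).
    """
    t_hit = sum(_any_overlap(ivs, idp_regions) for ivs in event_regions.values())
    t_tot = len(event_regions)
    b_hit = sum(
        _any_overlap(ivs, idp_regions) for ivs in background_regions.values()
    )
    b_tot = len(background_regions)
    p, _ = fisher_2x2(
        ContingencyTable2x2(t_hit, t_tot - t_hit, b_hit, b_tot - b_hit),
        alternative,
    )
    t_frac = t_hit / t_tot if t_tot else math.nan
    b_frac = b_hit / b_tot if b_tot else math.nan
    return p, t_frac, b_frac
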