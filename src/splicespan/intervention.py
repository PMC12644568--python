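"""Treatment-vs-control delta-PSI analysis for a lifespan-extending
intervention.

Condition-level PSI is derived from median inclusion/exclusion read counts;
per-event significance of an inclusion increase is a one-sided Fisher test on
the 2x2 count table with BH-FDR across events.  Events are labeled pos-MLS,
neg-MLS or background from the cross-species association results, and the
fraction of significantly upregulated events is compared between categories
over a grid of delta-PSI thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from splicespan.set_stats import ContingencyTable2x2, bh_fdr, fisher_2x2

CATEGORIES = ("pos_MLS", "neg_MLS", "background")


@dataclass(frozen=True)
class EventCounts:
    """Median-across-replicates inclusion/exclusion read counts for one event
    in one condition."""

    event_id: str
    inclusion_reads: int
    exclusion_reads: int

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValueError("negative read count")

    @property
    def psi(self) -> float:
        total = self.inclusion_reads + self.exclusion_reads
        return math.nan if total == 0 else 100.0 * self.inclusion_reads / total


def delta_psi(
    treatment: Mapping[str, EventCounts],
    control: Mapping[str, EventCounts],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-event delta-PSI (treatment - control) with a one-sided Fisher test
    for inclusion increase and BH-FDR across testable events.

    Events present in only one condition, or with undefined PSI in either,
    are skipped.  ``categories`` labels events pos_MLS / neg_MLS / background
    (unlabeled events default to background).
    """
    rows = []
    for event_id in sorted(set(treatment) & set(control)):
        t, c = treatment[event_id], control[event_id]
        if math.isnan(t.psi) or math.isnan(c.psi):
            continue
        p, _ = fisher_2x2(
            ContingencyTable2x2(
                t.inclusion_reads,
                t.exclusion_reads,
                c.inclusion_reads,
                c.exclusion_reads,
            ),
            alternative="greater",
        )
        category = "background"
        if categories is not None:
            category = categories.get(event_id, "background")
        rows.append(
            {
                "event_id": event_id,
                "category": category,
                "psi_treatment": t.psi,
                "psi_control": c.psi,
                "delta_psi": t.psi - c.psi,
                "p_increase": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "category",
            "psi_treatment",
            "psi_control",
            "delta_psi",
            "p_increase",
        ],
    ).set_index("event_id")
    if len(df):
        df["fdr"] = bh_fdr(df["p_increase"].to_numpy())
    else:
        df["fdr"] = []
    return df


def category_comparison(
    results: pd.DataFrame,
    thresholds: Sequence[float] = (0.0, 5.0, 10.0, 15.0),
    fdr_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Upregulated fractions per MLS category per delta-PSI threshold, and
    Fisher comparisons of each MLS category against background.

    An event is upregulated at a threshold when delta_psi > threshold and its
    inclusion-increase FDR < ``fdr_cutoff``.  Returns (fractions, tests);
    fractions are missing for empty categories.
    """
    fractions = []
    tests = []
    counts = {c: int((results["category"] == c).sum()) for c in CATEGORIES}
    for thr in thresholds:
        up = (results["delta_psi"] > thr) & (results["fdr"] < fdr_cutoff)
        n_up = {c: int((up & (results["category"] == c)).sum()) for c in CATEGORIES}
        row = {"threshold": thr}
        for c in CATEGORIES:
            row[f"frac_{c}"] = (
                n_up[c] / counts[c] if counts[c] else math.nan
            )
        fractions.append(row)
        for c in ("pos_MLS", "neg_MLS"):
            if counts[c] == 0 or counts["background"] == 0:
                continue
            alternative = "greater" if c == "pos_MLS" else "less"
            p, oddsratio = fisher_2x2(
                ContingencyTable2x2(
                    n_up[c],
                    counts[c] - n_up[c],
                    n_up["background"],
                    counts["background"] - n_up["background"],
                ),
                alternative=alternative,
            )
            tests.append(
                {
                    "threshold": thr,
                    "category": c,
                    "alternative": alternative,
                    "p": p,
                    "odds_ratio": oddsratio,
                }
            )
    return (
        pd.DataFrame(fractions).set_index("threshold"),
        pd.DataFrame(tests, columns=["threshold", "category", "alternative", "p", "odds_ratio"]),
    )
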