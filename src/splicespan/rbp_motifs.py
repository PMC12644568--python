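"""RNA-binding-protein motif scanning and enrichment.

Event scan regions (event exonic/intronic sequence plus flanks: exon ±100 nt,
intron ±50 nt) are scanned on the sense strand for each RBP's motifs;
occurrences are length-normalized.  Group enrichment compares a target event
group against random groups matched on AS-type composition; per-event motif
load is summarized as within-RBP percentiles for biclustering; and motif
frequency is correlated with PSI across species.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from splicespan.io_formats import IUPAC_CODES, Config, Motif, MotifSet
from splicespan.set_stats import bh_fdr

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ScanRegion:
    """The concatenated, strand-resolved sequence scanned for one event."""

    event_id: str
    event_type: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.event_id}: non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequence)


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are counted; classes contain only
    # ACGT, so N in the sequence never matches
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
        for c in consensus
    )
    return re.compile(f"(?={body})")


def count_matches(sequence: str, motif: Motif) -> int:
    """Number of (possibly overlapping) match start positions of one motif on
    the sense strand; 0 when the motif is longer than the sequence."""
    if len(motif) > len(sequence):
        return 0
    if motif.consensus is not None:
        return len(_consensus_regex(motif.consensus).findall(sequence))
    # PWM: position scores, threshold as fraction of the maximum score
    L = motif.pwm.shape[0]
    idx = np.array([_BASE_INDEX.get(b, -1) for b in sequence])
    n_pos = len(sequence) - L + 1
    scores = np.zeros(n_pos)
    valid = np.ones(n_pos, dtype=bool)
    logp = np.log(np.maximum(motif.pwm, 1e-9))
    for offset in range(L):
        col = idx[offset : offset + n_pos]
        valid &= col >= 0  # windows containing N never match
        scores += logp[offset, np.clip(col, 0, 3)]
    max_score = float(logp.max(axis=1).sum())
    min_score = float(logp.min(axis=1).sum())
    cutoff = min_score + motif.threshold * (max_score - min_score)
    return int((valid & (scores >= cutoff)).sum())


def scan(
    regions: Sequence[ScanRegion], motifs: MotifSet
) -> pd.DataFrame:
    """Length-normalized motif occurrence per (event, RBP).

    Returns a long-format DataFrame with columns event_id, event_type, rbp,
    raw_count, length, rate (= raw_count / region length, summed over the
    RBP's motifs).
    """
    rows = []
    for region in regions:
        for rbp in sorted(motifs):
            raw = sum(count_matches(region.sequence, m) for m in motifs[rbp])
            rows.append(
                {
                    "event_id": region.event_id,
                    "event_type": region.event_type,
                    "rbp": rbp,
                    "raw_count": raw,
                    "length": len(region),
                    "rate": raw / len(region) if len(region) else math.nan,
                }
            )
    return pd.DataFrame(rows)


def rate_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Events x RBPs matrix of length-normalized rates."""
    return profiles.pivot(index="event_id", columns="rbp", values="rate")


def percentile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Within-RBP percentile (average ranks for ties, scaled to [0,100]) of
    each event's rate among all profiled events."""
    rates = rate_matrix(profiles)
    return rates.rank(axis=0, method="average", pct=True) * 100.0


@dataclass
class EnrichmentRatio:
    rbp: str
    ratio: float
    target_mean: float
    null_mean: float
    null_sd: float  # SD of per-draw mean rates across draws
    n_draws: int
    seed: int


def group_enrichment(
    target_events: set[str],
    profiles: pd.DataFrame,
    n_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif enrichment of a target event group by matched resampling.

    Random groups are drawn from the profiled universe without replacement,
    preserving the target's per-AS-type counts exactly.  The enrichment ratio
    per RBP is the target's mean length-normalized rate divided by the mean
    of the per-draw mean rates over ``n_draws`` random groups.
    """
    rates = rate_matrix(profiles)
    types = profiles.drop_duplicates("event_id").set_index("event_id")[
        "event_type"
    ]
    universe = list(rates.index)
    missing = target_events - set(universe)
    if missing:
        raise ValueError(f"target events not profiled: {sorted(missing)[:3]}")
    target = sorted(target_events)
    type_counts = types.loc[target].value_counts().to_dict()
    pools = {
        t: np.array(sorted(types[types == t].index)) for t in type_counts
    }
    for t, need in type_counts.items():
        if len(pools[t]) < need:
            raise ValueError(
                f"universe has {len(pools[t])} events of type {t}, need {need}"
            )
    rng = np.random.default_rng(seed)
    X = rates.to_numpy(dtype=float)
    pos = {e: i for i, e in enumerate(rates.index)}
    target_mean = X[[pos[e] for e in target]].mean(axis=0)
    draw_means = np.empty((n_draws, X.shape[1]))
    for i in range(n_draws):
        chosen: list[int] = []
        for t, need in sorted(type_counts.items()):
            picked = rng.choice(pools[t], size=need, replace=False)
            chosen.extend(pos[e] for e in picked)
        draw_means[i] = X[chosen].mean(axis=0)
    null_mean = draw_means.mean(axis=0)
    null_sd = draw_means.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(null_mean > 0, target_mean / null_mean, np.nan)
    return pd.DataFrame(
        {
            "ratio": ratio,
            "target_mean": target_mean,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "n_draws": n_draws,
            "seed": seed,
        },
        index=pd.Index(rates.columns, name="rbp"),
    )


def percentile_bicluster(
    percentiles: pd.DataFrame, n_clusters: int = 2
) -> dict:
    """Average-linkage hierarchical biclustering of the event x RBP percentile
    matrix (Euclidean distance), with deterministic leaf order.

    Returns linkages, leaf orders, and flat cluster assignments at
    ``n_clusters`` for both axes.
    """
    if percentiles.shape[0] < 2 or percentiles.shape[1] < 2:
        raise ValueError("need at least 2 events and 2 RBPs")
    if percentiles.isna().any().any():
        raise ValueError("percentile matrix must be complete")
    # sort by identifier first so scipy's tie-breaking is deterministic
    mat = percentiles.sort_index(axis=0).sort_index(axis=1)
    out = {"event_ids": list(mat.index), "rbp_ids": list(mat.columns)}
    for axis, key in ((0, "event"), (1, "rbp")):
        data = mat.to_numpy() if axis == 0 else mat.to_numpy().T
        link = hierarchy.linkage(data, method="average", metric="euclidean")
        out[f"{key}_linkage"] = link
        out[f"{key}_leaves"] = list(hierarchy.leaves_list(link))
        out[f"{key}_clusters"] = hierarchy.fcluster(
            link, t=n_clusters, criterion="maxclust"
        )
    return out


def motif_psi_correlation(
    rates_by_species: pd.DataFrame,
    psi_by_species: pd.DataFrame,
    config: Config | None = None,
    min_points: int = 10,
) -> pd.DataFrame:
    """Spearman correlation between per-species motif rate and PSI.

    ``rates_by_species`` is indexed by (event_id, rbp) with species columns;
    ``psi_by_species`` is events x species.  Pairs need strictly more than
    ``min_points`` paired non-missing species; significance requires
    |rho| > rho_cutoff and BH-FDR < fdr_cutoff across tested pairs.
    """
    config = config or Config()
    rows = []
    for (event_id, rbp), rates in rates_by_species.iterrows():
        if event_id not in psi_by_species.index:
            continue
        psi = psi_by_species.loc[event_id]
        paired = pd.concat([rates, psi], axis=1, keys=["rate", "psi"]).dropna()
        if len(paired) <= min_points:
            continue
        if paired["rate"].nunique() == 1 or paired["psi"].nunique() == 1:
            continue
        rho, p = stats.spearmanr(paired["rate"], paired["psi"])
        rows.append(
            {
                "event_id": event_id,
                "rbp": rbp,
                "rho": float(rho),
                "n_used": len(paired),
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows, columns=["event_id", "rbp", "rho", "n_used", "p"])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = (df["rho"].abs() > config.rho_cutoff) & (
            df["fdr"] < config.fdr_cutoff
        )
    else:
        df["fdr"] = []
        df["significant"] = []
    return df.set_index(["event_id", "rbp"])


def paired_group_comparison(
    ratios_a: pd.DataFrame, ratios_b: pd.DataFrame, top_n: int | None = 20
) -> tuple[float, float]:
    """Paired t-test comparing two groups' enrichment ratios over shared RBPs.

    When ``top_n`` is given, the RBPs are the union of each group's top-n by
    ratio (restricted to RBPs present in both).  Returns (t, p).
    """
    common = ratios_a.index.intersection(ratios_b.index)
    a = ratios_a.loc[common, "ratio"]
    b = ratios_b.loc[common, "ratio"]
    if top_n is not None:
        keep = set(a.nlargest(top_n).index) | set(b.nlargest(top_n).index)
        a, b = a.loc[sorted(keep)], b.loc[sorted(keep)]
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
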