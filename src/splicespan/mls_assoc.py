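"""Cross-species association of splicing with lifespan and body mass.

Per-event Spearman correlations of PSI with species maximum lifespan (MLS) or
body mass (BM) with BH-FDR, phylogenetically independent contrasts (PIC) and
the contrast-based robustness check, the MLS = b0 + b1*BM + b2*PSI
decomposition, and tissue-specificity / divergent-direction summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from splicespan.io_formats import Config
from splicespan.set_stats import bh_fdr


@dataclass
class SpeciesTraits:
    """Per-species maximum lifespan (years) and adult body mass."""

    mls: pd.Series
    bm: pd.Series

    def __post_init__(self) -> None:
        if (self.mls <= 0).any() or (self.bm <= 0).any():
            raise ValueError("traits must be positive")

    @property
    def species(self) -> list[str]:
        return list(self.mls.index)

    def trait(self, name: str) -> pd.Series:
        if name == "MLS":
            return self.mls
        if name == "BM":
            return self.bm
        raise KeyError(name)


@dataclass
class AssociationResult:
    event_id: str
    tissue: str
    trait: str
    rho: float
    n_used: int
    p: float
    fdr: float = math.nan
    significant: bool = False

    @property
    def direction(self) -> str:
        return "pos" if self.rho > 0 else "neg"


def spearman_trait_assoc(
    psi: pd.DataFrame,
    traits: SpeciesTraits,
    trait: str = "MLS",
    tissue: str = "tissue",
    config: Config | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each event's species PSI against a trait.

    Pairwise-complete species are used per event; events with fewer than
    ``min_species`` usable values or zero PSI variance are dropped.  BH-FDR
    is computed across the tested events of this tissue x trait family, and
    significance requires |rho| > rho_cutoff and FDR < fdr_cutoff.
    """
    config = config or Config()
    tvals = traits.trait(trait)
    rows = []
    for event_id in psi.index:
        vals = psi.loc[event_id].dropna()
        common = vals.index.intersection(tvals.index)
        if len(common) < config.min_species:
            continue
        x = vals.loc[common].to_numpy(dtype=float)
        y = tvals.loc[common].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append(
            {
                "event_id": event_id,
                "tissue": tissue,
                "trait": trait,
                "rho": float(rho),
                "n_used": len(common),
                "p": float(p),
            }
        )
    df = pd.DataFrame(
        rows, columns=["event_id", "tissue", "trait", "rho", "n_used", "p"]
    ).set_index("event_id")
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = (df["rho"].abs() > config.rho_cutoff) & (
            df["fdr"] < config.fdr_cutoff
        )
        df["direction"] = np.where(df["rho"] > 0, "pos", "neg")
    else:
        df["fdr"] = []
        df["significant"] = []
        df["direction"] = []
    return df


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts


def pic(tree: dendropy.Tree, tip_values: Mapping[str, float]) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts.

    The tree is resolved to binary (zero-length branches at introduced nodes)
    and each internal node contributes the standardized contrast
    (x_left - x_right) / sqrt(b_left + b_right), where the branch below each
    resolved node is lengthened by b_left*b_right / (b_left + b_right).
    Returns the n_tips - 1 contrasts in postorder.
    """
    work = tree.clone(depth=1)
    work.suppress_unifurcations()
    work.resolve_polytomies(update_bipartitions=False)
    contrasts = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_values:
                raise KeyError(f"no value for tip {label!r}")
            node.pic_value = float(tip_values[label])
            node.pic_extra = 0.0
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree not binary after resolution")
        left, right = children
        bl = (left.edge.length or 0.0) + left.pic_extra
        br = (right.edge.length or 0.0) + right.pic_extra
        total = bl + br
        if total <= 0:
            raise ValueError("zero total branch length at an internal node")
        contrasts.append((left.pic_value - right.pic_value) / math.sqrt(total))
        node.pic_value = (br * left.pic_value + bl * right.pic_value) / total
        node.pic_extra = bl * br / total
    return np.asarray(contrasts)


def _origin_correlation(cx: np.ndarray, cy: np.ndarray) -> float:
    """Correlation of contrasts through the origin: sum(xy)/sqrt(sum x^2 sum y^2)."""
    denom = math.sqrt(float(np.sum(cx**2)) * float(np.sum(cy**2)))
    if denom == 0:
        return math.nan
    return float(np.sum(cx * cy)) / denom


def pic_correlation(
    tree: dendropy.Tree,
    x_values: Mapping[str, float],
    y_values: Mapping[str, float],
) -> float:
    """Phylogenetically corrected correlation between two tip-value maps,
    restricted to the tips present in both, as the through-origin correlation
    of their independent contrasts."""
    common = sorted(set(x_values) & set(y_values))
    if len(common) < 3:
        return math.nan
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(common)
    cx = pic(sub, {s: x_values[s] for s in common})
    cy = pic(sub, {s: y_values[s] for s in common})
    return _origin_correlation(cx, cy)


def pic_robustness(
    assocs: pd.DataFrame,
    tree: dendropy.Tree,
    psi: pd.DataFrame,
    traits: SpeciesTraits,
    contrast_cutoff: float = 0.2,
) -> tuple[float, pd.DataFrame]:
    """Fraction of significant associations retained after phylogenetic
    correction.

    An association is retained when the PIC correlation between PSI and the
    trait exceeds the cutoff in absolute value *and* matches the sign of the
    raw Spearman rho.  Returns (retained fraction, per-event table).
    """
    sig = assocs[assocs["significant"]]
    rows = []
    for event_id, row in sig.iterrows():
        vals = psi.loc[event_id].dropna()
        tvals = traits.trait(row["trait"])
        r_pic = pic_correlation(tree, vals.to_dict(), tvals.to_dict())
        retained = (
            not math.isnan(r_pic)
            and abs(r_pic) > contrast_cutoff
            and np.sign(r_pic) == np.sign(row["rho"])
        )
        rows.append(
            {"event_id": event_id, "pic_r": r_pic, "retained": retained}
        )
    table = pd.DataFrame(
        rows, columns=["event_id", "pic_r", "retained"]
    ).set_index("event_id")
    frac = float(table["retained"].mean()) if len(table) else math.nan
    return frac, table


# ---------------------------------------------------------------------------
# Body-mass decomposition


@dataclass
class BmDecomposition:
    event_id: str
    beta0: float
    beta1: float  # BM coefficient
    beta2: float  # PSI coefficient
    p_beta1: float
    p_beta2: float
    category: str


def bm_decompose(
    event_id: str,
    psi: pd.Series,
    traits: SpeciesTraits,
    min_species: int = 10,
    alpha: float = 0.05,
    log_traits: bool = False,
) -> BmDecomposition:
    """OLS fit of MLS = b0 + b1*BM + b2*PSI on complete species triples.

    Categories: PSI_only (p2 < alpha, p1 > alpha), joint (both < alpha),
    BM_only (p1 < alpha, p2 > alpha), else neither.
    """
    common = psi.dropna().index.intersection(traits.mls.index)
    if len(common) < min_species:
        raise ValueError(
            f"{event_id}: only {len(common)} complete triples (< {min_species})"
        )
    y = traits.mls.loc[common].to_numpy(dtype=float)
    bm = traits.bm.loc[common].to_numpy(dtype=float)
    x_psi = psi.loc[common].to_numpy(dtype=float)
    if log_traits:
        y, bm = np.log(y), np.log(bm)
    r = np.corrcoef(bm, x_psi)[0, 1]
    if abs(r) >= 1 - 1e-12:
        raise ValueError(f"{event_id}: BM and PSI are collinear")
    X = sm.add_constant(np.column_stack([bm, x_psi]))
    fit = sm.OLS(y, X).fit()
    p1, p2 = float(fit.pvalues[1]), float(fit.pvalues[2])
    if p2 < alpha and p1 > alpha:
        category = "PSI_only"
    elif p2 < alpha and p1 < alpha:
        category = "joint"
    elif p1 < alpha:
        category = "BM_only"
    else:
        category = "neither"
    return BmDecomposition(
        event_id=event_id,
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        beta2=float(fit.params[2]),
        p_beta1=p1,
        p_beta2=p2,
        category=category,
    )


# ---------------------------------------------------------------------------
# Tissue specificity and divergent directions


def tissue_specificity(
    assocs_by_tissue: Mapping[str, pd.DataFrame],
    focal_tissue: str = "brain",
) -> pd.DataFrame:
    """Per-event tissue-specificity summary across tissues.

    For every event significant in at least one tissue: the set of tissues
    where it is significant, the number of such tissues, and a divergence
    flag.  An event is divergent when it is significant in the focal tissue
    and its rho sign there is opposite to its sign in *every* other tissue
    where rho is defined (opposing evidence required: at least one other
    tissue with a defined rho).
    """
    if len(assocs_by_tissue) < 2:
        raise ValueError("need association results for at least two tissues")
    tissues = sorted(assocs_by_tissue)
    all_events = sorted(
        set().union(*(set(df.index) for df in assocs_by_tissue.values()))
    )
    rows = []
    for event_id in all_events:
        sig_tissues = []
        signs = {}
        for tissue in tissues:
            df = assocs_by_tissue[tissue]
            if event_id not in df.index:
                continue
            row = df.loc[event_id]
            signs[tissue] = np.sign(row["rho"])
            if row["significant"]:
                sig_tissues.append(tissue)
        if not sig_tissues:
            continue
        divergent = False
        if focal_tissue in sig_tissues:
            focal_sign = signs[focal_tissue]
            others = [s for t, s in signs.items() if t != focal_tissue]
            if others and all(s == -focal_sign for s in others):
                divergent = True
        rows.append(
            {
                "event_id": event_id,
                "n_tissues": len(sig_tissues),
                "tissues": ",".join(sig_tissues),
                "multi_tissue": len(sig_tissues) > 1,
                "divergent": divergent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "n_tissues", "tissues", "multi_tissue", "divergent"],
    ).set_index("event_id")


def upset_counts(spec_table: pd.DataFrame) -> pd.Series:
    """Counts of events per exact tissue combination (upset-style)."""
    return spec_table.groupby("tissues").size().sort_values(ascending=False)
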