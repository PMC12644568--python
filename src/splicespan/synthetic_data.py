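"""Synthetic-data generators emulating the study design.

The generators produce every input the pipeline consumes, with known ground
truth: a birth-only phylogeny of 26 species whose log lifespan and log body
mass evolve by correlated Brownian motion (lifespan rescaled to the 2.2-37 y,
>16-fold range); per-tissue species PSI matrices with a planted fraction of
lifespan-associated events (logit-scale effects plus phylogenetic and
independent noise) and a brain-divergent subset; event-region sequences
diverging with tree distance for the homology stage; a GTEx-like human cohort
with age-associated and covariate-confounded events; planted RBP motifs; and
treatment/control read counts with planted inclusion shifts.

Every generator is deterministic given (config, seed): each derives its random
stream from ``SimConfig.seed`` plus a fixed per-stage offset.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from splicespan.homology_map import AnchorRegionSet
from splicespan.intervention import EventCounts
from splicespan.io_formats import Motif, MotifSet
from splicespan.age_assoc import CohortTable
from splicespan.mls_assoc import SpeciesTraits

TISSUES = ("brain", "heart", "kidney", "liver", "lung", "skin")

# Event-type composition used when assigning types to synthetic events;
# cassette exons dominate, mutually exclusive exons are rare.
TYPE_WEIGHTS = {
    "SE": 0.55,
    "AF": 0.15,
    "A3": 0.09,
    "A5": 0.08,
    "RI": 0.08,
    "AL": 0.03,
    "MX": 0.02,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: 26 species spanning a >16-fold
    lifespan range, six tissues, 500 events per tissue with 10% planted at an
    effect giving a true |rho| around 0.7, a 400-sample human cohort with 20
    of 500 events age-associated, and 500-deep treatment/control counts.
    """

    seed: int = 0
    # tree + traits
    n_species: int = 26
    birth_rate: float = 1.0
    brownian_rate: float = 0.5
    trait_correlation: float = 0.5  # Brownian correlation of log MLS vs log BM
    mls_min: float = 2.2
    mls_fold_range: float = 37.0 / 2.2
    bm_min: float = 5.0
    bm_fold_range: float = 2000.0
    # species PSI
    n_events: int = 500
    planted_fraction: float = 0.10
    brain_divergent_fraction: float = 0.2  # of planted events
    effect_size: float = 1.0  # logit-PSI slope per SD of log MLS
    phylo_noise_sd: float = 0.15
    iid_noise_sd: float = 0.92
    missing_rate: float = 0.05
    tissues: tuple[str, ...] = TISSUES
    focal_tissue: str = "brain"
    # sequences
    n_seq_events: int = 40
    anchor_length: int = 200
    divergence_rate: float = 0.05  # substitutions/site per unit patristic distance
    loss_fraction: float = 0.1
    # cohort
    n_samples: int = 400
    n_cohort_events: int = 500
    n_age_events: int = 20
    n_confounded_events: int = 10
    age_slope: float = 0.5  # PSI units per year
    cohort_noise_sd: float = 7.0
    # motifs
    motif_multiplier: float = 3.0
    # intervention
    n_per_category: int = 200
    intervention_shift: float = 15.0
    read_depth: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (
            self.planted_fraction,
            self.brain_divergent_fraction,
            self.missing_rate,
            self.loss_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.iid_noise_sd <= 0 or self.cohort_noise_sd <= 0:
            raise ValueError("noise variances must be positive")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stage])


# ---------------------------------------------------------------------------
# Tree and traits


def simulate_tree_traits(config: SimConfig) -> tuple[dendropy.Tree, SpeciesTraits]:
    """Pure-birth tree with correlated Brownian log-lifespan / log-body-mass.

    Tip values are exponentiated; log MLS is min-max rescaled so the realized
    range is exactly [mls_min, mls_min * mls_fold_range] (ranks, and hence
    Spearman correlations, are unchanged by the monotone rescale).  BM is
    rescaled the same way to its own range.
    """
    from dendropy.simulate import treesim

    rng = config.rng(1)
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=random.Random(int(rng.integers(2**31))),
    )
    # rename tips deterministically
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for i, taxon in enumerate(taxa, start=1):
        taxon.label = f"sp{i:02d}"
    # the simulator stops exactly at the n-th speciation, which leaves the
    # youngest pair of tips with zero-length branches; extend every tip edge
    # by one exponential waiting time so all terminal branches are positive
    # (the tree stays ultrametric)
    extra = float(rng.exponential(1.0 / (config.birth_rate * config.n_species)))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # drop the simulator's origin branch: it predates the tip MRCA and would
    # only shift all tips by a common offset
    tree.seed_node.edge.length = None
    values = _correlated_brownian(tree, config, rng)
    species = sorted(values)
    log_mls = np.array([values[s][0] for s in species])
    log_bm = np.array([values[s][1] for s in species])
    mls = config.mls_min * config.mls_fold_range ** _unit_rescale(log_mls)
    bm = config.bm_min * config.bm_fold_range ** _unit_rescale(log_bm)
    traits = SpeciesTraits(
        mls=pd.Series(mls, index=species, name="mls"),
        bm=pd.Series(bm, index=species, name="bm"),
    )
    return tree, traits


def _unit_rescale(x: np.ndarray) -> np.ndarray:
    span = np.ptp(x)
    if span == 0:
        return np.full_like(x, 0.5)
    return (x - x.min()) / span


def _correlated_brownian(
    tree: dendropy.Tree, config: SimConfig, rng: np.random.Generator
) -> dict[str, tuple[float, float]]:
    rho = config.trait_correlation
    cov = config.brownian_rate * np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    state: dict[int, np.ndarray] = {}
    out: dict[str, tuple[float, float]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[id(node)] = np.zeros(2)
        else:
            t = node.edge.length or 0.0
            step = chol @ rng.standard_normal(2) * math.sqrt(max(t, 0.0))
            state[id(node)] = state[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = tuple(state[id(node)])
    return out


def brownian_tips(
    tree: dendropy.Tree, rate: float, rng: np.random.Generator
) -> pd.Series:
    """Single-trait Brownian simulation on a tree; returns tip values."""
    state: dict[int, float] = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[id(node)] = 0.0
        else:
            t = node.edge.length or 0.0
            state[id(node)] = state[id(node.parent_node)] + rng.standard_normal() * math.sqrt(
                rate * max(t, 0.0)
            )
        if node.is_leaf():
            out[node.taxon.label] = state[id(node)]
    return pd.Series(out).sort_index()


def _mean_root_tip_depth(tree: dendropy.Tree) -> float:
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return float(np.mean(depths))


# ---------------------------------------------------------------------------
# Species PSI


def _assign_types(n: int, rng: np.random.Generator) -> list[str]:
    types = list(TYPE_WEIGHTS)
    probs = np.array([TYPE_WEIGHTS[t] for t in types])
    return list(rng.choice(types, size=n, p=probs / probs.sum()))


@dataclass
class SpeciesPsiTruth:
    """Ground-truth labels for the cross-species PSI generator."""

    table: pd.DataFrame  # index event_id; planted, direction, brain_divergent
    event_genes: dict[str, str]
    event_types: dict[str, str]


def simulate_species_psi(
    tree: dendropy.Tree,
    traits: SpeciesTraits,
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SpeciesPsiTruth]:
    """Per-tissue species PSI matrices with planted lifespan effects.

    Planted events follow logit(PSI/100) = a + b*z(log MLS) + Brownian noise
    + iid noise with b = ±effect_size; a brain-divergent subset of the
    planted events flips the sign of b in the focal tissue.  Null events omit
    the slope.  Per-(species, event) missingness is applied at
    ``missing_rate``.  Also returns a gene TPM table (genes x species
    samples) for the expression filter, and the truth labels.
    """
    rng = config.rng(2)
    species = sorted(traits.mls.index)
    z_mls = traits.mls.loc[species].to_numpy()
    z_mls = (np.log(z_mls) - np.log(z_mls).mean()) / np.log(z_mls).std()
    n = config.n_events
    n_planted = int(round(n * config.planted_fraction))
    n_divergent = int(round(n_planted * config.brain_divergent_fraction))
    types = _assign_types(n, rng)
    event_ids = [
        f"{types[k]}:G{k:04d}:chr1:{1000 * k}-{1000 * k + 200}:+" for k in range(n)
    ]
    genes = {ev: f"G{k:04d}" for k, ev in enumerate(event_ids)}
    planted = np.zeros(n, dtype=bool)
    planted[:n_planted] = True
    direction = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    divergent = np.zeros(n, dtype=bool)
    divergent[:n_divergent] = True  # divergent events are a subset of planted
    baseline = rng.uniform(-0.8, 0.8, size=n)
    # scale the phylogenetic noise so its tip SD matches phylo_noise_sd
    depth = _mean_root_tip_depth(tree)
    phylo_rate = config.phylo_noise_sd**2 / max(depth, 1e-9)

    matrices: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        logit = np.empty((n, len(species)))
        for k in range(n):
            b = 0.0
            if planted[k]:
                b = config.effect_size * direction[k]
                if divergent[k] and tissue == config.focal_tissue:
                    b = -b
            phylo = brownian_tips(tree, phylo_rate, rng).loc[species].to_numpy()
            eps = rng.normal(0.0, config.iid_noise_sd, size=len(species))
            logit[k] = baseline[k] + b * z_mls + phylo + eps
        psi = 100.0 / (1.0 + np.exp(-logit))
        mask = rng.random(psi.shape) < config.missing_rate
        psi[mask] = np.nan
        matrices[tissue] = pd.DataFrame(psi, index=event_ids, columns=species)

    gene_ids = sorted(set(genes.values()))
    gene_tpm = pd.DataFrame(
        rng.lognormal(mean=1.0, sigma=0.6, size=(len(gene_ids), len(species))),
        index=gene_ids,
        columns=species,
    )
    truth = pd.DataFrame(
        {
            "planted": planted,
            "direction": np.where(direction > 0, "pos", "neg"),
            "brain_divergent": divergent,
            "event_type": types,
        },
        index=pd.Index(event_ids, name="event_id"),
    )
    return matrices, gene_tpm, SpeciesPsiTruth(truth, genes, dict(zip(event_ids, types)))


# ---------------------------------------------------------------------------
# Event-region sequences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < p:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def simulate_event_sequences(
    tree: dendropy.Tree,
    config: SimConfig,
) -> tuple[dict[str, AnchorRegionSet], dict[str, list[AnchorRegionSet]], pd.DataFrame]:
    """Anchor event regions and per-species diverged orthologs.

    The first species (sorted order) acts as the anchor ("mouse") reference.
    Each other species' ortholog is derived by per-site substitution with
    probability ``divergence_rate`` x patristic distance to the anchor tip
    (capped at 0.75); a ``loss_fraction`` of species lack the event entirely.
    Returns (anchors, per-species candidate sets, truth table of retention).
    """
    rng = config.rng(3)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    species = sorted(taxa)
    anchor_sp = species[0]
    distances = {
        sp: float(pdm.patristic_distance(taxa[anchor_sp], taxa[sp]))
        for sp in species
    }
    types = _assign_types(config.n_seq_events, rng)
    anchors: dict[str, AnchorRegionSet] = {}
    per_species: dict[str, list[AnchorRegionSet]] = {sp: [] for sp in species[1:]}
    truth_rows = []
    from splicespan.homology_map import REQUIRED_REGIONS

    for k in range(config.n_seq_events):
        etype = types[k]
        event_id = f"{etype}:anchor{k:03d}"
        regions = {
            role: _random_seq(rng, config.anchor_length)
            for role in REQUIRED_REGIONS[etype]
        }
        anchors[event_id] = AnchorRegionSet(
            event_id=event_id, event_type=etype, regions=regions, span=config.anchor_length
        )
        for sp in species[1:]:
            present = rng.random() >= config.loss_fraction
            truth_rows.append(
                {"event_id": event_id, "species": sp, "present": present}
            )
            if not present:
                continue
            p = min(0.75, config.divergence_rate * distances[sp])
            per_species[sp].append(
                AnchorRegionSet(
                    event_id=f"{etype}:{sp}:{k:03d}",
                    event_type=etype,
                    regions={
                        role: _mutate(seq, p, rng) for role, seq in regions.items()
                    },
                    span=config.anchor_length,
                )
            )
    truth = pd.DataFrame(truth_rows)
    return anchors, per_species, truth


# ---------------------------------------------------------------------------
# Human cohort


@dataclass
class CohortTruth:
    table: pd.DataFrame  # index event_id; age_associated, confounded, slope


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, CohortTable, CohortTruth]:
    """GTEx-like cohort: ages uniform on [20, 70], numeric covariates (5
    genotype-PC and 15 expression-factor surrogates, standard normal) plus
    two categorical covariates (sex, platform), and an events x samples PSI
    matrix.

    Age-associated events carry PSI = baseline + slope*age + covariate
    effects + noise (clipped to [0,100]); confounded events instead track a
    covariate that itself correlates with age, so a correctly adjusted model
    must not select them.  Null events are covariate + noise only.
    """
    if config.n_samples < 100:
        raise ValueError("cohort size must be >= 100")
    rng = config.rng(4)
    n, m = config.n_samples, config.n_cohort_events
    samples = [f"s{i:04d}" for i in range(n)]
    age = pd.Series(rng.uniform(20, 70, size=n), index=samples, name="age")
    cov = {}
    for i in range(1, 6):
        cov[f"PC{i}"] = rng.standard_normal(n)
    for i in range(1, 16):
        cov[f"InferredCov{i}"] = rng.standard_normal(n)
    # one inferred factor partially tracks age (the confounder)
    cov["InferredCov1"] = 0.6 * (age.to_numpy() - 45.0) / 14.4 + 0.8 * rng.standard_normal(n)
    cov["sex"] = rng.choice(["F", "M"], size=n)
    cov["platform"] = rng.choice(["HiSeq2000", "HiSeqX"], size=n)
    covariates = pd.DataFrame(cov, index=samples)
    cohort = CohortTable(age=age, covariates=covariates)

    event_ids = [f"SE:H{k:04d}:chr2:{500 * k}-{500 * k + 150}:+" for k in range(m)]
    age_assoc = np.zeros(m, dtype=bool)
    confounded = np.zeros(m, dtype=bool)
    age_assoc[: config.n_age_events] = True
    confounded[config.n_age_events : config.n_age_events + config.n_confounded_events] = True
    slopes = np.zeros(m)
    sign = np.where(rng.random(m) < 0.5, 1.0, -1.0)
    slopes[age_assoc] = config.age_slope * sign[age_assoc]
    baseline = rng.uniform(25, 75, size=m)
    conf = cov["InferredCov1"]
    psi = np.empty((m, n))
    for k in range(m):
        mu = baseline[k] + slopes[k] * (age.to_numpy() - 45.0)
        if confounded[k]:
            mu = baseline[k] + 12.0 * sign[k] * conf
        # mild dependence on two genotype PCs for realism
        mu = mu + 1.5 * cov["PC1"] - 1.0 * cov["PC2"]
        psi[k] = np.clip(mu + rng.normal(0, config.cohort_noise_sd, size=n), 0, 100)
    psi_df = pd.DataFrame(psi, index=event_ids, columns=samples)
    truth = pd.DataFrame(
        {"age_associated": age_assoc, "confounded": confounded, "slope": slopes},
        index=pd.Index(event_ids, name="event_id"),
    )
    return psi_df, cohort, CohortTruth(truth)


# ---------------------------------------------------------------------------
# Motif planting


def default_motifs() -> MotifSet:
    """A compact panel of consensus motifs for well-known splicing RBPs."""
    consensi = {
        "FUS": "TGGTG",
        "PTBP1": "TCTTC",
        "RBFOX1": "TGCATG",
        "NOVA1": "TCATT",
        "SRSF1": "GGAGGA",
        "HNRNPA1": "TAGGGT",
        "QKI": "ACTAAC",
        "MBNL1": "TGCTGC",
    }
    return {
        name: [Motif(name=name, consensus=seq)] for name, seq in consensi.items()
    }


def simulate_motif_regions(
    truth: pd.DataFrame,
    config: SimConfig,
    motifs: MotifSet | None = None,
    region_length: int = 1000,
    base_rate: float = 0.02,
    enriched_rbps: Sequence[str] = ("RBFOX1", "QKI"),
) -> list:
    """Scan regions for every event in ``truth``: random background sequence
    with the enriched RBPs' motifs stamped in at Poisson counts — base rate
    per nucleotide everywhere, ``motif_multiplier`` times that in planted
    (lifespan-associated) events.

    Instances are placed at non-overlapping positions so stamps cannot erase
    one another and the realized length-normalized rate stays proportional to
    the intended rate.  RBPs that are not stamped occur only at the uniform
    background frequency of their consensus, so their group-enrichment ratio
    is ~1 by construction.
    """
    from splicespan.rbp_motifs import ScanRegion

    motifs = motifs or default_motifs()
    rng = config.rng(5)
    regions = []
    for event_id, row in truth.iterrows():
        seq = list(_random_seq(rng, region_length))
        occupied: list[tuple[int, int]] = []
        for rbp in sorted(enriched_rbps):
            consensus = motifs[rbp][0].consensus
            rate = base_rate
            if bool(row.get("planted", False)):
                rate = base_rate * config.motif_multiplier
            for _ in range(rng.poisson(rate * region_length)):
                for _try in range(100):
                    start = int(rng.integers(0, region_length - len(consensus)))
                    end = start + len(consensus)
                    if all(start >= e or end <= s for s, e in occupied):
                        occupied.append((start, end))
                        seq[start:end] = list(consensus)
                        break
        regions.append(
            ScanRegion(
                event_id=event_id,
                event_type=row.get("event_type", "SE"),
                sequence="".join(seq),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Intervention counts


def simulate_intervention(
    config: SimConfig,
) -> tuple[dict[str, EventCounts], dict[str, EventCounts], dict[str, str]]:
    """Treatment/control read counts with a planted inclusion shift.

    Control PSI is uniform on [20, 80]; treatment PSI adds
    ``+intervention_shift`` for pos-MLS events, ``-intervention_shift`` for
    neg-MLS events, and nothing for background.  Counts are binomial at
    ``read_depth`` around the condition PSI.
    """
    rng = config.rng(6)
    treatment: dict[str, EventCounts] = {}
    control: dict[str, EventCounts] = {}
    categories: dict[str, str] = {}
    for cat, shift in (
        ("pos_MLS", config.intervention_shift),
        ("neg_MLS", -config.intervention_shift),
        ("background", 0.0),
    ):
        for k in range(config.n_per_category):
            event_id = f"SE:I{cat}:{k:04d}"
            psi_c = rng.uniform(20, 80)
            psi_t = float(np.clip(psi_c + shift, 0, 100))
            inc_c = int(rng.binomial(config.read_depth, psi_c / 100))
            inc_t = int(rng.binomial(config.read_depth, psi_t / 100))
            control[event_id] = EventCounts(event_id, inc_c, config.read_depth - inc_c)
            treatment[event_id] = EventCounts(event_id, inc_t, config.read_depth - inc_t)
            categories[event_id] = cat
    return treatment, control, categories
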