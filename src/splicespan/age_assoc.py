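"""Human age association by elastic net over all splicing events.

Age is modeled as a linear function of every event's PSI plus nuisance
covariates (sex, genotype PCs, expression-factor surrogates, platform,
protocol).  The PSI block is penalized (L1+L2); covariates are adjustments
and stay unpenalized, implemented exactly by Frisch-Waugh partialling-out:
residualizing age and the PSI block on the covariate design and fitting the
penalized model on the residuals is algebraically identical to the joint
problem with an unpenalized covariate block.  Events with a non-zero
coefficient are age-associated; error control is empirical, by refitting
under age-label permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from splicespan.io_formats import Config


@dataclass
class CohortTable:
    """Sample ages and nuisance covariates.

    Categorical covariates are one-hot encoded (lexicographic level order,
    first level dropped) so the design is deterministic.
    """

    age: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if self.age.isna().any():
            raise ValueError("missing ages")
        if not self.age.index.equals(self.covariates.index):
            raise ValueError("age and covariate sample indices differ")

    def design(self) -> pd.DataFrame:
        """Numeric covariate design matrix (categoricals one-hot encoded)."""
        blocks = []
        for col in sorted(self.covariates.columns):
            series = self.covariates[col]
            if pd.api.types.is_numeric_dtype(series):
                blocks.append(series.astype(float).to_frame(col))
            else:
                levels = sorted(series.astype(str).unique())
                for level in levels[1:]:
                    blocks.append(
                        (series.astype(str) == level)
                        .astype(float)
                        .to_frame(f"{col}={level}")
                    )
        return pd.concat(blocks, axis=1)


@dataclass
class ElasticNetFit:
    coefficients: pd.Series  # per-event, on the standardized-PSI scale
    intercept: float
    l1_ratio: float
    alpha: float
    selected_events: list[str]
    seed: int
    dropped_events: list[str] = field(default_factory=list)


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or matrix) on the column space of C."""
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def _prepare(
    psi: pd.DataFrame, cohort: CohortTable
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], np.ndarray]:
    """Complete-case event filtering, PSI standardization, and partialling-out
    of the covariate design (with intercept) from both age and PSI."""
    samples = list(cohort.age.index)
    X_df = psi.T.loc[samples]  # samples x events
    dropped = [c for c in X_df.columns if X_df[c].isna().any()]
    X_df = X_df.drop(columns=dropped)
    kept = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    C = np.column_stack(
        [np.ones(len(samples)), cohort.design().to_numpy(dtype=float)]
    )
    y = cohort.age.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant age")
    if len(samples) < C.shape[1] + 2:
        raise ValueError("fewer samples than covariates + 2")
    return _residualize(y, C), _residualize(X, C), kept, dropped, C


def _fit_enet_cv(
    X_r: np.ndarray, y_r: np.ndarray, config: Config
) -> ElasticNet:
    """CV-tuned elastic net with the one-standard-error rule.

    The penalty is the largest alpha on a 30-point path whose CV
    mean-squared error is within one standard error of the minimum (the
    glmnet ``lambda.1se`` convention): the sparsest model statistically
    indistinguishable from the best-predicting one.  Under a label
    permutation this collapses to a near-empty model, which is what makes
    the permutation null sharp.
    """
    seed = config.seed % 2**31
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    search = ElasticNetCV(
        l1_ratio=config.elastic_net_l1_ratio,
        cv=cv,
        fit_intercept=True,
        alphas=30,
        eps=0.01,
        tol=1e-3,
        max_iter=2000,
        random_state=seed,
    )
    search.fit(X_r, y_r)
    mse = search.mse_path_.mean(axis=1)
    se = search.mse_path_.std(axis=1, ddof=1) / math.sqrt(search.mse_path_.shape[1])
    i_min = int(mse.argmin())
    alpha = float(search.alphas_[mse <= mse[i_min] + se[i_min]].max())
    model = ElasticNet(
        alpha=alpha,
        l1_ratio=config.elastic_net_l1_ratio,
        fit_intercept=True,
        tol=1e-3,
        max_iter=2000,
    )
    model.fit(X_r, y_r)
    return model


def fit_age_model(
    psi: pd.DataFrame,
    cohort: CohortTable,
    config: Config | None = None,
) -> ElasticNetFit:
    """Fit the all-events elastic net and return the selected event set.

    Events with any missing sample PSI are dropped (the model needs a
    complete matrix).  The penalty is chosen by seeded k-fold CV minimizing
    mean-squared error; the mixing parameter defaults to 0.5.
    """
    config = config or Config()
    y_r, X_r, kept, dropped, _ = _prepare(psi, cohort)
    model = _fit_enet_cv(X_r, y_r, config)
    coefs = pd.Series(model.coef_, index=kept)
    return ElasticNetFit(
        coefficients=coefs,
        intercept=float(model.intercept_),
        l1_ratio=config.elastic_net_l1_ratio,
        alpha=float(model.alpha),
        selected_events=[e for e in kept if coefs[e] != 0],
        seed=config.seed,
        dropped_events=dropped,
    )


@dataclass
class PermutationFdr:
    n_perm: int
    table: pd.DataFrame  # index: cutoff; columns: mean_permuted, observed, fdr
    permuted_counts: np.ndarray  # (n_perm, n_cutoffs) selections per permutation


def permutation_fdr(
    psi: pd.DataFrame,
    cohort: CohortTable,
    config: Config | None = None,
    n_perm: int | None = None,
    cutoffs: Sequence[float] = (0.0, 0.1, 0.3, 0.7),
    fit: ElasticNetFit | None = None,
) -> PermutationFdr:
    """Empirical FDR by age-label permutation.

    Each permutation shuffles ages across samples and reruns the *entire*
    fitting procedure (residualization on covariates and CV-tuned elastic
    net), so permuted selection counts are exchangeable with the observed
    count under the null; selections are counted above each absolute
    standardized-coefficient cutoff.  Empirical FDR per cutoff is
    (mean permuted count) / (observed count); undefined (NaN) when the
    observed count is zero.
    """
    config = config or Config()
    n_perm = n_perm if n_perm is not None else config.n_permutations
    if fit is None:
        fit = fit_age_model(psi, cohort, config)
    y_r, X_r, kept, _, C = _prepare(psi, cohort)
    cutoffs = list(cutoffs)
    observed = np.array(
        [(fit.coefficients.abs().to_numpy() > c).sum() for c in cutoffs]
    )
    rng = np.random.default_rng(config.seed)
    y_raw = cohort.age.to_numpy(dtype=float)
    counts = np.zeros((n_perm, len(cutoffs)), dtype=int)
    for i in range(n_perm):
        y_perm = rng.permutation(y_raw)
        model = _fit_enet_cv(X_r, _residualize(y_perm, C), config)
        counts[i] = [(np.abs(model.coef_) > c).sum() for c in cutoffs]
    mean_perm = counts.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(observed > 0, mean_perm / np.maximum(observed, 1), np.nan)
    table = pd.DataFrame(
        {"mean_permuted": mean_perm, "observed": observed, "fdr": fdr},
        index=pd.Index(cutoffs, name="cutoff"),
    )
    return PermutationFdr(n_perm=n_perm, table=table, permuted_counts=counts)


# ---------------------------------------------------------------------------
# Set similarity and the overlap permutation test


def tissue_similarity(
    sets: Mapping[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Jaccard and overlap-coefficient matrices over tissue-wise
    selected-event sets.  Pairs where a set is empty are missing."""
    from splicespan.set_stats import jaccard, overlap_coefficient

    if len(sets) < 2:
        raise ValueError("need at least two tissues")
    names = sorted(sets)
    jac = pd.DataFrame(np.nan, index=names, columns=names)
    oc = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                jac.loc[a, b] = oc.loc[a, b] = 1.0
            elif sets[a] and sets[b]:
                jac.loc[a, b] = jaccard(sets[a], sets[b])
                oc.loc[a, b] = overlap_coefficient(sets[a], sets[b])
    return jac, oc


@dataclass
class OverlapPermutation:
    observed: int
    expected: float
    p_depletion: float
    p_enrichment: float
    n: int

    def format_p(self, p: float) -> str:
        return f"< {1.0 / (self.n + 1):.2g}" if p <= 1.0 / (self.n + 1) else f"{p:.4g}"


def overlap_permutation(
    set_a: set[str],
    set_b: set[str],
    bg_a: set[str],
    bg_b: set[str],
    n: int = 10000,
    seed: int = 0,
) -> OverlapPermutation:
    """Permutation test for the overlap of two sets with distinct backgrounds.

    Each of ``n`` iterations draws |A| identifiers from background A and |B|
    from background B (uniformly, without replacement) and counts the overlap
    on the shared identifier space.  Add-one empirical p-values:
    p_depletion = (1 + #{sim <= obs}) / (n+1), p_enrichment analogous with >=.
    """
    if not set_a <= bg_a or not set_b <= bg_b:
        raise ValueError("each set must be a subset of its background")
    if len(set_a) > len(bg_a) or len(set_b) > len(bg_b):
        raise ValueError("set larger than its background")
    shared = bg_a & bg_b
    observed = len(set_a & set_b & shared)
    rng = np.random.default_rng(seed)
    arr_a = np.array(sorted(bg_a))
    arr_b = np.array(sorted(bg_b))
    sims = np.empty(n, dtype=int)
    for i in range(n):
        sa = set(rng.choice(arr_a, size=len(set_a), replace=False))
        sb = set(rng.choice(arr_b, size=len(set_b), replace=False))
        sims[i] = len(sa & sb & shared)
    p_dep = (1 + int((sims <= observed).sum())) / (n + 1)
    p_enr = (1 + int((sims >= observed).sum())) / (n + 1)
    return OverlapPermutation(
        observed=observed,
        expected=float(sims.mean()),
        p_depletion=p_dep,
        p_enrichment=p_enr,
        n=n,
    )
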