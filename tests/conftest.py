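"""Shared fixtures: synthetic datasets are generated once per session at the
default study conditions and reused by the module and acceptance tests."""

from __future__ import annotations

import pytest

from splicespan import age_assoc, events_psi, mls_assoc
from splicespan.io_formats import Config, GenomicInterval, TranscriptModel
from splicespan.synthetic_data import (
    SimConfig,
    simulate_cohort,
    simulate_species_psi,
    simulate_tree_traits,
)

SEED = 20240917 % 2**31


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def analysis_config() -> Config:
    return Config(seed=SEED)


@pytest.fixture(scope="session")
def species_dataset(sim_config):
    """Tree, traits, per-tissue PSI, gene TPM and truth labels."""
    tree, traits = simulate_tree_traits(sim_config)
    matrices, gene_tpm, truth = simulate_species_psi(tree, traits, sim_config)
    return {
        "tree": tree,
        "traits": traits,
        "matrices": matrices,
        "gene_tpm": gene_tpm,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def mls_associations(species_dataset, sim_config, analysis_config):
    """Per-tissue MLS association tables on the filtered default dataset."""
    out = {}
    for tissue, psi in species_dataset["matrices"].items():
        kept = events_psi.filter_events(
            psi,
            species_dataset["gene_tpm"],
            species_dataset["truth"].event_genes,
            analysis_config,
        )
        out[tissue] = mls_assoc.spearman_trait_assoc(
            psi.loc[kept],
            species_dataset["traits"],
            trait="MLS",
            tissue=tissue,
            config=analysis_config,
        )
    return out


@pytest.fixture(scope="session")
def cohort_dataset(sim_config):
    psi, cohort, truth = simulate_cohort(sim_config)
    return {"psi": psi, "cohort": cohort, "truth": truth.table}


@pytest.fixture(scope="session")
def null_cohort_dataset():
    sim = SimConfig(seed=SEED + 1, n_age_events=0, n_confounded_events=0)
    psi, cohort, truth = simulate_cohort(sim)
    return {"psi": psi, "cohort": cohort, "truth": truth.table}


@pytest.fixture(scope="session")
def age_fit(cohort_dataset, analysis_config):
    return age_assoc.fit_age_model(
        cohort_dataset["psi"], cohort_dataset["cohort"], analysis_config
    )


def make_transcript(tid, gene, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, gene, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )
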