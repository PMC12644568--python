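"""Stage orchestration: simulate -> events/PSI filters -> homology ->
MLS association -> age association -> RBP motifs -> intervention -> report.

Every stage reads its inputs from, and writes plain headered TSVs to, one
output directory, so stages can be run (or re-run) individually and a full
run at a fixed seed is byte-reproducible.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from splicespan import age_assoc, events_psi, homology_map, intervention
from splicespan import mls_assoc, rbp_motifs, synthetic_data
from splicespan.io_formats import (
    Config,
    read_fasta,
    read_newick,
    read_psi_table,
    read_table,
    write_fasta,
    write_newick,
    write_table,
)

STAGES = (
    "simulate",
    "homology",
    "mls-assoc",
    "age-assoc",
    "rbp-enrich",
    "intervention",
    "report",
)


def _outdir(path: str | Path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------


def stage_simulate(
    out_dir: str | Path, sim: synthetic_data.SimConfig, config: Config
) -> None:
    out = _outdir(out_dir)
    tree, traits = synthetic_data.simulate_tree_traits(sim)
    write_newick(tree, out / "tree.nwk")
    write_table(
        pd.DataFrame({"mls": traits.mls, "bm": traits.bm}),
        out / "traits.tsv",
        config,
    )
    matrices, gene_tpm, truth = synthetic_data.simulate_species_psi(
        tree, traits, sim
    )
    for tissue, psi in matrices.items():
        write_table(psi, out / f"psi_{tissue}.tsv", config)
    write_table(gene_tpm, out / "gene_tpm.tsv", config)
    write_table(truth.table, out / "truth_species.tsv", config)

    anchors, per_species, seq_truth = synthetic_data.simulate_event_sequences(
        tree, sim
    )
    write_fasta(
        {
            f"{a.event_id}|{role}": seq
            for a in anchors.values()
            for role, seq in a.regions.items()
        },
        out / "anchors.fasta",
    )
    write_fasta(
        {
            f"{sp}|{c.event_id}|{role}": seq
            for sp, cands in per_species.items()
            for c in cands
            for role, seq in c.regions.items()
        },
        out / "species_regions.fasta",
    )
    write_table(seq_truth, out / "truth_sequences.tsv", config, index=False)

    cohort_psi, cohort, cohort_truth = synthetic_data.simulate_cohort(sim)
    write_table(cohort_psi, out / "cohort_psi.tsv", config)
    cov = cohort.covariates.copy()
    cov.insert(0, "age", cohort.age)
    write_table(cov, out / "cohort_covariates.tsv", config)
    write_table(cohort_truth.table, out / "truth_cohort.tsv", config)

    treatment, control, categories = synthetic_data.simulate_intervention(sim)
    rows = []
    for event_id in sorted(treatment):
        t, c = treatment[event_id], control[event_id]
        rows.append(
            {
                "event_id": event_id,
                "category": categories[event_id],
                "inc_treatment": t.inclusion_reads,
                "exc_treatment": t.exclusion_reads,
                "inc_control": c.inclusion_reads,
                "exc_control": c.exclusion_reads,
            }
        )
    write_table(
        pd.DataFrame(rows).set_index("event_id"),
        out / "intervention_counts.tsv",
        config,
    )


def _load_region_sets(path: Path) -> dict[str, homology_map.AnchorRegionSet]:
    groups: dict[str, dict[str, str]] = {}
    for name, seq in read_fasta(path).items():
        *prefix, role = name.split("|")
        key = "|".join(prefix)
        groups.setdefault(key, {})[role] = seq
    out = {}
    for key, regions in groups.items():
        event_id = key.split("|")[-1]
        etype = event_id.split(":")[0]
        out[key] = homology_map.AnchorRegionSet(
            event_id=event_id, event_type=etype, regions=regions
        )
    return out


def stage_homology(out_dir: str | Path, config: Config) -> None:
    out = Path(out_dir)
    anchors = _load_region_sets(out / "anchors.fasta")
    species_sets: dict[str, list] = {}
    for key, rset in _load_region_sets(out / "species_regions.fasta").items():
        sp = key.split("|")[0]
        species_sets.setdefault(sp, []).append(rset)
    calls = []
    for anchor in anchors.values():
        for sp, cands in sorted(species_sets.items()):
            calls.append(
                homology_map.match_event(
                    anchor, cands, sp, config.alignment_coverage
                )
            )
    conserved = homology_map.conserved_set(calls, config.min_species)
    table = homology_map.calls_table(calls)
    write_table(table, out / "homology_calls.tsv", config, index=False)
    write_table(
        pd.DataFrame({"event_id": sorted(conserved)}),
        out / "conserved_events.tsv",
        config,
        index=False,
    )


def stage_mls_assoc(
    out_dir: str | Path, sim: synthetic_data.SimConfig, config: Config
) -> None:
    out = Path(out_dir)
    tree = read_newick(out / "tree.nwk")
    traits_df = read_table(out / "traits.tsv")
    traits = mls_assoc.SpeciesTraits(mls=traits_df["mls"], bm=traits_df["bm"])
    gene_tpm = read_table(out / "gene_tpm.tsv")
    truth = read_table(out / "truth_species.tsv")
    event_genes = {ev: ev.split(":")[1] for ev in truth.index}

    assocs_by_tissue = {}
    for tissue in sim.tissues:
        psi = read_psi_table(out / f"psi_{tissue}.tsv")
        kept = events_psi.filter_events(psi, gene_tpm, event_genes, config)
        psi = psi.loc[kept]
        for trait in ("MLS", "BM"):
            assoc = mls_assoc.spearman_trait_assoc(
                psi, traits, trait=trait, tissue=tissue, config=config
            )
            write_table(assoc, out / f"assoc_{tissue}_{trait}.tsv", config)
            if trait == "MLS":
                assocs_by_tissue[tissue] = assoc
                frac, pic_table = mls_assoc.pic_robustness(
                    assoc, tree, psi, traits, config.contrast_cutoff
                )
                write_table(pic_table, out / f"pic_{tissue}.tsv", config)
                decomp_rows = []
                for event_id in assoc.index[assoc["significant"]]:
                    try:
                        d = mls_assoc.bm_decompose(
                            event_id,
                            psi.loc[event_id],
                            traits,
                            min_species=config.min_species,
                        )
                    except ValueError:
                        continue
                    decomp_rows.append(vars(d))
                if decomp_rows:
                    write_table(
                        pd.DataFrame(decomp_rows).set_index("event_id"),
                        out / f"bm_decomposition_{tissue}.tsv",
                        config,
                    )
    spec = mls_assoc.tissue_specificity(
        assocs_by_tissue, focal_tissue=sim.focal_tissue
    )
    write_table(spec, out / "tissue_specificity.tsv", config)


def stage_age_assoc(
    out_dir: str | Path, sim: synthetic_data.SimConfig, config: Config
) -> None:
    out = Path(out_dir)
    psi = read_psi_table(out / "cohort_psi.tsv")
    cov = read_table(out / "cohort_covariates.tsv")
    cohort = age_assoc.CohortTable(
        age=cov["age"], covariates=cov.drop(columns=["age"])
    )
    fit = age_assoc.fit_age_model(psi, cohort, config)
    write_table(
        pd.DataFrame(
            {
                "coefficient": fit.coefficients,
                "selected": fit.coefficients != 0,
            }
        ),
        out / "age_selected.tsv",
        config,
    )
    perm = age_assoc.permutation_fdr(
        psi, cohort, config, n_perm=config.n_permutations, fit=fit
    )
    write_table(perm.table, out / "age_permutation_fdr.tsv", config)

    # MLS vs Age overlap on the shared synthetic gene space
    truth_sp = read_table(out / "truth_species.tsv")
    mls_sets = set()
    for tissue in sim.tissues:
        path = out / f"assoc_{tissue}_MLS.tsv"
        if path.exists():
            assoc = read_table(path)
            mls_sets |= set(assoc.index[assoc["significant"]])
    # identifiers differ between the species and cohort universes; overlap is
    # computed on event ordinals as the shared identifier space
    bg_a = {ev.split(":")[1] for ev in truth_sp.index}
    sel_a = {ev.split(":")[1] for ev in mls_sets}
    bg_b = {f"G{k:04d}" for k in range(sim.n_cohort_events)}
    sel_b = {ev.split(":")[1].replace("H", "G") for ev in fit.selected_events}
    res = age_assoc.overlap_permutation(
        sel_a & bg_a,
        sel_b & bg_b,
        bg_a,
        bg_b,
        n=config.n_overlap_samplings,
        seed=config.seed,
    )
    write_table(
        pd.DataFrame([vars(res)]),
        out / "mls_age_overlap.tsv",
        config,
        index=False,
    )


def stage_rbp(
    out_dir: str | Path, sim: synthetic_data.SimConfig, config: Config
) -> None:
    out = Path(out_dir)
    truth = read_table(out / "truth_species.tsv")
    regions = synthetic_data.simulate_motif_regions(truth, sim)
    profiles = rbp_motifs.scan(regions, synthetic_data.default_motifs())
    write_table(profiles, out / "motif_profiles.tsv", config, index=False)
    target = set(truth.index[truth["planted"]])
    ratios = rbp_motifs.group_enrichment(
        target, profiles, n_draws=config.n_resample, seed=config.seed
    )
    write_table(ratios, out / "motif_enrichment.tsv", config)
    percentiles = rbp_motifs.percentile_matrix(profiles)
    bic = rbp_motifs.percentile_bicluster(percentiles)
    write_table(
        pd.DataFrame(
            {"event_id": bic["event_ids"], "cluster": bic["event_clusters"]}
        ),
        out / "motif_event_clusters.tsv",
        config,
        index=False,
    )


def stage_intervention(out_dir: str | Path, config: Config) -> None:
    out = Path(out_dir)
    counts = read_table(out / "intervention_counts.tsv")
    treatment = {
        ev: intervention.EventCounts(
            ev, int(r["inc_treatment"]), int(r["exc_treatment"])
        )
        for ev, r in counts.iterrows()
    }
    control = {
        ev: intervention.EventCounts(
            ev, int(r["inc_control"]), int(r["exc_control"])
        )
        for ev, r in counts.iterrows()
    }
    categories = counts["category"].to_dict()
    results = intervention.delta_psi(treatment, control, categories)
    write_table(results, out / "delta_psi.tsv", config)
    fractions, tests = intervention.category_comparison(results)
    write_table(fractions, out / "intervention_fractions.tsv", config)
    write_table(tests, out / "intervention_tests.tsv", config, index=False)


def stage_report(
    out_dir: str | Path, sim: synthetic_data.SimConfig, config: Config
) -> None:
    out = Path(out_dir)
    lines = ["# splicespan run report", ""]
    lines.append(f"- seed: {config.seed}; config hash: {config.hash()}")
    truth = read_table(out / "truth_species.tsv")
    lines.append(
        f"- species PSI: {len(truth)} events/tissue, "
        f"{int(truth['planted'].sum())} planted"
    )
    conserved = read_table(out / "conserved_events.tsv", index_col=None)
    lines.append(f"- conserved events (sequence stage): {len(conserved)}")
    for tissue in sim.tissues:
        path = out / f"assoc_{tissue}_MLS.tsv"
        if not path.exists():
            continue
        assoc = read_table(path)
        sig = assoc[assoc["significant"]]
        pos = int((sig["direction"] == "pos").sum())
        lines.append(
            f"- {tissue}: {len(sig)} MLS-associated events "
            f"({pos} pos / {len(sig) - pos} neg)"
        )
    spec = read_table(out / "tissue_specificity.tsv")
    if len(spec):
        lines.append(
            f"- multi-tissue: {int(spec['multi_tissue'].sum())} of {len(spec)}; "
            f"divergent in {sim.focal_tissue}: {int(spec['divergent'].sum())}"
        )
    sel = read_table(out / "age_selected.tsv")
    lines.append(f"- age-associated (non-zero coefficient): {int(sel['selected'].sum())}")
    perm = read_table(out / "age_permutation_fdr.tsv")
    lines.append(
        "- permutation FDR by |coef| cutoff: "
        + ", ".join(
            f"{c:g}: {f:.3f}" for c, f in zip(perm.index, perm["fdr"]) if not math.isnan(f)
        )
    )
    frac = read_table(out / "intervention_fractions.tsv")
    lines.append(
        "- intervention upregulated fraction at dPSI>0: "
        + ", ".join(
            f"{c.removeprefix('frac_')}: {frac.iloc[0][c]:.2f}" for c in frac.columns
        )
    )
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(
    out_dir: str | Path,
    sim: synthetic_data.SimConfig | None = None,
    config: Config | None = None,
    stages: Sequence[str] | None = None,
) -> Path:
    """Run the selected stages (default: all, in dependency order)."""
    sim = sim or synthetic_data.SimConfig()
    config = config or Config(seed=sim.seed)
    out = _outdir(out_dir)
    selected = list(stages) if stages else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:
        if stage not in selected:
            continue
        if stage != "simulate" and not (out / "tree.nwk").exists():
            raise RuntimeError(
                f"stage {stage!r} requires outputs of 'simulate' in {out}"
            )
        if stage == "simulate":
            stage_simulate(out, sim, config)
        elif stage == "homology":
            stage_homology(out, config)
        elif stage == "mls-assoc":
            stage_mls_assoc(out, sim, config)
        elif stage == "age-assoc":
            stage_age_assoc(out, sim, config)
        elif stage == "rbp-enrich":
            stage_rbp(out, sim, config)
        elif stage == "intervention":
            stage_intervention(out, config)
        elif stage == "report":
            stage_report(out, sim, config)
    return out
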