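"""End-to-end orchestration: metrics -> profiles -> clustering -> expression.

A single RunConfig drives all stages; stages whose inputs are absent emit
missing (NaN) metric columns rather than fabricated values. All randomness
flows from the configured seed and every output table is written as TSV with
a header, so repeat runs are byte-identical.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model_io import (
    METRIC_ORDER,
    read_alignment_dir,
    read_catalog,
    read_expression_map,
    read_gene_orders,
    read_gff3_gene_models,
    read_bedgraph,
    read_module_partition,
    read_orthology,
    read_snp_table,
    read_tree,
    parse_cafe_report,
    validate_og_metric_table,
    write_metric_table,
)
from .og_metrics import compute_og_metrics, read_identity_table
from .turnover import compute_turnover
from .seq_divergence import compute_divergence_table
from .site_metrics import compute_site_metrics
from .family_profiling import build_family_profiles, family_og_sets, family_metric_matrix
from .profile_clustering import (
    DEFAULT_SCALES,
    DISTANCES,
    LINKAGES,
    pca_profiles,
    run_all_combinations,
    scale_matrix,
    subtree_cooccurrence,
    total_replicates,
)
from .expression_similarity import (
    cooccurrence_table,
    evo_expr_pairing,
    export_similarity_graph,
    module_cooccurrence,
)


@dataclass
class RunConfig:
    out_dir: str
    orthology: str
    tree: str
    catalog: str
    orders: str | None = None
    identities: str | None = None
    alignments: str | None = None
    cafe_report: str | None = None
    snps: str | None = None
    gene_models: str | None = None
    wga_track: str | None = None
    phc_track: str | None = None
    expression_map: str | None = None
    module_partition: str | None = None
    focal_species: str | None = None
    stat: str = "mean"
    n_perm: int = 10_000
    seed: int = 1
    distances: tuple = DISTANCES
    linkages: tuple = LINKAGES
    scales: tuple = DEFAULT_SCALES
    n_per_scale: int = 1000
    resolutions: tuple = ("cell", "supercell")
    headline_combination: tuple = ("pearson", "average")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for name in ("orthology", "tree", "catalog"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"required input {name!r} not found: {p}")
        for name in (
            "orders", "identities", "alignments", "cafe_report", "snps",
            "gene_models", "wga_track", "phc_track", "expression_map",
            "module_partition",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of the in-memory outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    outputs: dict = {}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        tree = read_tree(config.tree)
        orthology = read_orthology(config.orthology, tree.leaf_labels)
        catalog = read_catalog(config.catalog)

        # --- stage: per-OG metrics -------------------------------------
        orders = read_gene_orders(config.orders) if config.orders else None
        identities = (
            read_identity_table(config.identities) if config.identities else None
        )
        og_part = compute_og_metrics(orthology, tree, orders=orders,
                                     identities=identities)

        if config.cafe_report:
            events = parse_cafe_report(config.cafe_report, tree)
            turn = compute_turnover(orthology, tree, cafe_events=events)
        else:
            turn = compute_turnover(orthology, tree)

        parts = [og_part, turn]
        if config.alignments:
            aln = read_alignment_dir(config.alignments)
            parts.append(compute_divergence_table(aln.alignments))

        snps = read_snp_table(config.snps) if config.snps else None
        models = (
            read_gff3_gene_models(config.gene_models) if config.gene_models else None
        )
        wga = (
            read_bedgraph(config.wga_track, value_range=(0, tree.n_leaves))
            if config.wga_track
            else None
        )
        phc = (
            read_bedgraph(config.phc_track, value_range=(0.0, 1.0))
            if config.phc_track
            else None
        )
        if snps is not None or (models is not None and (wga or phc)):
            parts.append(
                compute_site_metrics(
                    orthology, snps=snps, gene_models=models,
                    wga_track=wga, phc_track=phc,
                    focal_species=config.focal_species,
                )
            )

        og_metrics = pd.concat(parts, axis=1)
        og_metrics = og_metrics.reindex(
            columns=[m for m in METRIC_ORDER if m in og_metrics.columns]
        )
        validate_og_metric_table(og_metrics, n_species=tree.n_leaves)
        write_metric_table(og_metrics, out / "og_metrics.tsv")
        outputs["og_metrics"] = og_metrics

        # --- stage: family profiles ------------------------------------
        profiles = build_family_profiles(
            og_metrics, catalog, orthology,
            stat=config.stat, n_perm=config.n_perm, seed=config.seed,
        )
        profiles.to_csv(out / "family_profiles.tsv", sep="\t", index=False,
                        float_format="%.10g")
        outputs["family_profiles"] = profiles

        # --- stage: clustering -----------------------------------------
        og_sets = family_og_sets(catalog, orthology)
        fam_matrix = family_metric_matrix(og_metrics, og_sets, stat=config.stat)
        fam_matrix = fam_matrix.dropna(axis=1, how="any")
        scaled = scale_matrix(fam_matrix)
        results = run_all_combinations(
            scaled, distances=config.distances, linkages=config.linkages,
            scales=config.scales, n_per_scale=config.n_per_scale,
            seed=config.seed,
        )
        n_reps = total_replicates(results)
        head = results[tuple(config.headline_combination)]
        (out / "dendrogram.nwk").write_text(
            head.observed.newick(head.observed.node_support) + "\n"
        )
        all_parents = []
        for res in results.values():
            all_parents.extend(res.replicate_parent_clades)
        evo_sim = subtree_cooccurrence(all_parents, list(scaled.index))
        write_metric_table(evo_sim, out / "family_similarity.tsv",
                           index_label="family")
        loadings, scores, var_frac = pca_profiles(scaled)
        write_metric_table(scores, out / "pca_scores.tsv", index_label="family")
        write_metric_table(loadings, out / "pca_loadings.tsv", index_label="metric")
        var_frac.to_frame("variance_fraction").to_csv(
            out / "pca_variance.tsv", sep="\t", index_label="component"
        )
        outputs["bootstrap"] = results
        outputs["family_similarity"] = evo_sim
        outputs["n_bootstrap_replicates"] = n_reps

        # --- stage: expression similarity ------------------------------
        expr_tables = []
        if config.expression_map:
            emap = read_expression_map(config.expression_map)
            for res_name in config.resolutions:
                tab = cooccurrence_table(
                    emap, catalog, resolution=res_name,
                    n_perm=config.n_perm, seed=config.seed,
                )
                expr_tables.append(tab)
        if config.module_partition:
            partition = read_module_partition(config.module_partition)
            expr_tables.append(
                module_cooccurrence(partition, catalog,
                                    n_perm=config.n_perm, seed=config.seed)
            )
        if expr_tables:
            coexpr = pd.concat(expr_tables, ignore_index=True)
            coexpr.to_csv(out / "coexpression.tsv", sep="\t", index=False,
                          float_format="%.10g")
            outputs["coexpression"] = coexpr
            paired = pd.concat(
                [evo_expr_pairing(evo_sim, t) for t in expr_tables],
                ignore_index=True,
            )
            paired.to_csv(out / "evo_expr_pairs.tsv", sep="\t", index=False,
                          float_format="%.10g")
            outputs["evo_expr_pairs"] = paired
            export_similarity_graph(
                expr_tables[0], out / "similarity_graph.dot",
                all_families=catalog.families,
            )

        caught = [str(w.message) for w in wlist]

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "stat": config.stat,
        "n_ogs": len(orthology.og_ids),
        "n_species": tree.n_leaves,
        "n_families": len(catalog.families),
        "bootstrap_combinations": [
            [d, l] for d in config.distances for l in config.linkages
        ],
        "n_bootstrap_replicates": int(outputs.get("n_bootstrap_replicates", 0)),
        "warnings": caught,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    outputs["run_log"] = run_log
    return outputs
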