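"""Seeded generators for every pipeline input, with ground-truth records.

Each generator is deterministic given its seed and returns the truth needed
to test the downstream metric (per-branch events, true omega, SNP rates,
rearrangement counts, planted expression overlap). The packaged immune
catalog fixture can be instantiated into synthetic gene/OG identifiers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data_model_io import (
    ExpressionMap,
    GeneCatalog,
    GeneModel,
    GenomeGeneOrder,
    NucleotideTrack,
    OrthologyTable,
    SnpAnnotationTable,
    SpeciesTree,
    load_packaged_catalog_summary,
    orthology_from_members,
)
from .og_metrics import PairwiseIdentityTable
from .seq_divergence import STANDARD_CODE


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated dataset."""

    seed: int
    records: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        Path(path).write_text(
            json.dumps({"seed": self.seed, **self.records}, indent=1, default=default)
        )


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(n_leaves: int, root_age: float, seed: int | None = None,
                          rng: np.random.Generator | None = None) -> SpeciesTree:
    """Random coalescent-shaped ultrametric tree scaled to ``root_age`` My.

    Kingman coalescent: lineage pairs merge at Exp(k*(k-1)/2) waiting times;
    all node ages are rescaled so the root sits exactly at ``root_age``.
    """
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    if rng is None:
        rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    lineages = []
    for i in range(n_leaves):
        nd = dendropy.Node(taxon=taxa.new_taxon(label=f"sp{i+1:02d}"))
        lineages.append(nd)
    age = {nd: 0.0 for nd in lineages}
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        age[parent] = t
        lineages = [lineages[x] for x in range(k) if x not in (i, j)]
        lineages.append(parent)
    root = lineages[0]
    factor = root_age / age[root]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = (age[nd.parent_node] - age[nd]) * factor
    return SpeciesTree.from_dendropy(tree)


# ---------------------------------------------------------------------------
# orthology / copy-number evolution


def simulate_orthology(
    tree: SpeciesTree,
    n_ogs: int,
    gain_rate: float,
    loss_rate: float,
    root_count: int = 1,
    seed: int | None = None,
) -> tuple:
    """Gain/loss birth-death simulation of copy counts along the tree.

    Events occur at total rate (gain+loss)*k along a branch, each a gain
    with probability gain/(gain+loss); count 0 is absorbing. OGs extinct in
    all extant species are dropped (count recorded in the truth).
    """
    rng = np.random.default_rng(seed)
    branch_truth = []
    members: dict = {}
    dropped = 0
    kept = 0
    og_index = 0
    while kept < n_ogs:
        og_index += 1
        og = f"og{og_index:05d}"
        counts = {tree.tree.seed_node: int(root_count)}
        events = []
        for parent, child in tree.branches():
            k = counts[parent]
            t_remaining = child.edge.length or 0.0
            while k > 0 and t_remaining > 0:
                rate = (gain_rate + loss_rate) * k
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > t_remaining:
                    break
                t_remaining -= wait
                if rng.random() < gain_rate / (gain_rate + loss_rate):
                    k += 1
                else:
                    k -= 1
            counts[child] = k
            cl = child.taxon.label if child.is_leaf() else child.label
            events.append((og, cl, counts[parent], k, k - counts[parent]))
        leaf_counts = {
            lf.taxon.label: counts[lf] for lf in tree.tree.leaf_node_iter()
        }
        if sum(leaf_counts.values()) == 0:
            dropped += 1
            continue
        kept += 1
        branch_truth.extend(events)
        mem = []
        for sp, c in leaf_counts.items():
            for i in range(c):
                mem.append((f"{og}_{sp}_g{i+1}", sp))
        members[og] = mem
    orthology = orthology_from_members(members, tree.leaf_labels)
    truth = SimulationTruth(
        seed=seed if seed is not None else -1,
        records={
            "dropped_extinct_ogs": dropped,
            "gain_rate": gain_rate,
            "loss_rate": loss_rate,
            "root_count": root_count,
            "branch_events": [
                {"og_id": og, "branch": br, "parent": p, "child": c, "net": d}
                for og, br, p, c, d in branch_truth
            ],
        },
    )
    return orthology, truth


def truth_branch_events(truth: SimulationTruth) -> pd.DataFrame:
    df = pd.DataFrame(truth.records["branch_events"])
    df["label"] = np.select(
        [df["net"] > 0, df["net"] < 0], ["gain", "loss"], default="stable"
    )
    return df


# ---------------------------------------------------------------------------
# codon alignments


_SENSE_CODONS = sorted(c for c, aa in STANDARD_CODE.items() if aa != "*")
_NUCS = "ACGT"


def simulate_codon_alignment(
    n_taxa: int,
    n_codons: int,
    omega: float,
    branch_mutations: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Star-tree codon evolution with nonsynonymous acceptance ratio omega.

    Single-nt proposals (Poisson(branch_mutations) per lineage) are accepted
    always when synonymous, with probability omega when nonsynonymous, and
    never when producing a stop codon.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestor = [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]
    seqs = []
    n_syn = n_nonsyn = 0
    for t in range(n_taxa):
        codons = list(ancestor)
        n_mut = rng.poisson(branch_mutations)
        for _ in range(n_mut):
            ci = int(rng.integers(0, n_codons))
            pos = int(rng.integers(0, 3))
            old = codons[ci]
            alts = [b for b in _NUCS if b != old[pos]]
            new_nt = alts[int(rng.integers(0, 3))]
            new = old[:pos] + new_nt + old[pos + 1:]
            if STANDARD_CODE[new] == "*":
                continue
            if STANDARD_CODE[new] == STANDARD_CODE[old]:
                codons[ci] = new
                n_syn += 1
            elif rng.random() < omega:
                codons[ci] = new
                n_nonsyn += 1
        seqs.append((f"tax{t+1}", "".join(codons)))
    truth = {
        "omega": omega,
        "branch_mutations": branch_mutations,
        "n_syn_substitutions": n_syn,
        "n_nonsyn_substitutions": n_nonsyn,
        "ancestor": "".join(ancestor),
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# genome orders


def simulate_genome_orders(
    orthology: OrthologyTable,
    n_translocations: int,
    seed: int | None = None,
) -> GenomeGeneOrder:
    """Shared ancestral OG order, then random single-gene translocations.

    Every species genome lists its genes on one scaffold, ordered by a
    common ancestral OG order (copies of an OG adjacent), after which each
    species independently receives ``n_translocations`` remove-and-reinsert
    moves. Gene content is preserved by construction.
    """
    rng = np.random.default_rng(seed)
    og_order = list(orthology.og_ids)
    rng.shuffle(og_order)
    orders: dict = {}
    for sp in orthology.species:
        genes = []
        for og in og_order:
            genes.extend(sorted(orthology.genes_of(og, species=sp)))
        for _ in range(n_translocations):
            if len(genes) < 2:
                break
            i = int(rng.integers(0, len(genes)))
            g = genes.pop(i)
            j = int(rng.integers(0, len(genes) + 1))
            genes.insert(j, g)
        orders[sp] = {"scaffold_1": genes}
    return GenomeGeneOrder(orders=orders)


# ---------------------------------------------------------------------------
# SNPs and tracks


def simulate_snps(
    cds_lengths: dict,
    syn_rate: float,
    nonsyn_rate: float,
    seed: int | None = None,
) -> SnpAnnotationTable:
    """Poisson syn/nonsyn SNP counts per gene at per-nt rates."""
    rng = np.random.default_rng(seed)
    genes = sorted(cds_lengths)
    lens = np.array([cds_lengths[g] for g in genes])
    df = pd.DataFrame(
        {
            "n_syn": rng.poisson(syn_rate * lens),
            "n_nonsyn": rng.poisson(nonsyn_rate * lens),
            "cds_length": lens,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return SnpAnnotationTable(table=df)


def make_gene_models(
    cds_lengths: dict, scaffold: str = "scaffold_1", spacing: int = 100
) -> dict:
    """Lay genes head-to-tail on one scaffold (single CDS interval each)."""
    models = {}
    pos = 1
    for g in sorted(cds_lengths):
        length = int(cds_lengths[g])
        models[g] = GeneModel(
            gene_id=g, scaffold=scaffold, strand="+",
            cds_intervals=[(pos, pos + length - 1)],
        )
        pos += length + spacing
    return models


def piecewise_track(
    segments: dict, default: float = 0.0, value_range=(-np.inf, np.inf)
) -> NucleotideTrack:
    """Track from ``scaffold -> [(start, end, value), ...]`` segment lists."""
    intervals = {}
    for scaf, segs in segments.items():
        segs = sorted(segs)
        intervals[scaf] = (
            np.array([s for s, _, _ in segs]),
            np.array([e for _, e, _ in segs]),
            np.array([v for _, _, v in segs], dtype=float),
        )
    return NucleotideTrack(intervals=intervals, default=default, value_range=value_range)


def simulate_tracks(
    gene_models: dict,
    seed: int | None = None,
    segment_length: int = 50,
    value_sampler=None,
    default: float = 0.0,
) -> NucleotideTrack:
    """Piecewise-constant random track covering all gene scaffolds."""
    rng = np.random.default_rng(seed)
    if value_sampler is None:
        value_sampler = lambda r: float(r.uniform(0, 1))  # noqa: E731
    extents: dict = {}
    for gm in gene_models.values():
        end = max(e for _, e in gm.cds_intervals)
        extents[gm.scaffold] = max(extents.get(gm.scaffold, 0), end)
    segments: dict = {}
    for scaf, end in extents.items():
        segs = []
        pos = 0
        while pos < end:
            seg_end = min(end, pos + segment_length)
            segs.append((pos, seg_end, value_sampler(rng)))
            pos = seg_end
        segments[scaf] = segs
    return piecewise_track(segments, default=default)


# ---------------------------------------------------------------------------
# expression map


def simulate_expression_map(
    grid_rows: int,
    grid_cols: int,
    family_sizes: dict,
    planted_pairs=(),
    n_background_genes: int = 0,
    subset_size: int = 3,
    seed: int | None = None,
    species: str = "synthetic",
) -> tuple:
    """Uniform gene placement with planted co-clustering family pairs.

    ``planted_pairs`` is a sequence of ((family1, family2), rho) entries:
    genes of either family land in a shared ``subset_size``-cell subset with
    probability rho, otherwise uniformly anywhere.
    """
    rng = np.random.default_rng(seed)
    n_cells = grid_rows * grid_cols
    planted = {}
    truth_pairs = []
    for (f1, f2), rho in planted_pairs:
        subset = rng.choice(n_cells, size=min(subset_size, n_cells), replace=False)
        planted[f1] = (subset, rho)
        planted[f2] = (subset, rho)
        truth_pairs.append({"pair": [f1, f2], "rho": rho,
                            "cells": subset.tolist()})
    cell_of = {}
    assignments = {}
    for fam in sorted(family_sizes):
        for i in range(family_sizes[fam]):
            g = f"{fam}_gene_{i+1:03d}"
            if fam in planted and rng.random() < planted[fam][1]:
                flat = int(rng.choice(planted[fam][0]))
            else:
                flat = int(rng.integers(0, n_cells))
            cell_of[g] = (flat // grid_cols, flat % grid_cols)
            assignments[g] = (fam, species)
    for i in range(n_background_genes):
        g = f"bg_gene_{i+1:05d}"
        flat = int(rng.integers(0, n_cells))
        cell_of[g] = (flat // grid_cols, flat % grid_cols)
    emap = ExpressionMap(grid_rows=grid_rows, grid_cols=grid_cols,
                         cell_of=cell_of, toroidal=True)
    catalog = GeneCatalog(assignments=assignments)
    truth = SimulationTruth(
        seed=seed if seed is not None else -1,
        records={"planted_pairs": truth_pairs, "subset_size": subset_size},
    )
    return emap, catalog, truth


# ---------------------------------------------------------------------------
# pairwise identities (background + per OG)


def simulate_identities(
    orthology: OrthologyTable,
    tree: SpeciesTree,
    seed: int | None = None,
    divergence_factor: float = 1.0,
) -> PairwiseIdentityTable:
    """Background identities from tree distances; OG identities jittered."""
    rng = np.random.default_rng(seed)
    species = tree.leaf_labels
    background = {}
    root_age = tree.root_age or 1.0
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            age = tree.mrca_age([s1, s2])
            background[frozenset({s1, s2})] = 95.0 - 40.0 * (age / root_age)
    og_identity = {}
    for og in orthology.og_ids:
        present = orthology.species_present(og)
        d = {}
        for i, s1 in enumerate(sorted(present)):
            for s2 in sorted(present)[i + 1:]:
                pair = frozenset({s1, s2})
                bg = background[pair]
                ident = 100.0 - divergence_factor * (100.0 - bg) * rng.uniform(0.5, 1.5)
                d[pair] = float(np.clip(ident, 0.0, 100.0))
        og_identity[og] = d
    return PairwiseIdentityTable(background=background, og_identity=og_identity)


# ---------------------------------------------------------------------------
# packaged catalog fixture


def table2_fixture() -> pd.DataFrame:
    """Per-family gene/OG counts of the packaged immune catalog."""
    return load_packaged_catalog_summary()


def instantiate_catalog(
    species: str = "anopheles_gambiae",
) -> tuple:
    """Synthetic gene/OG identifiers realizing the packaged per-family counts.

    Returns (GeneCatalog, og_members) where og_members maps each synthetic OG
    id to its genes; genes are distributed over a family's OGs as evenly as
    possible (every OG gets >= 1 gene).
    """
    summary = table2_fixture()
    gene_col = f"{species}_genes"
    og_col = f"{species}_ogs"
    assignments = {}
    og_members: dict = {}
    for fam, row in summary.iterrows():
        n_genes = int(row[gene_col])
        n_ogs = int(row[og_col])
        genes = [f"{fam}_gene_{i+1:03d}" for i in range(n_genes)]
        for g in genes:
            assignments[g] = (fam, species)
        if n_ogs == 0:
            continue
        base, extra = divmod(n_genes, n_ogs)
        gi = 0
        for k in range(n_ogs):
            take = base + (1 if k < extra else 0)
            og_members[f"{fam}_og_{k+1:03d}"] = [
                (g, species) for g in genes[gi: gi + take]
            ]
            gi += take
    vocab = frozenset(summary.index)
    return GeneCatalog(assignments=assignments, family_vocabulary=vocab), og_members


# ---------------------------------------------------------------------------
# full input bundle


def simulate_bundle(
    seed: int,
    out_dir,
    n_species: int = 8,
    n_ogs: int = 60,
    n_families: int = 10,
    root_age: float = 250.0,
    gain_rate: float = 0.001,
    loss_rate: float = 0.001,
    grid: tuple = (10, 10),
    n_perm_hint: int = 1000,
) -> dict:
    """Write a complete, mutually consistent synthetic input bundle.

    Produces every file the pipeline consumes plus a truth JSON; returns the
    mapping of logical input name -> path.
    """
    from .data_model_io import (
        write_bedgraph,
        write_catalog,
        write_codon_alignment,
        write_expression_map,
        write_gene_orders,
        write_gff3_gene_models,
        write_orthology,
        write_snp_table,
        write_tree,
    )
    from .og_metrics import write_identity_table

    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = simulate_species_tree(n_species, root_age, rng=rng)
    orthology, orth_truth = simulate_orthology(
        tree, n_ogs, gain_rate, loss_rate, root_count=1,
        seed=int(rng.integers(2**31)),
    )
    orders = simulate_genome_orders(orthology, 0, seed=int(rng.integers(2**31)))
    identities = simulate_identities(orthology, tree, seed=int(rng.integers(2**31)))

    focal = tree.leaf_labels[0]
    # family catalog over focal-species genes, round-robin over OGs
    assignments = {}
    fam_names = [f"FAM{i+1:02d}" for i in range(n_families)]
    for i, og in enumerate(orthology.og_ids):
        fam = fam_names[i % n_families]
        for g in orthology.genes_of(og, species=focal):
            assignments[g] = (fam, focal)
    catalog = GeneCatalog(assignments=assignments)

    # codon alignments per OG (sequence ids = member genes)
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    omega_truth = {}
    for og in orthology.og_ids:
        genes = [g for g, _sp in orthology.members[og]]
        n_taxa = min(len(genes), 5)
        if n_taxa < 2:
            continue
        omega = float(rng.choice([0.2, 0.5, 1.0]))
        seqs, t = simulate_codon_alignment(
            n_taxa, 100, omega, branch_mutations=15.0, rng=rng
        )
        seqs = [(genes[i], s) for i, (_, s) in enumerate(seqs)]
        write_codon_alignment(seqs, aln_dir / f"{og}.fasta")
        omega_truth[og] = omega

    # SNPs, gene models, tracks for the focal species
    focal_genes = sorted(
        g for og in orthology.og_ids for g in orthology.genes_of(og, species=focal)
    )
    cds_lengths = {g: 300 for g in focal_genes}
    snps = simulate_snps(cds_lengths, 0.02, 0.005, seed=int(rng.integers(2**31)))
    models = make_gene_models(cds_lengths)
    wga = simulate_tracks(
        models, seed=int(rng.integers(2**31)),
        value_sampler=lambda r: float(r.integers(0, n_species + 1)),
    )
    phc = simulate_tracks(models, seed=int(rng.integers(2**31)))

    # expression map with one planted family pair
    fam_sizes = {
        f: max(1, len(catalog.genes_of_family(f))) for f in catalog.families
    }
    planted = [((fam_names[0], fam_names[1]), 0.9)]
    emap, _map_catalog, map_truth = simulate_expression_map(
        grid[0], grid[1],
        fam_sizes, planted_pairs=planted,
        n_background_genes=200, seed=int(rng.integers(2**31)),
    )
    # re-map synthetic map genes onto the real catalog genes, family by family
    remap = {}
    for fam in catalog.families:
        real = catalog.genes_of_family(fam)
        synth = [g for g in sorted(emap.cell_of) if g.startswith(f"{fam}_gene_")]
        for rg, sg in zip(real, synth):
            remap[rg] = emap.cell_of[sg]
    for g, cell in emap.cell_of.items():
        if g.startswith("bg_gene_"):
            remap[g] = cell
    emap = ExpressionMap(grid_rows=emap.grid_rows, grid_cols=emap.grid_cols,
                         cell_of=remap, toroidal=True)

    paths = {
        "tree": out / "species_tree.nwk",
        "orthology": out / "orthology.tsv",
        "orders": out / "gene_orders.tsv",
        "identities": out / "identities.tsv",
        "catalog": out / "catalog.tsv",
        "alignments": aln_dir,
        "snps": out / "snps.tsv",
        "gene_models": out / "genes.gff3",
        "wga_track": out / "wga.bedgraph",
        "phc_track": out / "phastcons.bedgraph",
        "expression_map": out / "expression_map.tsv",
    }
    write_tree(tree, paths["tree"])
    write_orthology(orthology, paths["orthology"])
    write_gene_orders(orders, paths["orders"])
    write_identity_table(identities, paths["identities"])
    write_catalog(catalog, paths["catalog"])
    write_snp_table(snps, paths["snps"])
    write_gff3_gene_models(models, paths["gene_models"])
    write_bedgraph(wga, paths["wga_track"])
    write_bedgraph(phc, paths["phc_track"])
    write_expression_map(emap, paths["expression_map"])

    truth = SimulationTruth(
        seed=seed,
        records={
            "focal_species": focal,
            "omega_per_og": omega_truth,
            "snp_rates": {"syn": 0.02, "nonsyn": 0.005},
            "n_translocations": 0,
            "orthology": orth_truth.records,
            "expression_map": map_truth.records,
        },
    )
    truth.to_json(out / "truth.json")
    result = {k: str(v) for k, v in paths.items()}
    result["focal_species"] = focal
    return result
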