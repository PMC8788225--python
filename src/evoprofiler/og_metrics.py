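"""Orthology-based per-OG metrics: AGE, UNI, DUP, ACN, CNV, SYN, EVR.

AGE is the age (My) of the MRCA of the species present in an OG; UNI the
fraction of all species represented; DUP the fraction of represented species
with >= 2 copies; ACN/CNV mean and relative spread of copy numbers over
species present; SYN the fraction of cross-species ortholog comparisons that
retain a shared flanking-gene OG; EVR a background-normalized protein
divergence ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import (
    DataModelError,
    GenomeGeneOrder,
    OrthologyTable,
    SpeciesTree,
)


@dataclass
class PairwiseIdentityTable:
    """Background and per-OG protein % identities per species pair."""

    background: dict  # frozenset({sp1, sp2}) -> mean % identity
    og_identity: dict  # og_id -> {frozenset({sp1, sp2}): mean member % identity}

    def __post_init__(self) -> None:
        for d in [self.background, *self.og_identity.values()]:
            for pair, v in d.items():
                if not (0.0 <= v <= 100.0):
                    raise DataModelError(f"identity out of [0,100] for pair {set(pair)}")


def compute_age(species_present, tree: SpeciesTree) -> float:
    species = sorted(set(species_present))
    if not species:
        raise DataModelError("empty OG")
    return tree.mrca_age(species)


def compute_uni(species_present, n_total_species: int) -> float:
    if n_total_species <= 0:
        raise DataModelError("n_total_species must be positive")
    species = set(species_present)
    if not species:
        raise DataModelError("empty OG")
    return len(species) / n_total_species


def compute_dup(counts_present) -> float:
    counts = np.asarray([c for c in counts_present if c > 0])
    if counts.size == 0:
        raise DataModelError("empty OG")
    return float((counts >= 2).sum() / counts.size)


def compute_acn_cnv(counts_present, ddof: int = 1) -> tuple:
    """Mean copy number and sd/mean over species present (zeros excluded).

    ddof=1 gives the sample sd convention; a single-species OG has CNV = 0.
    """
    counts = np.asarray([c for c in counts_present if c > 0], dtype=float)
    if counts.size == 0:
        raise DataModelError("empty OG")
    acn = float(counts.mean())
    sd = float(counts.std(ddof=ddof)) if counts.size > ddof else 0.0
    return acn, sd / acn


def compute_syn(
    og: str,
    orthology: OrthologyTable,
    orders: GenomeGeneOrder,
    window: int = 1,
    per_gene: bool = False,
) -> float:
    """Fraction of ortholog comparisons that keep a shared neighbor OG.

    For each gene g of the OG in species s and each other species s' with
    >= 1 ortholog, the (g, s') pair is "maintained" when the OG set of g's
    flanking genes (<= window per side) intersects the flank OG set of any
    ortholog in s'. Genes with no flanks (singleton scaffolds) are excluded
    from the denominator. With ``per_gene`` a gene counts once, maintained
    when it is maintained against at least one other species.
    """
    gene_to_og = orthology.gene_to_og()
    members = orthology.members[og]

    def flank_ogs(sp: str, gene: str):
        nbrs = orders.neighbors(sp, gene, window=window)
        if orders.locate(sp, gene) is None:
            return None  # gene not placed in this genome
        return {gene_to_og[n] for n in nbrs if n in gene_to_og}

    placed = [(g, sp) for g, sp in members if orders.locate(sp, g) is not None]
    if not placed:
        return np.nan

    by_species: dict = {}
    for g, sp in placed:
        by_species.setdefault(sp, []).append(g)

    flanks = {(g, sp): flank_ogs(sp, g) for g, sp in placed}

    evaluated = 0
    maintained = 0
    gene_hits: dict = {}
    for g, sp in placed:
        fg = flanks[(g, sp)]
        if not fg:  # flankless gene: excluded from denominator
            continue
        for sp2, genes2 in by_species.items():
            if sp2 == sp:
                continue
            flank_union = set()
            any_flanked = False
            for g2 in genes2:
                f2 = flanks[(g2, sp2)]
                if f2:
                    any_flanked = True
                    flank_union |= f2
            if not any_flanked:
                continue
            evaluated += 1
            hit = bool(fg & flank_union)
            maintained += hit
            key = (g, sp)
            gene_hits[key] = gene_hits.get(key, False) or hit

    if per_gene:
        if not gene_hits:
            return np.nan
        return sum(gene_hits.values()) / len(gene_hits)
    if evaluated == 0:
        return np.nan
    return maintained / evaluated


def compute_evr(
    og: str, species_present, identities: PairwiseIdentityTable
) -> float:
    """Mean over species pairs of (100 - OG identity)/(100 - background)."""
    species = sorted(set(species_present))
    og_ids = identities.og_identity.get(og, {})
    ratios = []
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            pair = frozenset({s1, s2})
            if pair not in identities.background:
                raise DataModelError(f"no background identity for pair {set(pair)}")
            bg = identities.background[pair]
            if bg >= 100.0:
                continue  # zero background divergence: skip
            if pair not in og_ids:
                continue
            ratios.append((100.0 - og_ids[pair]) / (100.0 - bg))
    if not ratios:
        return np.nan
    return float(np.mean(ratios))


def compute_og_metrics(
    orthology: OrthologyTable,
    tree: SpeciesTree,
    orders: GenomeGeneOrder | None = None,
    identities: PairwiseIdentityTable | None = None,
    syn_window: int = 1,
) -> pd.DataFrame:
    """Per-OG table of the orthology-based metrics (NaN where not computable)."""
    n_total = tree.n_leaves
    rows = {}
    for og in orthology.og_ids:
        present = orthology.species_present(og)
        counts = [int(orthology.counts.at[og, sp]) for sp in present]
        rec = {
            "AGE": compute_age(present, tree),
            "UNI": compute_uni(present, n_total),
            "DUP": compute_dup(counts),
        }
        rec["ACN"], rec["CNV"] = compute_acn_cnv(counts)
        if orders is not None:
            rec["SYN"] = compute_syn(og, orthology, orders, window=syn_window)
        if identities is not None:
            rec["EVR"] = compute_evr(og, present, identities)
        rows[og] = rec
    cols = ["AGE", "UNI", "DUP", "ACN", "CNV"]
    if orders is not None:
        cols.append("SYN")
    if identities is not None:
        cols.append("EVR")
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=orthology.og_ids, columns=cols
    )


def read_identity_table(path) -> PairwiseIdentityTable:
    """TSV with columns og_id, species1, species2, identity; background rows
    use og_id = '__background__'."""
    df = pd.read_csv(path, sep="\t", dtype={"og_id": str})
    background = {}
    og_identity: dict = {}
    for r in df.itertuples(index=False):
        pair = frozenset({r.species1, r.species2})
        if r.og_id == "__background__":
            background[pair] = float(r.identity)
        else:
            og_identity.setdefault(r.og_id, {})[pair] = float(r.identity)
    return PairwiseIdentityTable(background=background, og_identity=og_identity)


def write_identity_table(identities: PairwiseIdentityTable, path) -> None:
    rows = []
    for pair, v in sorted(identities.background.items(), key=lambda kv: sorted(kv[0])):
        s1, s2 = sorted(pair)
        rows.append(("__background__", s1, s2, v))
    for og in sorted(identities.og_identity):
        for pair, v in sorted(
            identities.og_identity[og].items(), key=lambda kv: sorted(kv[0])
        ):
            s1, s2 = sorted(pair)
            rows.append((og, s1, s2, v))
    pd.DataFrame(rows, columns=["og_id", "species1", "species2", "identity"]).to_csv(
        path, sep="\t", index=False
    )
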