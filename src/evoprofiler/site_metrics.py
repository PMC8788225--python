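"""Variation-based (NSP, NSD, SSD) and alignment-based (WGA, PHC) metrics.

Per-gene values are computed from SNP annotation tables and per-nucleotide
tracks averaged over CDS length, then aggregated to per-OG values by an
unweighted mean over member genes of the focal species.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model_io import (
    DataModelError,
    GeneModel,
    NucleotideTrack,
    OrthologyTable,
    SnpAnnotationTable,
)


def snp_metrics(n_syn: int, n_nonsyn: int, cds_length: int) -> tuple:
    """(NSP, NSD, SSD) for one gene; NSP is NaN when the gene has no SNPs."""
    if n_syn < 0 or n_nonsyn < 0:
        raise DataModelError("negative SNP counts")
    if cds_length <= 0:
        raise DataModelError("non-positive CDS length")
    total = n_syn + n_nonsyn
    nsp = n_nonsyn / total if total > 0 else np.nan
    return nsp, n_nonsyn / cds_length, n_syn / cds_length


def snp_metrics_table(snps: SnpAnnotationTable) -> pd.DataFrame:
    """Per-gene NSP/NSD/SSD frame indexed by gene_id."""
    t = snps.table
    total = t["n_syn"] + t["n_nonsyn"]
    out = pd.DataFrame(index=t.index)
    out["NSP"] = np.where(total > 0, t["n_nonsyn"] / total.replace(0, 1), np.nan)
    out["NSD"] = t["n_nonsyn"] / t["cds_length"]
    out["SSD"] = t["n_syn"] / t["cds_length"]
    return out


def track_mean_over_cds(gene: GeneModel, track: NucleotideTrack) -> float:
    """Length-weighted mean track value over the union of CDS intervals.

    Positions with no track interval contribute the track default.
    """
    spans = gene.cds_spans_0based()
    if sum(e - s for s, e in spans) <= 0:
        raise DataModelError(f"gene {gene.gene_id!r} has zero CDS length")
    return track.mean_over(gene.scaffold, spans)


def track_metrics_table(
    gene_models: dict, wga: NucleotideTrack | None = None,
    phc: NucleotideTrack | None = None,
) -> pd.DataFrame:
    rows = {}
    for g in sorted(gene_models):
        rec = {}
        if wga is not None:
            rec["WGA"] = track_mean_over_cds(gene_models[g], wga)
        if phc is not None:
            rec["PHC"] = track_mean_over_cds(gene_models[g], phc)
        rows[g] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


def aggregate_gene_to_og(
    per_gene: pd.DataFrame,
    orthology: OrthologyTable,
    focal_species: str | None = None,
) -> pd.DataFrame:
    """Unweighted mean of per-gene metric values over each OG's member genes.

    With ``focal_species``, only that species' genes contribute (the
    variation/alignment data come from a single reference genome); OGs with no
    measured gene get NaN throughout.
    """
    rows = {}
    for og in orthology.og_ids:
        genes = [
            g
            for g, sp in orthology.members[og]
            if focal_species is None or sp == focal_species
        ]
        genes = [g for g in genes if g in per_gene.index]
        if genes:
            rows[og] = per_gene.loc[genes].mean(axis=0, skipna=True)
        else:
            rows[og] = pd.Series(np.nan, index=per_gene.columns)
    return pd.DataFrame.from_dict(rows, orient="index").reindex(orthology.og_ids)


def compute_site_metrics(
    orthology: OrthologyTable,
    snps: SnpAnnotationTable | None = None,
    gene_models: dict | None = None,
    wga_track: NucleotideTrack | None = None,
    phc_track: NucleotideTrack | None = None,
    focal_species: str | None = None,
) -> pd.DataFrame:
    """Per-OG NSP/NSD/SSD/WGA/PHC (columns present only when inputs are)."""
    parts = []
    if snps is not None:
        parts.append(snp_metrics_table(snps))
    if gene_models is not None and (wga_track is not None or phc_track is not None):
        parts.append(track_metrics_table(gene_models, wga_track, phc_track))
    if not parts:
        return pd.DataFrame(index=orthology.og_ids)
    per_gene = pd.concat(parts, axis=1)
    return aggregate_gene_to_og(per_gene, orthology, focal_species=focal_species)
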