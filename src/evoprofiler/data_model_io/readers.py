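"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are centralized here: GFF3 is 1-based inclusive,
bedGraph is 0-based half-open. All tables are written with a header row and
deterministic column order so that write->read round-trips are exact.
"""
from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .types import (
    CodonAlignmentSet,
    DataModelError,
    ExpressionMap,
    ExpressionMatrix,
    GeneCatalog,
    GeneModel,
    GenomeGeneOrder,
    NucleotideTrack,
    OrthologyTable,
    SnpAnnotationTable,
    SpeciesTree,
)

# ---------------------------------------------------------------------------
# species tree


def read_tree(path) -> SpeciesTree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return SpeciesTree.from_dendropy(tree)


def read_tree_string(newick: str) -> SpeciesTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return SpeciesTree.from_dendropy(tree)


def write_tree(tree: SpeciesTree, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# orthology


def read_orthology(path, species_list: Sequence[str]) -> OrthologyTable:
    """Read a TSV with columns og_id, gene_id, species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise DataModelError("no records in orthology table")
    for col in ("og_id", "gene_id", "species"):
        if col not in df.columns:
            raise DataModelError(f"orthology table missing column {col!r}")
    unknown = set(df["species"]) - set(species_list)
    if unknown:
        raise DataModelError(f"species not in declared species list: {sorted(unknown)}")
    dup = df.duplicated(subset=["og_id", "gene_id", "species"])
    if dup.any():
        off = df.loc[dup].iloc[0]
        raise DataModelError(
            f"duplicate gene {off['gene_id']!r} in OG {off['og_id']!r}"
            f" for species {off['species']!r}"
        )
    return orthology_from_members(
        {
            og: list(zip(sub["gene_id"], sub["species"]))
            for og, sub in df.groupby("og_id", sort=True)
        },
        species_list,
    )


def orthology_from_members(members: dict, species_list: Sequence[str]) -> OrthologyTable:
    og_ids = sorted(members)
    counts = pd.DataFrame(0, index=og_ids, columns=list(species_list), dtype=int)
    for og, mem in members.items():
        for _gene, sp in mem:
            counts.at[og, sp] += 1
    return OrthologyTable(counts=counts, members={og: list(members[og]) for og in og_ids})


def write_orthology(orthology: OrthologyTable, path) -> None:
    rows = []
    for og in orthology.og_ids:
        for gene, sp in sorted(orthology.members[og]):
            rows.append((og, gene, sp))
    pd.DataFrame(rows, columns=["og_id", "gene_id", "species"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene catalog


def read_catalog(path, vocabulary: Iterable[str] | None = None) -> GeneCatalog:
    """Read a TSV with columns gene_id, family, species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "family", "species"):
        if col not in df.columns:
            raise DataModelError(f"catalog missing column {col!r}")
    if df["gene_id"].duplicated().any():
        g = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataModelError(f"gene {g!r} assigned to more than one family")
    assignments = {
        r.gene_id: (r.family, r.species) for r in df.itertuples(index=False)
    }
    vocab = frozenset(vocabulary) if vocabulary is not None else frozenset()
    return GeneCatalog(assignments=assignments, family_vocabulary=vocab)


def write_catalog(catalog: GeneCatalog, path) -> None:
    rows = sorted(
        (g, fam, sp) for g, (fam, sp) in catalog.assignments.items()
    )
    pd.DataFrame(rows, columns=["gene_id", "family", "species"]).to_csv(
        path, sep="\t", index=False
    )


def load_packaged_catalog_summary() -> pd.DataFrame:
    """Per-family gene and OG counts for the packaged immune catalog fixture."""
    with resources.files("evoprofiler.data").joinpath("immune_catalog.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("family")


# ---------------------------------------------------------------------------
# genome gene order


def read_gene_orders(path) -> GenomeGeneOrder:
    """Read a TSV with columns species, scaffold, position, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype={"position": int}, keep_default_na=False)
    for col in ("species", "scaffold", "position", "gene_id"):
        if col not in df.columns:
            raise DataModelError(f"gene-order table missing column {col!r}")
    orders: dict = {}
    for (sp, scaf), sub in df.groupby(["species", "scaffold"], sort=True):
        sub = sub.sort_values("position")
        orders.setdefault(sp, {})[scaf] = list(sub["gene_id"])
    return GenomeGeneOrder(orders=orders)


def write_gene_orders(orders: GenomeGeneOrder, path) -> None:
    rows = []
    for sp in sorted(orders.orders):
        for scaf in sorted(orders.orders[sp]):
            for i, g in enumerate(orders.orders[sp][scaf]):
                rows.append((sp, scaf, i, g))
    pd.DataFrame(rows, columns=["species", "scaffold", "position", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# codon alignments (FASTA)


def read_codon_alignment(path) -> list:
    """Read one FASTA codon alignment as a list of (seq_id, sequence)."""
    from Bio import SeqIO

    seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise DataModelError(f"no sequences in {path}")
    return seqs


def read_alignment_dir(directory) -> CodonAlignmentSet:
    """Read every ``<og_id>.fasta`` / ``.fa`` / ``.fna`` file in a directory."""
    directory = Path(directory)
    alignments = {}
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in {".fasta", ".fa", ".fna"}:
            alignments[p.stem] = read_codon_alignment(p)
    if not alignments:
        raise DataModelError(f"no FASTA alignments found in {directory}")
    return CodonAlignmentSet(alignments=alignments)


def write_codon_alignment(seqs, path) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs:
            fh.write(f">{sid}\n{s}\n")


# ---------------------------------------------------------------------------
# SNP annotation


def read_snp_table(path) -> SnpAnnotationTable:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise DataModelError("SNP table missing column 'gene_id'")
    return SnpAnnotationTable(table=df.set_index("gene_id"))


def write_snp_table(snps: SnpAnnotationTable, path) -> None:
    snps.table.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        path, sep="\t", index=False
    )


_SYN_TERMS = {"synonymous_variant", "synonymous", "stop_retained_variant"}
_NONSYN_TERMS = {
    "missense_variant", "missense", "nonsynonymous",
    "stop_gained", "stop_lost", "start_lost",
}


def classify_ann_consequence(term: str) -> str | None:
    """Map an ANN-style consequence string to 'syn'/'nonsyn' (None otherwise)."""
    t = term.strip().lower()
    if t in _SYN_TERMS:
        return "syn"
    if t in _NONSYN_TERMS:
        return "nonsyn"
    return None


def snp_table_from_annotated_vcf(path, cds_lengths: dict) -> SnpAnnotationTable:
    """Minimal reader for VCFs with ANN=...|consequence|...|gene| fields.

    Only coding consequence terms mapping to syn/nonsyn are tallied.
    """
    counts: dict = {g: [0, 0] for g in cds_lengths}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                continue
            m = re.search(r"ANN=([^;]+)", fields[7])
            if not m:
                continue
            for ann in m.group(1).split(","):
                parts = ann.split("|")
                if len(parts) < 4:
                    continue
                kind = classify_ann_consequence(parts[1])
                gene = parts[3]
                if kind and gene in counts:
                    counts[gene][0 if kind == "syn" else 1] += 1
    df = pd.DataFrame(
        {
            "gene_id": list(counts),
            "n_syn": [counts[g][0] for g in counts],
            "n_nonsyn": [counts[g][1] for g in counts],
            "cds_length": [cds_lengths[g] for g in counts],
        }
    ).set_index("gene_id")
    return SnpAnnotationTable(table=df)


# ---------------------------------------------------------------------------
# nucleotide tracks (bedGraph)


def read_bedgraph(path, default: float = 0.0, value_range=( -np.inf, np.inf)) -> NucleotideTrack:
    df = pd.read_csv(
        path, sep="\t", comment="t", header=None,
        names=["scaffold", "start", "end", "value"],
        dtype={"scaffold": str},
        skiprows=_count_bedgraph_header_lines(path),
    )
    intervals = {}
    for scaf, sub in df.groupby("scaffold", sort=True):
        sub = sub.sort_values("start")
        intervals[scaf] = (
            sub["start"].to_numpy(int),
            sub["end"].to_numpy(int),
            sub["value"].to_numpy(float),
        )
    return NucleotideTrack(intervals=intervals, default=default, value_range=value_range)


def _count_bedgraph_header_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")):
                n += 1
            else:
                break
    return n


def write_bedgraph(track: NucleotideTrack, path) -> None:
    with open(path, "w") as fh:
        for scaf in sorted(track.intervals):
            starts, ends, values = track.intervals[scaf]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{scaf}\t{int(s)}\t{int(e)}\t{v:g}\n")


# ---------------------------------------------------------------------------
# gene models (GFF3)


def read_gff3_gene_models(path) -> dict:
    """Extract one GeneModel per gene from GFF3 CDS features.

    CDS features are attached to genes via the ``Parent=`` or ``gene_id``
    attribute (one transcript/model per gene in all fixtures).
    """
    per_gene: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene = attrs.get("Parent") or attrs.get("gene_id") or attrs.get("ID")
            if gene is None:
                raise DataModelError("CDS feature without Parent/gene_id attribute")
            per_gene.setdefault(gene, []).append((int(f[3]), int(f[4])))
            meta[gene] = (f[0], f[6])
    if not per_gene:
        raise DataModelError(f"no CDS features in {path}")
    return {
        g: GeneModel(gene_id=g, scaffold=meta[g][0], strand=meta[g][1],
                     cds_intervals=sorted(iv))
        for g, iv in per_gene.items()
    }


def write_gff3_gene_models(models: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models):
            gm = models[g]
            for s, e in gm.cds_intervals:
                fh.write(
                    f"{gm.scaffold}\t.\tCDS\t{s}\t{e}\t.\t{gm.strand}\t0\t"
                    f"Parent={gm.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# expression map / matrix


def read_expression_map(path, grid_rows: int | None = None,
                        grid_cols: int | None = None, toroidal: bool = True) -> ExpressionMap:
    """TSV with columns gene_id, row, col (grid dims inferred if omitted)."""
    df = pd.read_csv(path, sep="\t", dtype={"row": int, "col": int})
    for col in ("gene_id", "row", "col"):
        if col not in df.columns:
            raise DataModelError(f"expression map missing column {col!r}")
    if grid_rows is None:
        grid_rows = int(df["row"].max()) + 1
    if grid_cols is None:
        grid_cols = int(df["col"].max()) + 1
    cell_of = {r.gene_id: (r.row, r.col) for r in df.itertuples(index=False)}
    return ExpressionMap(grid_rows=grid_rows, grid_cols=grid_cols,
                         cell_of=cell_of, toroidal=toroidal)


def write_expression_map(emap: ExpressionMap, path) -> None:
    rows = sorted((g, r, c) for g, (r, c) in emap.cell_of.items())
    pd.DataFrame(rows, columns=["gene_id", "row", "col"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_module_partition(path) -> dict:
    """TSV with columns gene_id, module."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "module"):
        if col not in df.columns:
            raise DataModelError(f"partition missing column {col!r}")
    return dict(zip(df["gene_id"], df["module"]))


# ---------------------------------------------------------------------------
# external tool reports


def parse_cafe_report(path, tree: SpeciesTree) -> pd.DataFrame:
    """Parse a CAFE-style per-family per-branch count-change report.

    Expected TSV columns: og_id, branch (child-node label), delta. Returns a
    tidy frame with the gain/loss/stable label per (og, branch).
    """
    df = pd.read_csv(path, sep="\t", dtype={"og_id": str, "branch": str})
    for col in ("og_id", "branch", "delta"):
        if col not in df.columns:
            raise DataModelError(f"CAFE report missing column {col!r}")
    valid = set(tree.branch_labels())
    bad = set(df["branch"]) - valid
    if bad:
        raise DataModelError(f"CAFE report branches not in tree: {sorted(bad)}")
    df = df.copy()
    df["label"] = np.select(
        [df["delta"] > 0, df["delta"] < 0], ["gain", "loss"], default="stable"
    )
    return df[["og_id", "branch", "delta", "label"]]


_PAML_NUM = r"([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)"


def parse_paml_m0(path) -> tuple:
    """Extract (dS, dN, dN/dS) from a PAML mlc-style output file.

    Returns (PDS, PDN, SEL); SEL is NaN when dS == 0.
    """
    text = Path(path).read_text()
    ds = re.search(r"\bdS\s*=\s*" + _PAML_NUM, text)
    dn = re.search(r"\bdN\s*=\s*" + _PAML_NUM, text)
    if ds is None or dn is None:
        missing = "dS" if ds is None else "dN"
        raise DataModelError(f"PAML output missing required field {missing!r}")
    pds = float(ds.group(1))
    pdn = float(dn.group(1))
    if pds < 0 or pdn < 0:
        raise DataModelError("negative dN/dS values in PAML output")
    sel = pdn / pds if pds > 0 else np.nan
    return pds, pdn, sel


# ---------------------------------------------------------------------------
# metric tables


def write_metric_table(table: pd.DataFrame, path, index_label: str = "og_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_metric_table(path, index_col: str = "og_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
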