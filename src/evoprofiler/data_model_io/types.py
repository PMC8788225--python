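"""Domain types shared across the profiling pipeline.

All tabular types are thin, validated wrappers around pandas objects; the
species tree wraps a dendropy tree with precomputed node ages. Missing metric
values are always represented as NaN, never as 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

#: canonical column order for the 18 per-OG metrics
METRIC_ORDER = [
    "AGE", "UNI", "DUP", "ACN", "CNV", "EXP", "CON", "STA", "SYN", "EVR",
    "PDS", "PDN", "SEL", "NSP", "NSD", "SSD", "WGA", "PHC",
]

ULTRAMETRIC_RTOL = 1e-6


class DataModelError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign deterministic labels N1, N2, ... to unlabeled internal nodes
    (postorder), so branches can be addressed by child-node label."""
    i = 0
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            continue
        if nd.label is None or nd.label == "":
            i += 1
            nd.label = f"N{i}"


@dataclass
class SpeciesTree:
    """Rooted ultrametric species tree with node ages in My before present."""

    tree: dendropy.Tree
    ages: dict = field(default_factory=dict)  # node -> age (My)
    is_ultrametric: bool = True

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> "SpeciesTree":
        tree.is_rooted = True
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lb is None for lb in labels):
            raise DataModelError("tree contains an unlabeled leaf")
        if len(set(labels)) != len(labels):
            raise DataModelError("duplicate leaf labels in species tree")
        _label_internal_nodes(tree)
        depth = {tree.seed_node: 0.0}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            depth[nd] = depth[nd.parent_node] + bl
        leaf_depths = np.array([depth[lf] for lf in tree.leaf_node_iter()])
        max_depth = float(leaf_depths.max()) if len(leaf_depths) else 0.0
        ultra = True
        if max_depth > 0 and (max_depth - leaf_depths.min()) > rtol * max_depth:
            ultra = False
            warnings.warn(
                "tree is not ultrametric; node ages taken from max root-to-tip depth",
                stacklevel=3,
            )
        ages = {nd: max_depth - d for nd, d in depth.items()}
        if ultra:
            for lf in tree.leaf_node_iter():
                ages[lf] = 0.0
        return cls(tree=tree, ages=ages, is_ultrametric=ultra)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def root_age(self) -> float:
        return self.ages[self.tree.seed_node]

    def mrca_age(self, species: Iterable[str]) -> float:
        species = list(set(species))
        if not species:
            raise DataModelError("empty species set has no MRCA")
        missing = set(species) - set(self.leaf_labels)
        if missing:
            raise DataModelError(f"species not in tree: {sorted(missing)}")
        if len(species) == 1:
            leaf = self.tree.find_node_with_taxon_label(species[0])
            return self.ages[leaf]
        mrca = self.tree.mrca(taxon_labels=species)
        return self.ages[mrca]

    def branches(self):
        """All edges of the rooted tree as (parent, child) node pairs."""
        return [
            (nd.parent_node, nd)
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
        ]

    def branch_labels(self) -> list[str]:
        """Branches addressed by child-node label (taxon label for leaves)."""
        out = []
        for _, child in self.branches():
            out.append(child.taxon.label if child.is_leaf() else child.label)
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class OrthologyTable:
    """OG x species copy-count matrix plus gene-level membership."""

    counts: pd.DataFrame  # index: og_id, columns: species, dtype int
    members: dict  # og_id -> list of (gene_id, species)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DataModelError("negative copy counts")
        for og, mem in self.members.items():
            if og not in self.counts.index:
                raise DataModelError(f"members listed for unknown OG {og!r}")
            if not mem:
                raise DataModelError(f"OG {og!r} has no member genes")
            tally: dict[str, int] = {}
            for _, sp in mem:
                tally[sp] = tally.get(sp, 0) + 1
            for sp in self.counts.columns:
                if int(self.counts.at[og, sp]) != tally.get(sp, 0):
                    raise DataModelError(
                        f"counts/members mismatch for OG {og!r}, species {sp!r}"
                    )

    @property
    def og_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def species_present(self, og: str) -> list[str]:
        row = self.counts.loc[og]
        return list(row.index[row > 0])

    def gene_to_og(self) -> dict:
        out = {}
        for og, mem in self.members.items():
            for gene, _sp in mem:
                out[gene] = og
        return out

    def genes_of(self, og: str, species: str | None = None) -> list[str]:
        return [g for g, sp in self.members[og] if species is None or sp == species]


@dataclass
class GeneCatalog:
    """Mapping of genes to immune gene families (per species)."""

    assignments: dict  # gene_id -> (family, species)
    family_vocabulary: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.family_vocabulary:
            bad = {f for f, _ in self.assignments.values()} - set(self.family_vocabulary)
            if bad:
                raise DataModelError(f"unknown family acronyms: {sorted(bad)}")

    @property
    def families(self) -> list[str]:
        return sorted({f for f, _ in self.assignments.values()})

    def genes_of_family(self, family: str, species: str | None = None) -> list[str]:
        return sorted(
            g
            for g, (f, sp) in self.assignments.items()
            if f == family and (species is None or sp == species)
        )

    def family_of(self, gene: str) -> str | None:
        hit = self.assignments.get(gene)
        return hit[0] if hit else None


@dataclass
class GenomeGeneOrder:
    """Per-species scaffold-ordered gene lists (ascending start coordinate)."""

    orders: dict  # species -> scaffold -> [gene_id, ...]

    def __post_init__(self) -> None:
        for sp, scafs in self.orders.items():
            seen: set[str] = set()
            for genes in scafs.values():
                for g in genes:
                    if g in seen:
                        raise DataModelError(
                            f"gene {g!r} appears more than once in species {sp!r}"
                        )
                    seen.add(g)

    def locate(self, species: str, gene: str):
        """Return (scaffold, index) or None."""
        for scaf, genes in self.orders.get(species, {}).items():
            try:
                return scaf, genes.index(gene)
            except ValueError:
                continue
        return None

    def neighbors(self, species: str, gene: str, window: int = 1) -> list[str]:
        loc = self.locate(species, gene)
        if loc is None:
            return []
        scaf, i = loc
        genes = self.orders[species][scaf]
        left = genes[max(0, i - window): i]
        right = genes[i + 1: i + 1 + window]
        return left + right


@dataclass
class CodonAlignmentSet:
    """Per-OG codon-aware nucleotide alignments."""

    alignments: dict  # og_id -> list of (seq_id, sequence)

    _ALPHABET = set("ACGTN-")

    def __post_init__(self) -> None:
        for og, seqs in self.alignments.items():
            if not seqs:
                raise DataModelError(f"empty alignment for OG {og!r}")
            lengths = {len(s) for _, s in seqs}
            if len(lengths) != 1:
                raise DataModelError(f"unequal sequence lengths in OG {og!r}")
            (length,) = lengths
            if length % 3 != 0:
                raise DataModelError(f"alignment length not divisible by 3 in OG {og!r}")
            for sid, s in seqs:
                extra = set(s.upper()) - self._ALPHABET
                if extra:
                    raise DataModelError(
                        f"illegal characters {sorted(extra)} in {sid!r} (OG {og!r})"
                    )


@dataclass
class SnpAnnotationTable:
    """Per-gene synonymous/nonsynonymous coding SNP counts and CDS length."""

    table: pd.DataFrame  # index gene_id; columns n_syn, n_nonsyn, cds_length

    def __post_init__(self) -> None:
        t = self.table
        for col in ("n_syn", "n_nonsyn", "cds_length"):
            if col not in t.columns:
                raise DataModelError(f"SNP table missing column {col!r}")
        if (t[["n_syn", "n_nonsyn"]].values < 0).any():
            raise DataModelError("negative SNP counts")
        if (t["cds_length"] <= 0).any():
            raise DataModelError("non-positive CDS length")
        if (t["cds_length"] % 3 != 0).any():
            raise DataModelError("CDS length not divisible by 3")


@dataclass
class NucleotideTrack:
    """Sparse per-nucleotide track: sorted non-overlapping half-open intervals.

    positions are 0-based; uncovered positions take ``default`` (bedGraph
    sparsity convention).
    """

    intervals: dict  # scaffold -> (starts, ends, values) numpy arrays
    default: float = 0.0
    value_range: tuple = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        for scaf, (starts, ends, values) in self.intervals.items():
            starts = np.asarray(starts)
            ends = np.asarray(ends)
            values = np.asarray(values, dtype=float)
            if (ends <= starts).any():
                raise DataModelError(f"empty/inverted interval on {scaf!r}")
            if (starts[1:] < ends[:-1]).any():
                raise DataModelError(f"overlapping/unsorted intervals on {scaf!r}")
            if ((values < lo) | (values > hi)).any():
                raise DataModelError(f"track values out of range on {scaf!r}")
            self.intervals[scaf] = (starts, ends, values)

    def mean_over(self, scaffold: str, spans) -> float:
        """Length-weighted mean over 0-based half-open spans."""
        total_len = sum(e - s for s, e in spans)
        if total_len <= 0:
            raise DataModelError("zero-length span set")
        starts, ends, values = self.intervals.get(
            scaffold, (np.array([]), np.array([]), np.array([]))
        )
        acc = 0.0
        for s, e in spans:
            covered = 0
            if len(starts):
                i0 = np.searchsorted(ends, s, side="right")
                for i in range(i0, len(starts)):
                    if starts[i] >= e:
                        break
                    ov = min(e, ends[i]) - max(s, starts[i])
                    if ov > 0:
                        acc += ov * values[i]
                        covered += ov
            acc += (e - s - covered) * self.default
        return acc / total_len


@dataclass
class GeneModel:
    """Gene CDS structure in GFF3 convention (1-based inclusive intervals)."""

    gene_id: str
    scaffold: str
    strand: str
    cds_intervals: Sequence  # [(start, end), ...] 1-based inclusive, sorted

    def __post_init__(self) -> None:
        iv = sorted(tuple(x) for x in self.cds_intervals)
        if not iv:
            raise DataModelError(f"gene {self.gene_id!r} has no CDS intervals")
        for s, e in iv:
            if e < s:
                raise DataModelError(f"inverted CDS interval in {self.gene_id!r}")
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 <= e1:
                raise DataModelError(f"overlapping CDS intervals in {self.gene_id!r}")
        self.cds_intervals = iv

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    def cds_spans_0based(self):
        """CDS intervals converted to 0-based half-open spans."""
        return [(s - 1, e) for s, e in self.cds_intervals]


@dataclass
class ExpressionMap:
    """Clustered expression map: grid of cells with gene->cell assignments."""

    grid_rows: int
    grid_cols: int
    cell_of: dict  # gene_id -> (row, col)
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise DataModelError("grid dimensions must be positive")
        for g, (r, c) in self.cell_of.items():
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise DataModelError(f"gene {g!r} mapped outside grid: {(r, c)}")

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    def cell_index(self, cell) -> int:
        r, c = cell
        return r * self.grid_cols + c


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of log2 expression means."""

    values: pd.DataFrame  # index gene_id, columns condition ids

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def new_og_metric_table(og_ids: Iterable[str]) -> pd.DataFrame:
    """Empty per-OG metric table with canonical column order (NaN = missing)."""
    return pd.DataFrame(np.nan, index=list(og_ids), columns=METRIC_ORDER)


def validate_og_metric_table(table: pd.DataFrame, n_species: int | None = None) -> None:
    """Check the documented range invariants; NaN entries are skipped."""

    def _check(col: str, lo: float, hi: float) -> None:
        if col not in table.columns:
            return
        vals = table[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise DataModelError(f"{col} outside [{lo}, {hi}]")

    _check("UNI", np.nextafter(0.0, 1.0), 1.0)
    _check("DUP", 0.0, 1.0)
    _check("SYN", 0.0, 1.0)
    _check("NSP", 0.0, 1.0)
    _check("PHC", 0.0, 1.0)
    _check("STA", 0.0, 1.0)
    _check("EXP", 0.0, 1.0)
    _check("CON", 0.0, 1.0)
    for col in ("ACN",):
        vals = table[col].dropna()
        if (vals < 1).any():
            raise DataModelError("ACN below 1")
    for col in ("CNV", "PDS", "PDN", "NSD", "SSD", "EVR", "AGE"):
        if col in table.columns and (table[col].dropna() < 0).any():
            raise DataModelError(f"{col} negative")
    if n_species is not None and "WGA" in table.columns:
        vals = table["WGA"].dropna()
        if ((vals < 0) | (vals > n_species)).any():
            raise DataModelError("WGA outside [0, n_species]")
    trio = table[["EXP", "CON", "STA"]].dropna()
    if len(trio):
        s = trio.sum(axis=1)
        if (np.abs(s - 1.0) > 1e-9).any():
            raise DataModelError("EXP+CON+STA != 1")
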