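"""Family expression similarity on a clustered expression map.

Families are reduced to their sets of occupied map units (cells, 3x3
toroidal supercells, or coexpression modules); pairwise similarity is the
Jaccard overlap of those sets, with significance from permutations of the
gene-to-cell assignment that preserve every cell size and family size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import DataModelError, ExpressionMap, ExpressionMatrix, GeneCatalog

RESOLUTIONS = ("cell", "supercell", "module")


# ---------------------------------------------------------------------------
# occupied unit sets


def _supercell_block(cell, rows, cols, toroidal):
    r, c = cell
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if toroidal:
                yield rr % rows, cc % cols
            elif 0 <= rr < rows and 0 <= cc < cols:
                yield rr, cc


def occupied_cells(emap: ExpressionMap, genes) -> set:
    cells = set()
    for g in genes:
        if g in emap.cell_of:
            cells.add(emap.cell_of[g])
    return cells


def occupied_supercells(emap: ExpressionMap, genes) -> set:
    """Supercell centers whose 3x3 block contains >= 1 member gene
    (the 3x3 dilation of the occupied cell set)."""
    out = set()
    for cell in occupied_cells(emap, genes):
        out.update(
            _supercell_block(cell, emap.grid_rows, emap.grid_cols, emap.toroidal)
        )
    return out


def family_cell_sets(
    emap: ExpressionMap, catalog: GeneCatalog, resolution: str = "cell"
) -> dict:
    """family -> set of occupied units at the requested resolution."""
    if resolution not in ("cell", "supercell"):
        raise ValueError(f"unknown resolution {resolution!r}")
    out = {}
    for fam in catalog.families:
        genes = catalog.genes_of_family(fam)
        units = (
            occupied_cells(emap, genes)
            if resolution == "cell"
            else occupied_supercells(emap, genes)
        )
        if units:
            out[fam] = units
    return out


def cooccurrence_score(set_a: set, set_b: set) -> float:
    """Jaccard overlap |A n B| / |A u B|; NaN when either set is empty."""
    if not set_a or not set_b:
        return np.nan
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return inter / union


# ---------------------------------------------------------------------------
# permutation machinery


def _dilate_occupancy(occ: np.ndarray, rows: int, cols: int, toroidal: bool) -> np.ndarray:
    """3x3 dilation of (n, rows*cols) boolean occupancy matrices."""
    grid = occ.reshape(occ.shape[0], rows, cols)
    out = np.zeros_like(grid)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if toroidal:
                out |= np.roll(np.roll(grid, dr, axis=1), dc, axis=2)
            else:
                shifted = np.zeros_like(grid)
                rs = slice(max(dr, 0), rows + min(dr, 0))
                rsrc = slice(max(-dr, 0), rows + min(-dr, 0))
                cs = slice(max(dc, 0), cols + min(dc, 0))
                csrc = slice(max(-dc, 0), cols + min(-dc, 0))
                shifted[:, rs, cs] = grid[:, rsrc, csrc]
                out |= shifted
    return out.reshape(occ.shape)


def _jaccard_rows(occ_a: np.ndarray, occ_b: np.ndarray) -> np.ndarray:
    inter = (occ_a & occ_b).sum(axis=1)
    union = (occ_a | occ_b).sum(axis=1)
    union = np.where(union == 0, 1, union)
    return inter / union


@dataclass
class _MapArrays:
    genes: list
    assignment: np.ndarray  # flat cell index per gene
    n_units: int
    rows: int
    cols: int
    toroidal: bool


def _map_arrays(emap: ExpressionMap) -> _MapArrays:
    genes = sorted(emap.cell_of)
    assignment = np.array([emap.cell_index(emap.cell_of[g]) for g in genes])
    return _MapArrays(
        genes=genes,
        assignment=assignment,
        n_units=emap.n_cells,
        rows=emap.grid_rows,
        cols=emap.grid_cols,
        toroidal=emap.toroidal,
    )


def _occupancy(assignments: np.ndarray, member_idx: np.ndarray, n_units: int) -> np.ndarray:
    """(n_perm, n_units) boolean occupancy from (n_perm, n_genes) assignments."""
    n_perm = assignments.shape[0]
    occ = np.zeros((n_perm, n_units), dtype=bool)
    cells = assignments[:, member_idx]
    rows = np.repeat(np.arange(n_perm), len(member_idx))
    occ[rows, cells.ravel()] = True
    return occ


def _permuted_scores(
    arrays: _MapArrays,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    resolution: str,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Co-occurrence scores for n_perm shuffles of the gene->cell assignment.

    Shuffling permutes the assignment vector over genes, which preserves the
    multiset of cell sizes exactly; family memberships are untouched.
    """
    perms = rng.permuted(
        np.broadcast_to(arrays.assignment, (n_perm, arrays.assignment.size)).copy(),
        axis=1,
    )
    occ_a = _occupancy(perms, idx_a, arrays.n_units)
    occ_b = _occupancy(perms, idx_b, arrays.n_units)
    if resolution == "supercell":
        occ_a = _dilate_occupancy(occ_a, arrays.rows, arrays.cols, arrays.toroidal)
        occ_b = _dilate_occupancy(occ_b, arrays.rows, arrays.cols, arrays.toroidal)
    return _jaccard_rows(occ_a, occ_b)


def cooccurrence_permutation_test(
    emap: ExpressionMap,
    catalog: GeneCatalog,
    pair: tuple,
    resolution: str = "cell",
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    greater_equal: bool = False,
    plus_one: bool = False,
) -> tuple:
    """(observed score, p-value) for one family pair.

    p = #(permutation score > observed) / n_perm (strict inequality);
    ``greater_equal`` and ``plus_one`` select the >= and (b+1)/(m+1)
    variants.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fam_a, fam_b = pair
    arrays = _map_arrays(emap)
    gene_pos = {g: i for i, g in enumerate(arrays.genes)}
    idx_a = np.array(
        [gene_pos[g] for g in catalog.genes_of_family(fam_a) if g in gene_pos]
    )
    idx_b = np.array(
        [gene_pos[g] for g in catalog.genes_of_family(fam_b) if g in gene_pos]
    )
    if idx_a.size == 0 or idx_b.size == 0:
        return np.nan, np.nan
    obs_assign = arrays.assignment[None, :]
    occ_a = _occupancy(obs_assign, idx_a, arrays.n_units)
    occ_b = _occupancy(obs_assign, idx_b, arrays.n_units)
    if resolution == "supercell":
        occ_a = _dilate_occupancy(occ_a, arrays.rows, arrays.cols, arrays.toroidal)
        occ_b = _dilate_occupancy(occ_b, arrays.rows, arrays.cols, arrays.toroidal)
    observed = float(_jaccard_rows(occ_a, occ_b)[0])
    scores = _permuted_scores(arrays, idx_a, idx_b, resolution, n_perm, rng)
    if greater_equal:
        b = int((scores >= observed).sum())
    else:
        b = int((scores > observed).sum())
    p = (b + 1) / (n_perm + 1) if plus_one else b / n_perm
    return observed, p


def cooccurrence_table(
    emap: ExpressionMap,
    catalog: GeneCatalog,
    resolution: str = "cell",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Scores and p-values for all unordered family pairs with mapped genes."""
    rng = np.random.default_rng(seed)
    fams = [
        f
        for f in catalog.families
        if any(g in emap.cell_of for g in catalog.genes_of_family(f))
    ]
    rows = []
    for i, fa in enumerate(fams):
        for fb in fams[i + 1:]:
            score, p = cooccurrence_permutation_test(
                emap, catalog, (fa, fb), resolution=resolution,
                n_perm=n_perm, rng=rng,
            )
            rows.append(
                {
                    "family1": fa, "family2": fb, "score": score,
                    "p_value": p, "resolution": resolution,
                    "n_perm": n_perm, "seed": seed,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# module-based variant


def module_cooccurrence(
    partition: dict,
    catalog: GeneCatalog,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cell-style co-occurrence with coexpression modules as the units."""
    modules = sorted(set(partition.values()))
    mod_index = {m: i for i, m in enumerate(modules)}
    # reuse the map machinery with a 1 x n_modules non-toroidal grid
    emap = ExpressionMap(
        grid_rows=1,
        grid_cols=len(modules),
        cell_of={g: (0, mod_index[m]) for g, m in partition.items()},
        toroidal=False,
    )
    table = cooccurrence_table(
        emap, catalog, resolution="cell", n_perm=n_perm, seed=seed
    )
    table["resolution"] = "module"
    return table


def expression_partition_from_matrix(
    expr: ExpressionMatrix,
    conditions=None,
    n_modules: int | None = None,
    cut_height: float | None = None,
) -> dict:
    """Lightweight coexpression module partition (correlation clustering).

    Genes are clustered by Pearson correlation distance with average linkage
    over the selected condition subset and the tree cut at ``n_modules`` or
    ``cut_height``. Constant-expression genes get singleton "unclustered"
    modules.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    values = expr.values
    if conditions is not None:
        values = values[list(conditions)]
    if values.shape[1] < 2:
        raise DataModelError("need >= 2 conditions to build modules")
    if n_modules is None and cut_height is None:
        n_modules = 2
    X = values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    variable = sd > 0
    genes = list(values.index)
    partition: dict = {}
    unclustered = [g for g, v in zip(genes, variable) if not v]
    for i, g in enumerate(unclustered):
        partition[g] = f"unclustered_{i+1}"
    var_genes = [g for g, v in zip(genes, variable) if v]
    if len(var_genes) >= 2:
        Xv = X[variable]
        corr = np.corrcoef(Xv)
        D = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        if n_modules is not None:
            labels = hierarchy.fcluster(Z, t=n_modules, criterion="maxclust")
        else:
            labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        for g, lb in zip(var_genes, labels):
            partition[g] = f"module_{lb}"
    elif len(var_genes) == 1:
        partition[var_genes[0]] = "module_1"
    return partition


# ---------------------------------------------------------------------------
# evolutionary vs expression comparison, graph export


def evo_expr_pairing(
    evo_similarity: pd.DataFrame, expr_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One row per unordered family pair present in both inputs."""
    rows = []
    evo_fams = set(evo_similarity.index)
    for rec in expr_table.itertuples(index=False):
        if rec.family1 in evo_fams and rec.family2 in evo_fams:
            rows.append(
                {
                    "family1": rec.family1,
                    "family2": rec.family2,
                    "evo_score": float(evo_similarity.at[rec.family1, rec.family2]),
                    "expr_score": rec.score,
                    "expr_p": rec.p_value,
                    "resolution": rec.resolution,
                    "significant": bool(rec.p_value < alpha)
                    if not np.isnan(rec.p_value)
                    else False,
                }
            )
    return pd.DataFrame(rows)


def export_similarity_graph(
    table: pd.DataFrame,
    path,
    thresholds=(0.05, 0.01, 0.005),
    fmt: str = "dot",
    all_families=None,
) -> None:
    """Write family similarity edges below each p threshold to DOT/GraphML."""
    import networkx as nx

    thresholds = sorted(thresholds)
    G = nx.Graph()
    fams = set(all_families) if all_families is not None else (
        set(table["family1"]) | set(table["family2"])
    )
    G.add_nodes_from(sorted(fams))
    for rec in table.itertuples(index=False):
        p = rec.p_value
        if np.isnan(p) or p >= max(thresholds):
            continue
        cls = min(t for t in thresholds if p < t)
        G.add_edge(
            rec.family1, rec.family2,
            p_value=float(p), score=float(rec.score), threshold=f"p<{cls:g}",
        )
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph similarity {\n")
            for node in sorted(G.nodes):
                fh.write(f'  "{node}";\n')
            for a, b, data in sorted(G.edges(data=True)):
                fh.write(
                    f'  "{a}" -- "{b}" [label="{data["threshold"]}",'
                    f' p={data["p_value"]:.6g}, score={data["score"]:.4g}];\n'
                )
            fh.write("}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
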