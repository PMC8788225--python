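"""Hierarchical clustering of family profiles with bootstrap support.

Covers column z-scaling, four row dissimilarities (three correlation-based
plus Euclidean) crossed with four agglomeration methods, multiscale-bootstrap
AU/BP clade support, the Dice-normalized family subtree co-occurrence score
aggregated over all replicate dendrograms of all combinations, and PCA.

The agglomerative clustering is implemented directly (Lance-Williams
updates) so that merge tie-breaking is deterministic by lexicographically
smallest member label and clade sets are cheap to extract from every
bootstrap replicate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DISTANCES = ("pearson", "spearman", "kendall", "euclidean")
LINKAGES = ("single", "complete", "average", "median")
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


# ---------------------------------------------------------------------------
# scaling and distances


def scale_matrix(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-scale each metric column: (x - mean) / sample sd.

    Constant columns become all zeros with a warning.
    """
    scaled = profiles.copy().astype(float)
    for col in profiles.columns:
        x = profiles[col].astype(float)
        sd = x.std(ddof=ddof)
        if pd.isna(sd) or sd == 0:
            warnings.warn(f"metric column {col!r} is constant; scaled to zeros",
                          stacklevel=2)
            scaled[col] = np.where(x.notna(), 0.0, np.nan)
        else:
            scaled[col] = (x - x.mean()) / sd
    return scaled


def _pairwise_correlation_distance(a: np.ndarray, b: np.ndarray, method: str) -> float:
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 3:
        raise ValueError("row with < 3 jointly defined metrics")
    x, y = a[mask], b[mask]
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "kendall":
        r = stats.kendalltau(x, y).statistic
    else:  # pragma: no cover
        raise ValueError(method)
    if np.isnan(r):  # constant row after masking
        r = 0.0
    return 1.0 - float(r)


def distance_matrix(scaled: pd.DataFrame, method: str) -> pd.DataFrame:
    """Symmetric row dissimilarity matrix with zero diagonal."""
    if method not in DISTANCES:
        raise ValueError(f"unknown distance method {method!r}")
    labels = list(scaled.index)
    X = scaled.to_numpy(dtype=float)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if method == "euclidean":
                mask = ~(np.isnan(X[i]) | np.isnan(X[j]))
                d = float(np.sqrt(np.sum((X[i, mask] - X[j, mask]) ** 2)))
            else:
                d = _pairwise_correlation_distance(X[i], X[j], method)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# agglomerative clustering


@dataclass
class ClusterNode:
    leaves: frozenset
    height: float = 0.0
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    root: ClusterNode
    labels: list
    has_inversions: bool = False
    node_support: dict = field(default_factory=dict)  # clade -> {"bp":, "au":}

    def clades(self, include_root: bool = False) -> list:
        """Non-singleton clades (frozensets of labels), root excluded by default."""
        out = []

        def walk(node):
            if node.is_leaf:
                return
            if include_root or node is not self.root:
                out.append(node.leaves)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def parent_clades(self) -> dict:
        """leaf label -> leaf set of its minimal non-singleton clade."""
        out = {}

        def walk(node):
            for ch in node.children:
                if ch.is_leaf:
                    (leaf,) = ch.leaves
                    out[leaf] = node.leaves
                else:
                    walk(ch)

        walk(self.root)
        return out

    def newick(self, support: dict | None = None) -> str:
        def fmt(node):
            if node.is_leaf:
                (leaf,) = node.leaves
                return str(leaf)
            inner = ",".join(fmt(ch) for ch in sorted(
                node.children, key=lambda c: min(map(str, c.leaves))))
            comment = ""
            if support and node.leaves in support:
                vals = support[node.leaves]
                comment = "[&au={au:.3f},bp={bp:.3f}]".format(**vals)
            return f"({inner}){comment}:{node.height:.6g}"

        return fmt(self.root) + ";"


def hcluster(dist: pd.DataFrame, linkage: str) -> Dendrogram:
    """Agglomerative merge tree with deterministic tie-breaking.

    Median linkage applies the Lance-Williams update on squared distances;
    resulting height inversions are permitted and flagged.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    labels = list(dist.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    D = {  # working distances between active clusters
        frozenset((i, j)): float(dist.iat[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = {i: ClusterNode(leaves=frozenset([labels[i]])) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    sort_key = {i: (min(map(str, active[i].leaves)),) for i in range(n)}
    next_id = n
    inversions = False
    last_height = 0.0

    while len(active) > 1:
        # deterministic choice: min distance, then lexicographic pair key
        best = min(
            D.items(),
            key=lambda kv: (kv[1], tuple(sorted(sort_key[i] for i in kv[0]))),
        )
        pair, h = best
        i, j = sorted(pair, key=lambda x: sort_key[x])
        if h < last_height - 1e-12:
            inversions = True
        last_height = max(last_height, h)
        node = ClusterNode(
            leaves=active[i].leaves | active[j].leaves,
            height=h,
            children=(active[i], active[j]),
        )
        dij = D.pop(pair)
        ni, nj = sizes[i], sizes[j]
        new_d = {}
        for k in active:
            if k in (i, j):
                continue
            dik = D.pop(frozenset((i, k)))
            djk = D.pop(frozenset((j, k)))
            if linkage == "single":
                d = min(dik, djk)
            elif linkage == "complete":
                d = max(dik, djk)
            elif linkage == "average":
                d = (ni * dik + nj * djk) / (ni + nj)
            else:  # median, on squared distances
                d = np.sqrt(
                    max(0.0, 0.5 * dik**2 + 0.5 * djk**2 - 0.25 * dij**2)
                )
            new_d[k] = d
        del active[i], active[j], sizes[i], sizes[j], sort_key[i], sort_key[j]
        active[next_id] = node
        sizes[next_id] = len(node.leaves)
        sort_key[next_id] = (min(map(str, node.leaves)),)
        for k, d in new_d.items():
            D[frozenset((next_id, k))] = d
        next_id += 1

    (root,) = active.values()
    return Dendrogram(root=root, labels=labels, has_inversions=inversions)


# ---------------------------------------------------------------------------
# multiscale bootstrap


@dataclass
class BootstrapResult:
    distance: str
    linkage: str
    observed: Dendrogram
    bp: dict  # clade -> BP at scale 1
    au: dict  # clade -> AU value
    au_flag: dict  # clade -> "" | "clamped0" | "clamped1"
    scales: tuple
    n_per_scale: int
    replicate_parent_clades: list  # one dict per replicate (all scales)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_parent_clades)


def _fit_au(bp_by_scale: dict, n_per_scale: int) -> tuple:
    """pvclust-style two-parameter probit fit; returns (au, flag)."""
    scales = np.array(sorted(bp_by_scale))
    bps = np.array([bp_by_scale[r] for r in scales], dtype=float)
    if np.all(bps >= 1.0):
        return 1.0, "clamped1"
    if np.all(bps <= 0.0):
        return 0.0, "clamped0"
    eps = 1.0 / (2.0 * n_per_scale)
    bps = np.clip(bps, eps, 1.0 - eps)
    z = stats.norm.ppf(1.0 - bps)  # signed distance at each scale
    w = n_per_scale * stats.norm.pdf(z) ** 2 / (bps * (1.0 - bps))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    W = np.diag(w)
    beta, *_ = np.linalg.lstsq(
        np.sqrt(W) @ X, np.sqrt(w) * z, rcond=None
    )
    v, c = beta
    return float(1.0 - stats.norm.cdf(v - c)), ""


def multiscale_bootstrap(
    scaled_profiles: pd.DataFrame,
    distance: str,
    linkage: str,
    scales=DEFAULT_SCALES,
    n_per_scale: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    keep_replicates: bool = True,
) -> BootstrapResult:
    """Resample metric columns at multiple scales and score clade support.

    For each scale r, round(r * n_metrics) columns are drawn with
    replacement, the families re-clustered, and each observed clade's
    presence recorded. AU values come from the weighted probit fit of BP(r);
    BP is reported at r = 1 (the scale closest to 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = hcluster(distance_matrix(scaled_profiles, distance), linkage)
    clades = observed.clades()
    n_metrics = scaled_profiles.shape[1]
    presence = {cl: {} for cl in clades}
    replicate_parents = []
    for r in scales:
        m = max(2, int(round(r * n_metrics)))
        counts = {cl: 0 for cl in clades}
        for _ in range(n_per_scale):
            cols = rng.integers(0, n_metrics, size=m)
            boot = scaled_profiles.iloc[:, cols]
            boot.columns = range(m)
            tree = hcluster(distance_matrix(boot, distance), linkage)
            rep_clades = set(tree.clades())
            for cl in clades:
                if cl in rep_clades:
                    counts[cl] += 1
            if keep_replicates:
                replicate_parents.append(tree.parent_clades())
        for cl in clades:
            presence[cl][float(r)] = counts[cl] / n_per_scale

    bp, au, au_flag = {}, {}, {}
    r1 = min(scales, key=lambda r: abs(r - 1.0))
    for cl in clades:
        bp[cl] = presence[cl][float(r1)]
        au[cl], au_flag[cl] = _fit_au(presence[cl], n_per_scale)
    observed.node_support = {
        cl: {"bp": bp[cl], "au": au[cl]} for cl in clades
    }
    return BootstrapResult(
        distance=distance,
        linkage=linkage,
        observed=observed,
        bp=bp,
        au=au,
        au_flag=au_flag,
        scales=tuple(scales),
        n_per_scale=n_per_scale,
        replicate_parent_clades=replicate_parents,
    )


def run_all_combinations(
    scaled_profiles: pd.DataFrame,
    distances=DISTANCES,
    linkages=LINKAGES,
    scales=DEFAULT_SCALES,
    n_per_scale: int = 1000,
    seed: int | None = None,
) -> dict:
    """BootstrapResult per (distance, linkage) combination."""
    rng = np.random.default_rng(seed)
    results = {}
    for dmethod in distances:
        for lmethod in linkages:
            results[(dmethod, lmethod)] = multiscale_bootstrap(
                scaled_profiles, dmethod, lmethod,
                scales=scales, n_per_scale=n_per_scale, rng=rng,
            )
    return results


def total_replicates(results: dict) -> int:
    """Aggregate bootstrap replicate count over all combinations."""
    return sum(res.n_replicates for res in results.values())


# ---------------------------------------------------------------------------
# family subtree co-occurrence


def subtree_cooccurrence(replicate_parent_clades: list, families) -> pd.DataFrame:
    """Dice-normalized co-occurrence of family pairs in minimal subtrees.

    Two families co-occur in a replicate when one belongs to the other's
    minimal non-singleton clade. Score = 2*C12 / (C1_any + C2_any); diagonal
    is 1.
    """
    if not replicate_parent_clades:
        raise ValueError("zero replicate dendrograms")
    families = list(families)
    idx = {f: i for i, f in enumerate(families)}
    n = len(families)
    C = np.zeros((n, n))
    for parents in replicate_parent_clades:
        pairs = set()
        for f, clade in parents.items():
            for g in clade:
                if g != f:
                    pairs.add(frozenset((f, g)))
        for pair in pairs:
            a, b = tuple(pair)
            C[idx[a], idx[b]] += 1
            C[idx[b], idx[a]] += 1
    any_count = C.sum(axis=1)
    S = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            denom = any_count[i] + any_count[j]
            S[i, j] = 2.0 * C[i, j] / denom if denom > 0 else 0.0
    return pd.DataFrame(S, index=families, columns=families)


# ---------------------------------------------------------------------------
# PCA


def pca_profiles(profiles: pd.DataFrame, center: bool = True, scale: bool = False):
    """prcomp-style PCA of a family x metric table.

    Returns (loadings, scores, variance_fraction): loadings are metric x PC
    orthonormal columns; variance fractions sum to 1.
    """
    X = profiles.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{i+1}" for i in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=profiles.columns, columns=pcs)
    scores = pd.DataFrame(U * s, index=profiles.index, columns=pcs)
    return loadings, scores, pd.Series(var_frac, index=pcs)
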