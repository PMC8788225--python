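"""Family-level metric aggregation, delta profiles, and significance tests.

Each family's per-OG metric values are contrasted against all other
immune-family OGs: delta = family aggregate minus the aggregate over the
rest; significance is assessed with a two-sided rank-sum test and a
size-matched permutation test, and the smaller p-value is starred.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import GeneCatalog, OrthologyTable

STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def star_label(p: float) -> str:
    if np.isnan(p):
        return ""
    for thr, stars in STAR_THRESHOLDS:
        if p <= thr:
            return stars
    return ""


def family_og_sets(catalog: GeneCatalog, orthology: OrthologyTable) -> dict:
    """family -> set of OG ids containing >= 1 cataloged gene of that family.

    OGs shared by two families appear in both sets.
    """
    gene_to_og = orthology.gene_to_og()
    sets: dict = {f: set() for f in catalog.families}
    for gene, (family, _sp) in catalog.assignments.items():
        og = gene_to_og.get(gene)
        if og is not None:
            sets[family].add(og)
    return {f: s for f, s in sets.items() if s}


def _aggregate(values: np.ndarray, stat: str) -> float:
    if values.size == 0:
        return np.nan
    return float(np.median(values)) if stat == "median" else float(np.mean(values))


def family_metric_matrix(
    og_metrics: pd.DataFrame, og_sets: dict, stat: str = "mean"
) -> pd.DataFrame:
    """Family x metric table of per-family aggregates over member OGs."""
    rows = {}
    for fam, ogs in sorted(og_sets.items()):
        sub = og_metrics.loc[og_metrics.index.intersection(list(ogs))]
        rows[fam] = {
            m: _aggregate(sub[m].dropna().to_numpy(), stat) for m in og_metrics.columns
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(og_metrics.columns)]


def family_delta(
    og_metrics: pd.DataFrame, og_sets: dict, stat: str = "mean"
) -> pd.DataFrame:
    """Family x metric table of deltas vs all other immune-family OGs.

    The OG universe is the union of all family OG sets; an OG shared between
    families counts in both family sets and in each other's complement.
    """
    universe = sorted(set().union(*og_sets.values()))
    metrics = og_metrics.reindex(universe)
    rows = {}
    for fam, ogs in sorted(og_sets.items()):
        others = [og for og in universe if og not in ogs]
        rec = {}
        for m in og_metrics.columns:
            fam_vals = metrics.loc[metrics.index.isin(list(ogs)), m].dropna().to_numpy()
            oth_vals = metrics.loc[metrics.index.isin(others), m].dropna().to_numpy()
            if fam_vals.size == 0 or oth_vals.size == 0:
                rec[m] = np.nan
            else:
                rec[m] = _aggregate(fam_vals, stat) - _aggregate(oth_vals, stat)
        rows[fam] = rec
    return pd.DataFrame.from_dict(rows, orient="index")[list(og_metrics.columns)]


def scale_deltas(deltas: pd.DataFrame) -> pd.DataFrame:
    """Scale each metric column by its absolute-maximum delta (range [-1, 1]).

    All-zero (or all-missing) columns scale to zeros.
    """
    scaled = deltas.copy()
    for m in deltas.columns:
        col = deltas[m]
        amax = col.abs().max(skipna=True)
        if pd.isna(amax) or amax == 0:
            scaled[m] = col.where(col.isna(), 0.0)
        else:
            scaled[m] = col / amax
    return scaled


def permutation_pvalue(
    fam_vals: np.ndarray,
    other_vals: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    stat: str = "mean",
    two_sided: bool = True,
    plus_one: bool = False,
) -> float:
    """Size-matched permutation p-value for the family-vs-rest delta.

    Permutation sets of the family's size are drawn without replacement from
    the pooled values. Two-sided (default) compares |delta|; one-sided uses
    the raw "greater than observed" rule. ``plus_one`` applies the
    (b+1)/(m+1) correction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    k = fam_vals.size
    pooled = np.concatenate([fam_vals, other_vals])
    n = pooled.size
    obs = _aggregate(fam_vals, stat) - _aggregate(other_vals, stat)

    if stat == "mean":
        idx = rng.permuted(
            np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
        )[:, :k]
        sel_sum = pooled[idx].sum(axis=1)
        total = pooled.sum()
        deltas = sel_sum / k - (total - sel_sum) / (n - k)
    else:
        deltas = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            sel = pooled[perm[:k]]
            rest = pooled[perm[k:]]
            deltas[i] = _aggregate(sel, stat) - _aggregate(rest, stat)

    if two_sided:
        b = int((np.abs(deltas) >= abs(obs)).sum())
    else:
        b = int((deltas > obs).sum())
    if plus_one:
        return (b + 1) / (n_perm + 1)
    return b / n_perm


def family_significance(
    og_metrics: pd.DataFrame,
    og_sets: dict,
    family: str,
    metric: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    stat: str = "mean",
    two_sided: bool = True,
) -> tuple:
    """(p_wilcoxon, p_permutation, p_min, stars) for one family and metric."""
    universe = sorted(set().union(*og_sets.values()))
    metrics = og_metrics.reindex(universe)
    ogs = og_sets[family]
    others = [og for og in universe if og not in ogs]
    fam_vals = metrics.loc[metrics.index.isin(list(ogs)), metric].dropna().to_numpy()
    oth_vals = metrics.loc[metrics.index.isin(others), metric].dropna().to_numpy()
    if fam_vals.size == 0 or oth_vals.size == 0:
        return np.nan, np.nan, np.nan, ""
    if fam_vals.size >= 2:
        p_w = float(
            stats.mannwhitneyu(fam_vals, oth_vals, alternative="two-sided").pvalue
        )
    else:
        p_w = np.nan
    p_p = permutation_pvalue(
        fam_vals, oth_vals, n_perm=n_perm, seed=seed, stat=stat, two_sided=two_sided
    )
    p_min = np.nanmin([p_w, p_p])
    return p_w, p_p, float(p_min), star_label(p_min)


def build_family_profiles(
    og_metrics: pd.DataFrame,
    catalog: GeneCatalog,
    orthology: OrthologyTable,
    stat: str = "mean",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy per-(family, metric) profile table.

    Columns: mean, median, delta, scaled_delta, p_wilcoxon, p_permutation,
    p_min, stars. Deltas/p-values use the requested aggregate statistic.
    """
    og_sets = family_og_sets(catalog, orthology)
    deltas = family_delta(og_metrics, og_sets, stat=stat)
    scaled = scale_deltas(deltas)
    means = family_metric_matrix(og_metrics, og_sets, stat="mean")
    medians = family_metric_matrix(og_metrics, og_sets, stat="median")
    rng = np.random.default_rng(seed)
    rows = []
    for fam in sorted(og_sets):
        for m in og_metrics.columns:
            fam_vals = (
                og_metrics.loc[og_metrics.index.isin(list(og_sets[fam])), m]
                .dropna()
                .to_numpy()
            )
            universe = set().union(*og_sets.values())
            others = universe - og_sets[fam]
            oth_vals = (
                og_metrics.loc[og_metrics.index.isin(list(others)), m]
                .dropna()
                .to_numpy()
            )
            if fam_vals.size == 0 or oth_vals.size == 0:
                p_w = p_p = p_min = np.nan
                stars = ""
            else:
                p_w = (
                    float(
                        stats.mannwhitneyu(
                            fam_vals, oth_vals, alternative="two-sided"
                        ).pvalue
                    )
                    if fam_vals.size >= 2
                    else np.nan
                )
                p_p = permutation_pvalue(
                    fam_vals, oth_vals, n_perm=n_perm, rng=rng, stat=stat
                )
                p_min = float(np.nanmin([p_w, p_p]))
                stars = star_label(p_min)
            rows.append(
                {
                    "family": fam,
                    "metric": m,
                    "mean": means.at[fam, m],
                    "median": medians.at[fam, m],
                    "delta": deltas.at[fam, m],
                    "scaled_delta": scaled.at[fam, m],
                    "p_wilcoxon": p_w,
                    "p_permutation": p_p,
                    "p_min": p_min,
                    "stars": stars,
                }
            )
    return pd.DataFrame(rows)
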