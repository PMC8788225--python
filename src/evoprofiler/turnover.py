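"""Per-branch gene gain/loss/stable classification and EXP/CON/STA.

Ancestral copy numbers are reconstructed by a Sankoff dynamic program with
linear cost |i - j| per branch (Wagner parsimony on integer counts), a
desk-scale substitute for birth-death likelihood reconstruction; externally
produced per-branch change reports can be supplied instead.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model_io import OrthologyTable, SpeciesTree


def reconstruct_counts_parsimony(
    leaf_counts: dict, tree: SpeciesTree, max_count: int | None = None
) -> dict:
    """Minimal-|delta|-cost ancestral counts per node.

    ``leaf_counts`` maps species label -> integer count (absent species count
    0). Ties are broken toward the smallest state, both at the root and during
    top-down backtracking, which makes the reconstruction deterministic.
    Returns a mapping from node label (taxon label for leaves) to count.
    """
    counts = {sp: int(leaf_counts.get(sp, 0)) for sp in tree.leaf_labels}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative leaf counts")
    if max_count is None:
        max_count = max(counts.values()) + 2
    if max_count < max(counts.values()):
        raise ValueError("max_count below maximum leaf count")
    n_states = max_count + 1
    states = np.arange(n_states)
    # |i - j| cost matrix between all state pairs
    cost = np.abs(states[:, None] - states[None, :]).astype(float)

    node_cost: dict = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            v = np.full(n_states, np.inf)
            v[counts[nd.taxon.label]] = 0.0
            node_cost[nd] = v
        else:
            v = np.zeros(n_states)
            for ch in nd.child_nodes():
                # min over child state j of cost(i, j) + child_cost(j)
                v += (cost + node_cost[ch][None, :]).min(axis=1)
            node_cost[nd] = v

    assignment: dict = {}
    root = tree.tree.seed_node
    assignment[root] = int(np.argmin(node_cost[root]))  # argmin -> smallest state
    for nd in tree.tree.preorder_node_iter():
        if nd is root:
            continue
        parent_state = assignment[nd.parent_node]
        assignment[nd] = int(np.argmin(cost[parent_state] + node_cost[nd]))

    out = {}
    for nd, st in assignment.items():
        label = nd.taxon.label if nd.is_leaf() else nd.label
        out[label] = st
    return out


def parsimony_cost(leaf_counts: dict, tree: SpeciesTree, max_count: int | None = None) -> int:
    """Total |delta| cost of the minimal reconstruction."""
    rec = reconstruct_counts_parsimony(leaf_counts, tree, max_count)
    total = 0
    for parent, child in tree.branches():
        pl = parent.taxon.label if parent.is_leaf() else parent.label
        cl = child.taxon.label if child.is_leaf() else child.label
        total += abs(rec[pl] - rec[cl])
    return total


def branch_events(
    orthology: OrthologyTable, tree: SpeciesTree, max_count: int | None = None
) -> pd.DataFrame:
    """Per-OG per-branch delta and gain/loss/stable label (tidy frame)."""
    rows = []
    for og in orthology.og_ids:
        leaf_counts = {
            sp: int(orthology.counts.at[og, sp]) for sp in orthology.species
        }
        rec = reconstruct_counts_parsimony(leaf_counts, tree, max_count)
        for parent, child in tree.branches():
            pl = parent.taxon.label if parent.is_leaf() else parent.label
            cl = child.taxon.label if child.is_leaf() else child.label
            delta = rec[cl] - rec[pl]
            label = "gain" if delta > 0 else ("loss" if delta < 0 else "stable")
            rows.append((og, cl, delta, label))
    return pd.DataFrame(rows, columns=["og_id", "branch", "delta", "label"])


def turnover_proportions(
    events: pd.DataFrame, internal_only: bool = False, tree: SpeciesTree | None = None
) -> pd.DataFrame:
    """EXP/CON/STA per OG from a branch-event table.

    EXP + CON + STA = 1 exactly (the labels partition the branches). With
    ``internal_only`` the leaf branches are dropped (requires ``tree``).
    """
    ev = events
    if internal_only:
        if tree is None:
            raise ValueError("internal_only requires the tree")
        leaf_branches = set(tree.leaf_labels)
        ev = ev[~ev["branch"].isin(leaf_branches)]
    rows = {}
    for og, sub in ev.groupby("og_id", sort=True):
        n = len(sub)
        rows[og] = {
            "EXP": (sub["label"] == "gain").sum() / n,
            "CON": (sub["label"] == "loss").sum() / n,
            "STA": (sub["label"] == "stable").sum() / n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["EXP", "CON", "STA"]]


def compute_turnover(
    orthology: OrthologyTable,
    tree: SpeciesTree,
    cafe_events: pd.DataFrame | None = None,
    internal_only: bool = False,
) -> pd.DataFrame:
    """EXP/CON/STA per OG, from a parsed CAFE report when supplied."""
    events = cafe_events if cafe_events is not None else branch_events(orthology, tree)
    return turnover_proportions(events, internal_only=internal_only, tree=tree)
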