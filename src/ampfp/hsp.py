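"""Hidden-state prediction: infer trait values at a query's attachment point.

Two methods:

* ``max_parsimony`` — Sankoff minimum-change reconstruction per trait with
  linear cost |a - b| between integer states over the observed state range.
  The query hangs on a zero-cost pendant edge, so its value is the optimal
  state at its parent (the attachment node); ties go to the smallest state.
* ``distance_weighted`` — inverse-distance weighted mean of reference tip
  values, with distances measured along the tree from the attachment point
  (pendant length excluded). An exact tip placement returns that tip's
  values exactly.

Branch lengths are ignored by parsimony; polytomies are handled directly
(under the linear |a-b| cost this is equivalent to any zero-length
binarisation).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Sankoff state-space cap; wider integer traits fall back to distance_weighted.
MAX_PARSIMONY_STATES = 64

DISTANCE_EPSILON = 1e-9

METHOD_MAX_PARSIMONY = "max_parsimony"
METHOD_DISTANCE_WEIGHTED = "distance_weighted"
_METHOD_ALIASES = {
    "mp": METHOD_MAX_PARSIMONY,
    "max_parsimony": METHOD_MAX_PARSIMONY,
    "dw": METHOD_DISTANCE_WEIGHTED,
    "distance_weighted": METHOD_DISTANCE_WEIGHTED,
}


def canonical_method(name: str) -> str:
    try:
        return _METHOD_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown HSP method {name!r}; choose from {sorted(_METHOD_ALIASES)}") from None


def node_to_tip_distances(node: TreeNode) -> dict[str, float]:
    """Path length from ``node`` to every tip of its tree (undirected walk)."""
    dist: dict[TreeNode, float] = {node: 0.0}
    out: dict[str, float] = {}
    stack = [node]
    while stack:
        cur = stack.pop()
        d = dist[cur]
        if cur.is_tip() and cur is not node:
            out[cur.name] = d
        neighbours: list[tuple[TreeNode, float]] = []
        for child in cur.children:
            neighbours.append((child, child.length or 0.0))
        if cur.parent is not None:
            neighbours.append((cur.parent, cur.length or 0.0))
        for nxt, edge in neighbours:
            if nxt not in dist:
                dist[nxt] = d + edge
                stack.append(nxt)
    if node.is_tip():
        out[node.name] = 0.0
    return out


def _attachment_node(tree: TreeNode, query_id: str) -> TreeNode:
    query = tree.find(query_id)
    if not query.is_tip():
        raise ValueError(f"query {query_id!r} is not a tip of the grafted tree")
    if query.parent is None:
        raise ValueError(f"query {query_id!r} is the root; cannot locate attachment node")
    return query.parent


def hsp_distance_weighted(
    tree: TreeNode,
    traits: pd.DataFrame,
    query_id: str,
    eps: float = DISTANCE_EPSILON,
) -> pd.Series:
    """Inverse-distance weighted trait prediction for a grafted query tip.

    ``traits`` is indexed by reference tip id (all non-query tips must be
    covered). A zero-distance reference tip short-circuits to that tip's
    exact values (ties broken by lexicographically smaller tip id).
    """
    attach = _attachment_node(tree, query_id)
    dists = node_to_tip_distances(attach)
    dists.pop(query_id, None)
    ref_tips = sorted(dists)
    missing = [t for t in ref_tips if t not in traits.index]
    if missing:
        raise KeyError(f"trait matrix does not cover tips: {missing}")
    exact = sorted(t for t in ref_tips if dists[t] == 0.0)
    if exact:
        return traits.loc[exact[0]].astype(float)
    d = np.array([dists[t] for t in ref_tips])
    w = 1.0 / (d + eps)
    x = traits.loc[ref_tips].to_numpy(dtype=float)
    values = w @ x / w.sum()
    return pd.Series(values, index=traits.columns, dtype=float)


def _check_integer_traits(traits: pd.DataFrame) -> pd.DataFrame:
    arr = traits.to_numpy(dtype=float)
    if not np.allclose(arr, np.rint(arr), atol=1e-9):
        raise ValueError(
            "max-parsimony HSP requires non-negative integer traits; "
            "use the distance_weighted method for continuous traits"
        )
    if (arr < 0).any():
        raise ValueError("trait values must be non-negative")
    return traits.round().astype(int)


def _sankoff_root_costs(
    root: TreeNode, avoid: TreeNode | None, tip_states: dict[str, int], states: np.ndarray
) -> np.ndarray:
    """Cost vector at ``root`` of the tree re-rooted there, skipping ``avoid``.

    Iterative post-order over the undirected tree viewed from ``root``;
    transition cost between states a, b is |a - b| regardless of branch
    length. Tips contribute 0 for their observed state, +inf otherwise.
    """
    n_states = len(states)
    cost_matrix = np.abs(states[:, None] - states[None, :]).astype(float)

    def neighbours(node: TreeNode, parent: TreeNode | None) -> list[TreeNode]:
        nbrs = [c for c in node.children if c is not parent and c is not avoid]
        if node.parent is not None and node.parent is not parent and node.parent is not avoid:
            nbrs.append(node.parent)
        return nbrs

    # Post-order over (node, parent-in-rerooted-view) pairs, iteratively.
    order: list[tuple[TreeNode, TreeNode | None]] = []
    stack: list[tuple[TreeNode, TreeNode | None]] = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nbr in neighbours(node, parent):
            stack.append((nbr, node))

    costs: dict[int, np.ndarray] = {}
    for node, parent in reversed(order):
        nbrs = neighbours(node, parent)
        if not nbrs:  # leaf in the rerooted view
            vec = np.full(n_states, np.inf)
            state = tip_states.get(node.name)
            if state is None:
                raise KeyError(f"no trait state for tip {node.name!r}")
            vec[np.searchsorted(states, state)] = 0.0
            costs[id(node)] = vec
            continue
        vec = np.zeros(n_states)
        for nbr in nbrs:
            child_cost = costs.pop(id(nbr))
            vec += (child_cost[None, :] + cost_matrix).min(axis=1)
        costs[id(node)] = vec
    return costs[id(root)]


def hsp_max_parsimony(
    tree: TreeNode,
    traits: pd.DataFrame,
    query_id: str,
    max_states: int = MAX_PARSIMONY_STATES,
) -> tuple[pd.Series, pd.Series]:
    """Sankoff minimum-change prediction for a grafted query tip.

    Returns ``(values, costs)``: the predicted state per trait (smallest
    state among co-optimal ones) and the minimal total parsimony cost per
    trait. Traits whose observed integer range exceeds ``max_states``
    states fall back to distance-weighted prediction with a logged notice
    (their cost is reported as NaN).

    An attachment point coinciding exactly with a reference tip (path
    distance 0, e.g. an exact sequence match) short-circuits to that tip's
    values with zero added cost, so exact reference matches are always
    recovered verbatim.
    """
    attach = _attachment_node(tree, query_id)
    query = tree.find(query_id)
    int_traits = _check_integer_traits(traits)

    attach_dists = node_to_tip_distances(attach)
    attach_dists.pop(query_id, None)
    exact = sorted(t for t, d in attach_dists.items() if d == 0.0)
    if exact:
        values = traits.loc[exact[0]].astype(float)
        return values, pd.Series(0.0, index=traits.columns)

    ref_tips = [t.name for t in tree.tips() if t.name != query_id]
    missing = [t for t in ref_tips if t not in int_traits.index]
    if missing:
        raise KeyError(f"trait matrix does not cover tips: {missing}")

    values = pd.Series(index=traits.columns, dtype=float)
    costs = pd.Series(index=traits.columns, dtype=float)
    fallback_traits: list[str] = []
    dw_cache: pd.Series | None = None

    for trait in int_traits.columns:
        col = int_traits[trait]
        lo, hi = int(col.loc[ref_tips].min()), int(col.loc[ref_tips].max())
        if lo == hi:
            values[trait] = float(lo)
            costs[trait] = 0.0
            continue
        if hi - lo + 1 > max_states:
            if dw_cache is None:
                dw_cache = hsp_distance_weighted(tree, traits.astype(float), query_id)
            values[trait] = dw_cache[trait]
            costs[trait] = np.nan
            fallback_traits.append(trait)
            continue
        states = np.arange(lo, hi + 1)
        tip_states = {t: int(col[t]) for t in ref_tips}
        root_cost = _sankoff_root_costs(attach, avoid=query, tip_states=tip_states, states=states)
        best = root_cost.min()
        # smallest co-optimal state wins
        values[trait] = float(states[int(np.flatnonzero(root_cost == best)[0])])
        costs[trait] = float(best)

    if fallback_traits:
        logger.info(
            "%d trait(s) exceeded the %d-state parsimony cap; used distance-weighted "
            "prediction instead (e.g. %s)",
            len(fallback_traits),
            max_states,
            fallback_traits[:3],
        )
    return values, costs


def predict_query_traits(
    tree_with_query: TreeNode,
    traits: pd.DataFrame,
    query_id: str,
    method: str = METHOD_MAX_PARSIMONY,
) -> pd.Series:
    """Dispatch on HSP method; returns the predicted trait vector."""
    method = canonical_method(method)
    if method == METHOD_DISTANCE_WEIGHTED:
        return hsp_distance_weighted(tree_with_query, traits, query_id)
    values, _ = hsp_max_parsimony(tree_with_query, traits, query_id)
    return values
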