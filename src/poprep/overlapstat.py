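"""Cluster-category overlap scores and permutation tests.

Two overlap conventions are implemented.  For partition clusters the score
is the mean of Ratio 1 (= |I| / |category|) and Ratio 2 (= |I| / |cluster|).
For forest clusters the score is the intersection-over-union between the
category and the best-matching *connected subtree*, maximized over all
connected subtrees of every tree via Dinkelbach's fractional programming
scheme on a max-weight connected-subtree dynamic program.

Null distributions reshuffle either individual objects or whole twin sets
(the latter discounts the pixel-level similarity of twin exemplars and is
much more conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dmst import Forest
from .imgprops import CategoryScheme

__all__ = [
    "OverlapResult",
    "iou_from_ratios",
    "kmeans_overlap",
    "kmeans_overlap_test",
    "best_subtree_overlap",
    "enumerate_connected_subtrees",
    "dmst_overlap_test",
]

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    """Overlap of one cluster (or best subtree) with one category."""

    score: float
    ratio1: float
    ratio2: float
    best_subtree: frozenset = field(default_factory=frozenset)
    p_object: float | None = None
    p_twin: float | None = None
    significant_object: bool | None = None
    significant_twin: bool | None = None


def iou_from_ratios(ratio1: float, ratio2: float) -> float:
    """Intersection-over-union reconstructed from the two ratios.

    With I the intersection, ratio1 = I/|category| and ratio2 = I/|cluster|,
    so |union| = I/ratio1 + I/ratio2 - I and the IoU equals
    ``1 / (1/ratio1 + 1/ratio2 - 1)`` whenever I > 0.
    """
    if ratio1 <= 0 or ratio2 <= 0:
        return 0.0
    return 1.0 / (1.0 / ratio1 + 1.0 / ratio2 - 1.0)


def kmeans_overlap(cluster, category) -> OverlapResult:
    """Averaged-ratio overlap between a partition cluster and a category."""
    cluster, category = frozenset(cluster), frozenset(category)
    if not cluster or not category:
        raise ValueError("cluster and category must be non-empty")
    inter = len(cluster & category)
    r1 = inter / len(category)
    r2 = inter / len(cluster)
    return OverlapResult(score=(r1 + r2) / 2.0, ratio1=r1, ratio2=r2)


def kmeans_overlap_test(
    clusters: list,
    scheme: CategoryScheme,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Averaged-ratio overlaps with a size-preserving reshuffle null.

    ``clusters`` must partition the object universe.  For each (cluster,
    category) pair, the null redistributes objects among the clusters
    (preserving cluster sizes) and recomputes the score; p-values use the
    add-one permutation convention and are Bonferroni-corrected over the
    whole tested family.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    clusters = [frozenset(c) for c in clusters]
    universe = sorted(frozenset().union(*clusters))
    if sum(len(c) for c in clusters) != len(universe):
        raise ValueError("clusters must partition the universe")
    rng = np.random.default_rng(seed)
    objects = np.array(universe, dtype=object)
    sizes = [len(c) for c in clusters]
    bounds = np.cumsum([0] + sizes)

    cat_names = list(scheme.categories)
    cat_masks = {
        name: np.array([o in scheme.categories[name] for o in objects])
        for name in cat_names
    }
    clu_masks = np.array(
        [[o in c for o in objects] for c in clusters]
    )

    def scores_for(perm_clu_masks: np.ndarray) -> np.ndarray:
        out = np.empty((len(clusters), len(cat_names)))
        for ci in range(len(clusters)):
            cm = perm_clu_masks[ci]
            for ki, name in enumerate(cat_names):
                inter = int((cm & cat_masks[name]).sum())
                out[ci, ki] = 0.5 * (
                    inter / cat_masks[name].sum() + inter / cm.sum()
                )
        return out

    observed = scores_for(clu_masks)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(len(objects))
        pm = np.zeros_like(clu_masks)
        for ci in range(len(clusters)):
            pm[ci, perm[bounds[ci]:bounds[ci + 1]]] = True
        exceed += scores_for(pm) >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    n_tests = pvals.size
    rows = []
    for ci, cluster in enumerate(clusters):
        for ki, name in enumerate(cat_names):
            res = kmeans_overlap(cluster, scheme.categories[name])
            rows.append({
                "cluster": ci,
                "category": name,
                "ratio1": res.ratio1,
                "ratio2": res.ratio2,
                "overlap": res.score,
                "p": pvals[ci, ki],
                "significant": pvals[ci, ki] < alpha / n_tests,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# best connected subtree (intersection over union)

def _adjacency(edges: list[tuple]) -> dict:
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _max_weight_subtree(
    nodes: list, adj: dict, weight: dict
) -> tuple[float, frozenset]:
    """Best-scoring non-empty connected subgraph of a tree.

    Classic rooted DP: the best subtree containing v within v's rooted
    subtree is w(v) plus every positive child contribution.
    """
    root = nodes[0]
    best_at: dict = {}
    keep_children: dict = {}
    order, parent = [], {root: None}
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for u in adj.get(v, ()):  # tree: no revisiting needed beyond parent
            if u != parent[v]:
                parent[u] = v
                stack.append(u)
    for v in reversed(order):
        total = weight[v]
        kept = []
        for u in adj.get(v, ()):
            if parent.get(u) == v and best_at[u] > 0:
                total += best_at[u]
                kept.append(u)
        best_at[v] = total
        keep_children[v] = kept

    best_v = max(order, key=lambda v: best_at[v])

    members = set()
    stack = [best_v]
    while stack:
        v = stack.pop()
        members.add(v)
        stack.extend(keep_children[v])
    return best_at[best_v], frozenset(members)


def best_subtree_overlap(
    tree_nodes,
    tree_edges: list[tuple],
    category,
    tol: float = 1e-12,
) -> OverlapResult:
    """Maximum IoU between the category and any connected subtree.

    Dinkelbach iteration: for a candidate ratio r each node gets weight
    ``(1 + r)`` if it belongs to the category and ``-r`` otherwise; the
    max-weight connected subtree then certifies whether a subtree with
    IoU > r exists, and the iteration converges to the optimum in a finite
    number of steps.
    """
    nodes = list(tree_nodes)
    category = frozenset(category)
    if not category:
        raise ValueError("category must be non-empty")
    if not nodes:
        raise ValueError("tree must be non-empty")
    if len(nodes) > 1 and len(tree_edges) != len(nodes) - 1:
        raise ValueError("edges do not form a tree over the nodes")
    in_cat = {v: (v in category) for v in nodes}
    if not any(in_cat.values()):
        return OverlapResult(score=0.0, ratio1=0.0, ratio2=0.0,
                             best_subtree=frozenset())
    adj = _adjacency(tree_edges)
    n_cat = len(category)

    def iou(members: frozenset) -> float:
        inter = sum(1 for v in members if in_cat[v])
        return inter / (len(members) + n_cat - inter)

    # start from any single category member (IoU >= 1/n_cat)
    seed_member = next(v for v in nodes if in_cat[v])
    best_set = frozenset([seed_member])
    r = iou(best_set)
    # node weight (1 + r) * [v in category] - r, i.e. 1 or -r
    for _ in range(10 * len(nodes) + 20):  # r strictly increases: finite
        weight = {v: 1.0 if in_cat[v] else -r for v in nodes}
        value, members = _max_weight_subtree(nodes, adj, weight)
        # g(r) = I - r * (|S| + |cat| - I); subtree beats r iff g > r-slack
        g = value - r * n_cat
        if g <= tol:
            break
        new_r = iou(members)
        if new_r <= r + tol:
            break
        best_set, r = members, new_r

    inter = sum(1 for v in best_set if in_cat[v])
    return OverlapResult(
        score=r,
        ratio1=inter / n_cat,
        ratio2=inter / len(best_set),
        best_subtree=best_set,
    )


def enumerate_connected_subtrees(nodes, edges: list[tuple]):
    """All non-empty connected subsets of a tree (oracle; exponential)."""
    nodes = list(nodes)
    adj = _adjacency(edges)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    for mask in range(1, 1 << n):
        members = [nodes[i] for i in range(n) if mask & (1 << i)]
        seen = {members[0]}
        stack = [members[0]]
        member_set = set(members)
        while stack:
            v = stack.pop()
            for u in adj.get(v, ()):
                if u in member_set and u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) == len(members):
            yield frozenset(members)


# ---------------------------------------------------------------------------
# forest-level permutation test

def _forest_category_score(
    trees: list[tuple], category: frozenset
) -> tuple[float, OverlapResult]:
    """Max over trees of the best-subtree IoU for one category."""
    best = OverlapResult(score=-1.0, ratio1=0.0, ratio2=0.0)
    for nodes, edges in trees:
        res = best_subtree_overlap(nodes, edges, category)
        if res.score > best.score:
            best = res
    return best.score, best


def _permute_twin_sets(
    twin_sets: list[frozenset],
    target_size: int,
    rng: np.random.Generator,
) -> frozenset:
    """Null category: accumulate shuffled whole twin sets up to the size.

    Object-level sizes are matched as closely as twin-set granularity
    allows (the last set added may overshoot).
    """
    order = rng.permutation(len(twin_sets))
    members: set = set()
    for i in order:
        if len(members) >= target_size:
            break
        members |= twin_sets[i]
    return frozenset(members)


def dmst_overlap_test(
    forest: Forest,
    scheme: CategoryScheme,
    twin_sets: dict[str, frozenset] | None = None,
    n_perm: int = 10_000,
    mode: str = "both",
    alpha_levels: tuple = (0.01, 0.05),
    seed: int = 0,
) -> pd.DataFrame:
    """Best-subtree overlap per category with permutation significance.

    The observed statistic for a category is the maximum over forest trees
    of the best connected-subtree IoU.  The null permutes category
    membership over individual objects (``mode="object"``) and/or whole
    twin sets (``mode="twin"``); p-values use the add-one convention and
    are Holm-Bonferroni corrected within the scheme at each alpha level.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("twin", "object", "both"):
        raise ValueError("mode must be 'twin', 'object' or 'both'")
    universe = list(forest.object_ids)
    trees = list(zip(forest.trees(), forest.tree_edges()))
    trees = [(sorted(t), e) for t, e in trees]
    rng = np.random.default_rng(seed)

    if twin_sets is None:
        twin_sets = {str(o): frozenset([o]) for o in universe}
    twin_list = [s & frozenset(universe) for s in twin_sets.values()]
    twin_list = [s for s in twin_list if s]
    covered = frozenset().union(*twin_list)
    if covered != frozenset(universe):
        raise ValueError("twin sets must partition the object universe")
    if sum(len(s) for s in twin_list) != len(universe):
        raise ValueError("twin sets must be disjoint")

    do_twin = mode in ("twin", "both")
    do_object = mode in ("object", "both")

    names = []
    observed = []
    results = []
    for name, category in scheme.categories.items():
        cat = frozenset(category) & frozenset(universe)
        if not cat:
            raise ValueError(f"category {name!r} disjoint from the universe")
        if do_twin:
            split = [
                s for s in twin_list if s & cat and not s <= cat
            ]
            if split:
                logger.warning(
                    "category %r splits %d twin set(s)", name, len(split)
                )
        score, best = _forest_category_score(trees, cat)
        names.append(name)
        observed.append(score)
        results.append(best)

    exceed_obj = np.zeros(len(names))
    exceed_twin = np.zeros(len(names))
    objects = np.array(universe, dtype=object)
    sizes = [len(frozenset(scheme.categories[n]) & frozenset(universe))
             for n in names]
    for _ in range(n_perm):
        if do_object:
            for k, size in enumerate(sizes):
                null_cat = frozenset(
                    objects[rng.choice(len(objects), size, replace=False)]
                )
                s, _b = _forest_category_score(trees, null_cat)
                exceed_obj[k] += s >= observed[k]
        if do_twin:
            for k, size in enumerate(sizes):
                null_cat = _permute_twin_sets(twin_list, size, rng)
                s, _b = _forest_category_score(trees, null_cat)
                exceed_twin[k] += s >= observed[k]

    rows = []
    p_obj = (1.0 + exceed_obj) / (1.0 + n_perm) if do_object else None
    p_twin = (1.0 + exceed_twin) / (1.0 + n_perm) if do_twin else None
    for k, name in enumerate(names):
        rows.append({
            "category": name,
            "ratio1": results[k].ratio1,
            "ratio2": results[k].ratio2,
            "overlap": observed[k],
            "best_subtree": results[k].best_subtree,
            "p_twin": None if p_twin is None else float(p_twin[k]),
            "p_object": None if p_obj is None else float(p_obj[k]),
        })
    table = pd.DataFrame(rows)
    for col, prefix in (("p_twin", "sig_twin"), ("p_object", "sig_object")):
        if table[col].isna().all():
            for a in alpha_levels:
                table[f"{prefix}_{a}"] = None
            continue
        for a in alpha_levels:
            rej, _, _, _ = multipletests(
                table[col].to_numpy(dtype=float), alpha=a, method="holm"
            )
            table[f"{prefix}_{a}"] = rej
    return table
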