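"""Bounded-depth minimum spanning forest clustering.

The object set is augmented with an artificial root whose edge to every
object costs ``lambda_``; a spanning tree of the augmented graph in which
every object lies within a bounded number of links of its tree's
root-attached node (the cluster *center*) induces a partition of the
objects into trees.  Larger ``lambda_`` yields fewer clusters.

Two solvers are provided:

* :func:`exact_forest` — exact dynamic programming over node subsets,
  feasible up to ~12 objects; used as the reference oracle.
* :func:`build_forest` — max-sum message passing with reinforcement
  (seeded, non-deterministic across seeds) followed by a feasibility repair
  and a first-improvement local search; scales to hundreds of objects.

Depth convention: the artificial root has depth 0 and each cluster center
depth 1; a maximum depth ``d_max`` allows at most ``d_max - 1`` links
between any object and its cluster center.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DMSTParams",
    "Forest",
    "exact_forest",
    "build_forest",
    "stability_scan",
    "consensus_forest",
    "pair_agreement",
]

logger = logging.getLogger(__name__)

ROOT = -1


@dataclass
class DMSTParams:
    """Solver parameters: root-attachment cost and depth bound."""

    lambda_: float
    d_max: int = 6
    n_iter: int = 300
    seed: int = 0
    reinforcement_rate: float = 2e-3
    noise_scale: float = 1e-4
    anneal_steps: int = 3000

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")


@dataclass
class Forest:
    """A depth-bounded spanning forest over an object set.

    ``parents[i]`` is the index of object i's parent, or ``ROOT`` (-1) when
    the object is a cluster center.  ``link_weights[i]`` is the stability
    weight of the link (i, parents[i]) in [0, 1]; 1.0 for a single run.
    """

    parents: np.ndarray
    object_ids: list
    d_max: int
    link_weights: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.parents = np.asarray(self.parents, dtype=int)
        n = len(self.parents)
        if self.link_weights is None:
            self.link_weights = np.ones(n)
        self.link_weights = np.asarray(self.link_weights, dtype=float)
        self.validate()

    @property
    def n_objects(self) -> int:
        return len(self.parents)

    def depths(self) -> np.ndarray:
        """Depth of each object (center = 1); raises on cycles."""
        n = self.n_objects
        depth = np.full(n, -1)
        for i in range(n):
            chain = []
            j = i
            while j != ROOT and depth[j] < 0:
                chain.append(j)
                j = self.parents[j]
                if len(chain) > n:
                    raise ValueError("cycle in parent pointers")
            base = 0 if j == ROOT else depth[j]
            for k, node in enumerate(reversed(chain)):
                depth[node] = base + k + 1
        return depth

    def validate(self) -> None:
        depth = self.depths()
        if (depth > self.d_max).any():
            raise ValueError("depth bound violated")

    def tree_labels(self) -> np.ndarray:
        """Cluster index per object (trees hanging off the root)."""
        n = self.n_objects
        label = np.full(n, -1)
        centers = [i for i in range(n) if self.parents[i] == ROOT]
        for c_idx, c in enumerate(centers):
            label[c] = c_idx
        for i in range(n):
            chain = []
            j = i
            while label[j] < 0:
                chain.append(j)
                j = self.parents[j]
            for node in chain:
                label[node] = label[j]
        return label

    def trees(self) -> list[frozenset]:
        """Object-id sets of the clusters, largest first."""
        label = self.tree_labels()
        out = []
        for c in range(label.max() + 1):
            out.append(frozenset(
                self.object_ids[i] for i in np.flatnonzero(label == c)
            ))
        return sorted(out, key=lambda t: (-len(t), sorted(t)))

    def tree_edges(self) -> list[list[tuple]]:
        """Per tree (same order as :meth:`trees`), its undirected edges."""
        label = self.tree_labels()
        trees = self.trees()
        index = {frozenset(t): k for k, t in enumerate(trees)}
        edges: list[list[tuple]] = [[] for _ in trees]
        groups = {}
        for c in range(label.max() + 1):
            members = frozenset(
                self.object_ids[i] for i in np.flatnonzero(label == c)
            )
            groups[c] = index[members]
        for i in range(self.n_objects):
            p = self.parents[i]
            if p != ROOT:
                edges[groups[label[i]]].append(
                    (self.object_ids[i], self.object_ids[p])
                )
        return edges

    @property
    def n_clusters(self) -> int:
        return int((self.parents == ROOT).sum())

    def cost(self, d: np.ndarray, lambda_: float) -> float:
        total = 0.0
        for i, p in enumerate(self.parents):
            total += lambda_ if p == ROOT else d[i, p]
        return float(total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.parents):
            rows.append({
                "child": self.object_ids[i],
                "parent": "ROOT" if p == ROOT else self.object_ids[p],
                "weight": self.link_weights[i],
            })
        return pd.DataFrame(rows)


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("dissimilarity matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return d


# ---------------------------------------------------------------------------
# exact solver (subset dynamic programming)

def exact_forest(
    d: np.ndarray,
    lambda_: float,
    d_max: int,
    object_ids: list | None = None,
    max_n: int = 14,
) -> Forest:
    """Exact minimum-cost depth-bounded spanning forest (small n only).

    Dynamic programming over node subsets: ``tree(S, r, h)`` is the minimum
    cost of a tree spanning ``S`` rooted at ``r`` with height at most ``h``,
    split canonically on the lowest-index non-root element.
    """
    d = _check_dissimilarity(d)
    n = d.shape[0]
    if n > max_n:
        raise ValueError(f"exact solver limited to n <= {max_n}")
    if object_ids is None:
        object_ids = list(range(n))
    full = (1 << n) - 1
    height = d_max - 1  # links below the cluster center

    tree_memo: dict = {}

    def tree(S: int, r: int, h: int):
        """(cost, parent-assignments) for a tree on S rooted at r."""
        rest = S & ~(1 << r)
        if rest == 0:
            return 0.0, ()
        key = (S, r, h)
        if key in tree_memo:
            return tree_memo[key]
        if h == 0:
            tree_memo[key] = (np.inf, ())
            return tree_memo[key]
        u = (rest & -rest).bit_length() - 1  # lowest-index element
        best = (np.inf, ())
        # enumerate submasks T of rest that contain u
        T = rest
        while T:
            if T & (1 << u):
                for c in range(n):
                    if not T & (1 << c):
                        continue
                    sub_cost, sub_par = tree(T, c, h - 1)
                    if not np.isfinite(sub_cost):
                        continue
                    rem_cost, rem_par = tree(S & ~T, r, h)
                    total = d[r, c] + sub_cost + rem_cost
                    if total < best[0] - 1e-15:
                        best = (total, sub_par + ((c, r),) + rem_par)
            T = (T - 1) & rest
        tree_memo[key] = best
        return best

    forest_memo: dict = {}

    def forest(S: int):
        if S == 0:
            return 0.0, ()
        if S in forest_memo:
            return forest_memo[S]
        u = (S & -S).bit_length() - 1
        best = (np.inf, ())
        T = S
        while T:
            if T & (1 << u):
                for c in range(n):
                    if not T & (1 << c):
                        continue
                    t_cost, t_par = tree(T, c, height)
                    if not np.isfinite(t_cost):
                        continue
                    r_cost, r_par = forest(S & ~T)
                    total = lambda_ + t_cost + r_cost
                    if total < best[0] - 1e-15:
                        best = (total, t_par + ((c, ROOT),) + r_par)
            T = (T - 1) & S
        forest_memo[S] = best
        return best

    cost, assignment = forest(full)
    parents = np.full(n, ROOT)
    for child, parent in assignment:
        parents[child] = parent
    out = Forest(parents=parents, object_ids=list(object_ids), d_max=d_max)
    assert abs(out.cost(d, lambda_) - cost) < 1e-9
    return out


# ---------------------------------------------------------------------------
# max-sum message passing with reinforcement

def _repair(parents: np.ndarray, depths_limit: int, d: np.ndarray,
            lambda_: float) -> np.ndarray:
    """Turn an arbitrary parent assignment into a valid bounded forest.

    Nodes whose ancestry is cyclic or too deep are re-attached greedily
    (cheapest feasible parent among already-valid nodes, or the root).
    """
    n = len(parents)
    parents = parents.copy()
    depth = np.full(n, -1)
    # resolve nodes whose chain reaches ROOT within the depth bound
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if depth[i] >= 0:
                continue
            p = parents[i]
            if p == ROOT:
                depth[i] = 1
                changed = True
            elif depth[p] > 0 and depth[p] < depths_limit:
                depth[i] = depth[p] + 1
                changed = True
    unresolved = np.flatnonzero(depth < 0)
    # attach unresolved nodes one at a time, cheapest option first
    pending = set(unresolved.tolist())
    while pending:
        best = None
        for i in pending:
            cand_cost, cand_parent = lambda_, ROOT
            ok = (depth > 0) & (depth < depths_limit)
            if ok.any():
                js = np.flatnonzero(ok)
                j = js[np.argmin(d[i, js])]
                if d[i, j] < cand_cost:
                    cand_cost, cand_parent = d[i, j], int(j)
            if best is None or cand_cost < best[0]:
                best = (cand_cost, i, cand_parent)
        _, i, p = best
        parents[i] = p
        depth[i] = 1 if p == ROOT else depth[p] + 1
        pending.discard(i)
    return parents


def _depths_or_none(parents: np.ndarray) -> np.ndarray | None:
    """Depths for a parent assignment, or None if it contains a cycle."""
    n = len(parents)
    depth = np.full(n, -1)
    for i in range(n):
        chain = []
        j = i
        while j != ROOT and depth[j] < 0:
            chain.append(j)
            j = parents[j]
            if len(chain) > n:
                return None
        base = 0 if j == ROOT else depth[j]
        for k, node in enumerate(reversed(chain)):
            depth[node] = base + k + 1
    return depth


def _is_valid(parents: np.ndarray, d_max: int) -> bool:
    depth = _depths_or_none(parents)
    return depth is not None and (depth <= d_max).all()


def _assignment_cost(parents: np.ndarray, d: np.ndarray,
                     lambda_: float) -> float:
    is_root = parents == ROOT
    idx = np.flatnonzero(~is_root)
    return float(
        lambda_ * is_root.sum() + d[idx, parents[idx]].sum()
    )


def _swap_positions(parents: np.ndarray, u: int, v: int) -> np.ndarray:
    """Exchange the positions of nodes u and v in the forest topology."""
    p = parents.copy()
    pu, pv = p[u], p[v]
    for i in range(len(p)):
        if i in (u, v):
            continue
        if p[i] == u:
            p[i] = v
        elif p[i] == v:
            p[i] = u
    if pu == v:
        p[v], p[u] = u, pv
    elif pv == u:
        p[u], p[v] = v, pu
    else:
        p[u], p[v] = pv, pu
    return p


def _reroot(parents: np.ndarray, center: int) -> np.ndarray:
    """Make ``center`` the root-attached node of its tree."""
    p = parents.copy()
    path = []
    j = center
    while p[j] != ROOT:
        path.append(j)
        j = p[j]
    path.append(j)
    for a, b in zip(path, path[1:]):
        p[b] = a
    p[center] = ROOT
    return p


def _anneal(parents: np.ndarray, d: np.ndarray, lambda_: float, d_max: int,
            seed: int, steps: int) -> np.ndarray:
    """Simulated-annealing refinement over parent-move / swap / reroot."""
    if steps <= 0:
        return parents
    rng = np.random.default_rng(seed)
    n = len(parents)
    # temperature scaled to the dissimilarity magnitude
    off = d[~np.eye(n, dtype=bool)]
    T0 = 0.4 * (float(off.mean()) if off.size else 1.0)
    cur = parents.copy()
    cc = _assignment_cost(cur, d, lambda_)
    best, bc = cur.copy(), cc
    for t in range(steps):
        T = T0 * (1.0 - t / steps) + 1e-4
        kind = rng.integers(3)
        if kind == 0:
            i = int(rng.integers(n))
            newp = int(rng.integers(-1, n))
            if newp == i or newp == cur[i]:
                continue
            cand = cur.copy()
            cand[i] = newp
        elif kind == 1:
            u, v = int(rng.integers(n)), int(rng.integers(n))
            if u == v:
                continue
            cand = _swap_positions(cur, u, v)
        else:
            cand = _reroot(cur, int(rng.integers(n)))
        if not _is_valid(cand, d_max):
            continue
        c2 = _assignment_cost(cand, d, lambda_)
        if c2 < cc or rng.random() < np.exp(-(c2 - cc) / T):
            cur, cc = cand, c2
            if cc < bc - 1e-12:
                best, bc = cur.copy(), cc
    return best


def _local_search(parents: np.ndarray, d: np.ndarray, lambda_: float,
                  d_max: int, max_rounds: int = 200) -> np.ndarray:
    """First-improvement single-parent and position-swap moves."""
    n = len(parents)
    parents = parents.copy()

    def edge_cost(i, p):
        return lambda_ if p == ROOT else d[i, p]

    for _ in range(max_rounds):
        f = Forest(parents, list(range(n)), d_max)
        depth = f.depths()
        # subtree height below each node
        children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(parents):
            if p != ROOT:
                children[p].append(i)
        height = np.zeros(n, dtype=int)
        for i in sorted(range(n), key=lambda i: -depth[i]):
            for c in children[i]:
                height[i] = max(height[i], height[c] + 1)
        # descendant masks to forbid cycles
        desc = [set() for _ in range(n)]
        for i in sorted(range(n), key=lambda i: -depth[i]):
            for c in children[i]:
                desc[i].add(c)
                desc[i] |= desc[c]
        improved = False
        for i in range(n):
            old = edge_cost(i, parents[i])
            best_gain, best_p = 1e-12, None
            if parents[i] != ROOT and old - lambda_ > best_gain:
                best_gain, best_p = old - lambda_, ROOT
            for j in range(n):
                if j == i or j in desc[i] or j == parents[i]:
                    continue
                if depth[j] + 1 + height[i] > d_max:
                    continue
                gain = old - d[i, j]
                if gain > best_gain:
                    best_gain, best_p = gain, j
            if best_p is not None:
                parents[i] = best_p
                improved = True
                break
        if not improved:
            # position swaps: exchange two nodes in the fixed topology
            cur_cost = _assignment_cost(parents, d, lambda_)
            for u in range(n):
                for v in range(u + 1, n):
                    cand = _swap_positions(parents, u, v)
                    c2 = _assignment_cost(cand, d, lambda_)
                    if c2 < cur_cost - 1e-12:
                        parents = cand
                        improved = True
                        break
                if improved:
                    break
        if not improved:
            break
    return parents


def build_forest(
    d: np.ndarray,
    params: DMSTParams,
    object_ids: list | None = None,
    polish: bool = True,
) -> Forest:
    """Approximate the minimum-cost depth-bounded spanning forest.

    Max-sum message passing on the augmented-root graph with a linearly
    increasing reinforcement field; every iteration is decoded, repaired to
    feasibility, and the cheapest configuration found is returned (polished
    by local search unless ``polish=False``).  If the decoding never
    stabilizes within ``n_iter`` iterations the best configuration found is
    returned with ``converged=False``.
    """
    d = _check_dissimilarity(d)
    n = d.shape[0]
    if object_ids is None:
        object_ids = list(range(n))
    if n == 1:
        return Forest(np.array([ROOT]), list(object_ids), params.d_max)
    D = params.d_max
    lam = params.lambda_
    rng = np.random.default_rng(params.seed)

    NEG = -1e18
    # messages, ordered pair (j, i): j's state as seen from i
    E = rng.normal(0.0, params.noise_scale, (n, n, D + 1))
    F = rng.normal(0.0, params.noise_scale, (n, n, D + 1))
    C = rng.normal(0.0, params.noise_scale, (n, n))
    R = np.zeros((n, n + 1, D + 1))  # reinforcement field; column n = ROOT
    E[:, :, 0] = NEG
    F[:, :, :2] = NEG

    eye = np.eye(n, dtype=bool)
    best_parents, best_cost = None, np.inf
    stable_decodes, last_decode = 0, None

    for t in range(1, params.n_iter + 1):
        # N[k, j, d] = message from k to j when j is not k's parent
        N = np.empty((n, n, D + 1))
        N[:, :, :D] = np.maximum(F[:, :, 1:], C[:, :, None])
        N[:, :, D] = C
        N[:, :, 0] = NEG
        T = N.sum(axis=0) - N[np.arange(n), np.arange(n), :]  # (j, d)

        # val[j, m, d] = -c(j,m) + R + E_{m->j}(d-1) - N_{m->j}(d)
        val = np.full((n, n, D + 1), NEG)
        val[:, :, 2:] = (
            -d.T[:, :, None]
            + R[:, :n, 2:]
            + np.swapaxes(E, 0, 1)[:, :, 1:D]
            - np.swapaxes(N, 0, 1)[:, :, 2:]
        )
        val[eye] = NEG

        order = np.argsort(-val, axis=1)
        vmax = np.take_along_axis(val, order[:, :1, :], axis=1)[:, 0, :]
        v2nd = np.take_along_axis(val, order[:, 1:2, :], axis=1)[:, 0, :]
        amax = order[:, 0, :]

        E_new = np.empty_like(E)
        # depth >= 2: max over parents m != i
        exclude = amax[:, None, :] == np.arange(n)[None, :, None]
        inner = np.where(exclude, v2nd[:, None, :], vmax[:, None, :])
        E_new[:, :, :] = inner + T[:, None, :] - np.swapaxes(N, 0, 1)
        # depth 1: parent is the root
        E_new[:, :, 1] = (
            -lam + R[:, n, 1][:, None] + T[:, 1][:, None]
            - N[:, :, 1].T
        )
        E_new[:, :, 0] = NEG

        F_new = np.full_like(F, NEG)
        F_new[:, :, 2:] = (
            -d.T[:, :, None] + R[:, :n, 2:]
            + T[:, None, 2:] - np.swapaxes(N, 0, 1)[:, :, 2:]
        )
        C_new = E_new.max(axis=2)

        E, F, C = E_new, F_new, C_new

        # beliefs over (parent, depth); column n = ROOT
        b = np.full((n, n + 1, D + 1), NEG)
        b[:, :n, 2:] = val[:, :, 2:] + T[:, None, 2:]
        b[:, n, 1] = -lam + R[:, n, 1] + T[:, 1]
        b_flat = b.reshape(n, -1)
        choice = b_flat.argmax(axis=1)
        parents = choice // (D + 1)
        parents = np.where(parents == n, ROOT, parents)

        # reinforcement: linearly increasing bias toward current beliefs
        gamma = params.reinforcement_rate * t
        R = R + gamma * (b - b_flat.max(axis=1)[:, None, None])

        repaired = _repair(parents, D, d, lam)
        cost = Forest(repaired, list(range(n)), D).cost(d, lam)
        if cost < best_cost - 1e-12:
            best_cost, best_parents = cost, repaired
        if last_decode is not None and np.array_equal(parents, last_decode):
            stable_decodes += 1
            if stable_decodes >= 10:
                break
        else:
            stable_decodes = 0
        last_decode = parents

    converged = stable_decodes >= 10
    if not converged:
        logger.debug("max-sum did not stabilize; returning best found")
    if polish:
        polished = _local_search(best_parents, d, lam, D)
        polished = _anneal(
            polished, d, lam, D,
            seed=params.seed + 777, steps=params.anneal_steps,
        )
        polished = _local_search(polished, d, lam, D)
        pcost = _assignment_cost(polished, d, lam)
        if pcost <= best_cost + 1e-12:
            best_parents, best_cost = polished, pcost
    return Forest(
        parents=best_parents, object_ids=list(object_ids), d_max=D,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# stability analysis and consensus

def pair_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of object pairs whose co-clustering status agrees."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    n = len(labels_a)
    iu = np.triu_indices(n, k=1)
    co_a = (labels_a[:, None] == labels_a[None, :])[iu]
    co_b = (labels_b[:, None] == labels_b[None, :])[iu]
    return float((co_a == co_b).mean())


def stability_scan(
    d: np.ndarray,
    lambda_grid,
    dmax_grid,
    n_runs: int = 50,
    seed: int = 0,
    n_iter: int = 150,
    smooth_window: float = 0.15,
    sd_threshold: float = 0.5,
    overlap_threshold: float = 0.9,
    object_ids: list | None = None,
) -> dict:
    """Scan (lambda, d_max) for stability of repeated stochastic runs.

    Per grid cell, ``n_runs`` forests are built with distinct seeds; the
    cell reports the mean/SD of the cluster count and the mean pairwise
    co-clustering agreement between runs.  Per ``d_max``, the agreement is
    additionally smoothed over lambda with a sliding window, and the
    longest contiguous lambda span where the count SD and smoothed
    disagreement fall below the thresholds is reported as the stable
    region.
    """
    d = _check_dissimilarity(d)
    lambda_grid = list(lambda_grid)
    dmax_grid = list(dmax_grid)
    if not lambda_grid or not dmax_grid:
        raise ValueError("parameter grids must be non-empty")
    rows = []
    runs_store: dict = {}
    for d_max in dmax_grid:
        for lam in lambda_grid:
            forests = [
                build_forest(
                    d,
                    DMSTParams(
                        lambda_=lam, d_max=d_max, n_iter=n_iter,
                        seed=seed * 100003 + r,
                    ),
                    object_ids=object_ids,
                )
                for r in range(n_runs)
            ]
            runs_store[(d_max, lam)] = forests
            counts = np.array([f.n_clusters for f in forests])
            labels = [f.tree_labels() for f in forests]
            overlaps = [
                pair_agreement(a, b)
                for a, b in itertools.combinations(labels, 2)
            ] or [1.0]
            rows.append({
                "d_max": d_max,
                "lambda": lam,
                "mean_n_clusters": counts.mean(),
                "sd_n_clusters": counts.std(ddof=0),
                "mean_overlap": float(np.mean(overlaps)),
            })
    table = pd.DataFrame(rows)

    # sliding-window smoothing of overlap over lambda, per d_max
    smoothed = []
    for d_max in dmax_grid:
        sub = table[table["d_max"] == d_max].sort_values("lambda")
        lams = sub["lambda"].to_numpy()
        ov = sub["mean_overlap"].to_numpy()
        for lam in lams:
            w = np.abs(lams - lam) <= smooth_window / 2
            smoothed.append(float(ov[w].mean()))
    table = table.sort_values(["d_max", "lambda"]).reset_index(drop=True)
    table["smoothed_overlap"] = smoothed

    stable = (
        (table["sd_n_clusters"] <= sd_threshold)
        & (1.0 - table["smoothed_overlap"] <= 1.0 - overlap_threshold)
    )
    table["stable"] = stable
    regions = {}
    for d_max in dmax_grid:
        sub = table[table["d_max"] == d_max]
        best_span, cur = None, []
        for _, row in sub.iterrows():
            if row["stable"]:
                cur.append(row["lambda"])
            else:
                cur = []
            if cur and (best_span is None or len(cur) > len(best_span)):
                best_span = list(cur)
        if best_span:
            regions[d_max] = (min(best_span), max(best_span))
    return {"table": table, "stable_regions": regions, "runs": runs_store}


def consensus_forest(
    runs: list[Forest],
    link_threshold: float = 0.5,
) -> Forest:
    """Forest of the most stable links across repeated runs.

    Undirected link frequencies (object-object and object-root) are
    accumulated across runs; links at or above ``link_threshold`` are then
    added greedily by descending weight while maintaining forest validity.
    Objects left without a root path become cluster centers themselves
    (attached to the root), which is logged.
    """
    if not runs:
        raise ValueError("need at least one run")
    ids = runs[0].object_ids
    n = len(ids)
    d_max = max(f.d_max for f in runs)
    for f in runs:
        if f.object_ids != ids:
            raise ValueError("runs must cover the identical object set")

    counts: dict[tuple, int] = {}
    for f in runs:
        for i, p in enumerate(f.parents):
            key = (min(i, p), max(i, p)) if p != ROOT else (ROOT, i)
            counts[key] = counts.get(key, 0) + 1
    weights = {k: v / len(runs) for k, v in counts.items()}

    # greedy Kruskal by descending weight over the augmented graph
    order = sorted(
        weights.items(), key=lambda kv: (-kv[1], kv[0])
    )
    adj: list[set] = [set() for _ in range(n)]
    root_linked = np.zeros(n, dtype=bool)
    comp = list(range(n))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    comp_has_root = [False] * n
    for (a, b), w in order:
        if w < link_threshold:
            continue
        if a == ROOT:
            rb = find(b)
            if comp_has_root[rb]:
                continue
            root_linked[b] = True
            comp_has_root[rb] = True
        else:
            ra, rb = find(a), find(b)
            if ra == rb or (comp_has_root[ra] and comp_has_root[rb]):
                continue
            comp[ra] = rb
            comp_has_root[rb] = comp_has_root[rb] or comp_has_root[ra]
            adj[a].add(b)
            adj[b].add(a)

    # orient trees away from their centers; orphan components get their
    # most root-frequent member promoted to center
    parents = np.full(n, ROOT)
    seen = np.zeros(n, dtype=bool)
    link_weight = np.ones(n)

    def orient(center: int) -> None:
        stack = [center]
        seen[center] = True
        parents[center] = ROOT
        link_weight[center] = weights.get((ROOT, center), 0.0) or 1.0
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    parents[v] = u
                    link_weight[v] = weights[(min(u, v), max(u, v))]
                    stack.append(v)

    for i in np.flatnonzero(root_linked):
        if not seen[i]:
            orient(int(i))
    for i in range(n):
        if not seen[i]:
            comp_members = [
                j for j in range(n) if find(j) == find(i) and not seen[j]
            ]
            center = max(
                comp_members, key=lambda j: weights.get((ROOT, j), 0.0)
            )
            logger.info(
                "component without a surviving root link; promoting %s "
                "to center", ids[center],
            )
            orient(center)

    # enforce the depth bound by promoting too-deep nodes to centers
    while True:
        f = Forest(parents, list(ids), d_max * n)  # no depth check yet
        depth = f.depths()
        too_deep = np.flatnonzero(depth > d_max)
        if too_deep.size == 0:
            break
        i = int(too_deep[depth[too_deep].argmin()])
        logger.info("depth bound exceeded; promoting %s to center", ids[i])
        parents[i] = ROOT
        link_weight[i] = weights.get((ROOT, i), 0.0) or 1.0

    return Forest(
        parents=parents, object_ids=list(ids), d_max=d_max,
        link_weights=link_weight,
    )
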