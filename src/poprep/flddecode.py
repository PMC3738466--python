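"""Binary linear-discriminant decoding of category membership.

Pseudo-population vectors are simultaneity surrogates: for each object,
each vector draws (with replacement) one trial spike count per neuron.
A binary Fisher linear discriminant is trained to separate a positive
object set from its complement, with leave-two-objects-out cross-validation
(one positive, one negative object fully excluded per loop) and a label
shuffle null.

Category pruning removes the visual/semantic confound: the largest subset
of a category such that no two members share a category of the conflicting
hypothesis and no twin set contributes more than one member.  This maximum
independent set problem is solved exactly (max-weight clique on the
complement of the conflict graph) with a small random objective
perturbation so repeated calls sample different maximal solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .imgprops import CategoryScheme
from .neurogen import ResponseDataset

__all__ = [
    "PseudoPopulationSet",
    "PrunedCategory",
    "build_pseudopopulation",
    "fit_fld",
    "run_fld_task",
    "prune_category",
    "build_null_pruned",
]

logger = logging.getLogger(__name__)


@dataclass
class PseudoPopulationSet:
    """Per-object pseudo-population vectors of raw spike counts.

    ``vectors`` has shape ``(n_objects, n_vectors, n_neurons)``.
    """

    vectors: np.ndarray
    object_ids: list
    neuron_ids: list
    seed: int

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


@dataclass
class PrunedCategory:
    """Maximal constraint-satisfying positive / negative object sets."""

    positive: frozenset
    negative: frozenset
    too_small: bool = False
    log: list = field(default_factory=list)


def build_pseudopopulation(
    ds: ResponseDataset, n_vectors: int = 7, seed: int = 0
) -> PseudoPopulationSet:
    """Resample one trial per neuron, per object, per vector."""
    if ds.counts.shape[2] < 1:
        raise ValueError("every (neuron, object) cell needs >= 1 trial")
    rng = np.random.default_rng(seed)
    n_neu, n_obj, n_rep = ds.counts.shape
    picks = rng.integers(0, n_rep, size=(n_obj, n_vectors, n_neu))
    obj_idx = np.arange(n_obj)[:, None, None]
    neu_idx = np.arange(n_neu)[None, None, :]
    vectors = ds.counts[neu_idx, obj_idx, picks]
    return PseudoPopulationSet(
        vectors=vectors,
        object_ids=list(ds.object_ids),
        neuron_ids=list(ds.neuron_ids),
        seed=seed,
    )


def fit_fld(
    X: np.ndarray, y: np.ndarray, shrinkage: float | None = None
) -> tuple[np.ndarray, float]:
    """Binary Fisher discriminant: weight vector and decision threshold.

    Maximizes between-class over within-class variance, i.e.
    ``w = Sw^-1 (mu1 - mu0)``.  When the pooled within-class scatter is
    ill-conditioned a scalar shrinkage toward the identity (scaled by the
    mean within-class variance) is applied and logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    mu0 = X[~y].mean(axis=0)
    mu1 = X[y].mean(axis=0)
    X0 = X[~y] - mu0
    X1 = X[y] - mu1
    Sw = X0.T @ X0 + X1.T @ X1
    dim = X.shape[1]
    if shrinkage is None:
        cond = np.linalg.cond(Sw)
        shrinkage = 0.0 if np.isfinite(cond) and cond < 1e8 else 0.1
        if shrinkage:
            logger.debug("singular within-class scatter; shrinkage applied")
    if shrinkage:
        Sw = (1 - shrinkage) * Sw + shrinkage * (
            np.trace(Sw) / dim + 1e-12
        ) * np.eye(dim)
    w = np.linalg.solve(
        Sw + 1e-12 * np.eye(dim), mu1 - mu0
    )
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return w, threshold


def _one_loop(
    vectors: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """One leave-two-objects-out loop; returns accuracy on 2 test vectors."""
    pos_objs = np.flatnonzero(labels)
    neg_objs = np.flatnonzero(~labels)
    out_pos = int(rng.choice(pos_objs))
    out_neg = int(rng.choice(neg_objs))
    n_obj, n_vec, n_neu = vectors.shape
    train_objs = np.array(
        [o for o in range(n_obj) if o not in (out_pos, out_neg)]
    )
    X = vectors[train_objs].reshape(-1, n_neu)
    y = np.repeat(labels[train_objs], n_vec)
    w, thr = fit_fld(X, y)
    correct = 0.0
    for obj, want in ((out_pos, True), (out_neg, False)):
        test_vec = vectors[obj, rng.integers(n_vec)]
        pred = float(w @ test_vec) > thr
        correct += pred == want
    return correct / 2.0


def run_fld_task(
    ds: ResponseDataset,
    positive,
    n_loops: int = 30,
    n_runs: int = 200,
    n_vectors: int = 7,
    seed: int = 0,
    negative=None,
) -> dict:
    """Cross-validated FLD performance for one binary task, with a null.

    Per run a fresh pseudo-population set is drawn; per loop one positive
    and one negative object are fully left out, the discriminant fit on the
    rest, and one left-out vector per object scored.  The null repeats the
    procedure with object labels shuffled before each loop.  ``negative``
    defaults to the complement of ``positive``; when given, objects outside
    both sets are excluded from the task.
    """
    positive = frozenset(positive)
    universe = list(ds.object_ids)
    if negative is None:
        negative = frozenset(universe) - positive
    negative = frozenset(negative)
    if len(positive) < 2 or len(negative) < 2:
        raise ValueError(
            "positive and negative sets each need >= 2 objects"
        )
    keep = [i for i, o in enumerate(universe) if o in positive | negative]
    labels_all = np.array([universe[i] in positive for i in keep])
    rng = np.random.default_rng(seed)

    def one_run(shuffle: bool, run_seed: int) -> float:
        pps = build_pseudopopulation(ds, n_vectors, seed=run_seed)
        vectors = pps.vectors[keep]
        local = np.random.default_rng(run_seed + 1)
        accs = []
        for _ in range(n_loops):
            labels = labels_all
            if shuffle:
                labels = local.permutation(labels_all)
                if not (2 <= labels.sum() <= len(labels) - 2):
                    continue  # pragma: no cover - sizes preserved by perm
            accs.append(_one_loop(vectors, labels, local))
        return float(np.mean(accs))

    perf = np.array([
        one_run(False, int(rng.integers(2**31))) for _ in range(n_runs)
    ])
    null = np.array([
        one_run(True, int(rng.integers(2**31))) for _ in range(n_runs)
    ])
    observed = float(perf.mean())
    return {
        "performance": observed,
        "sd": float(perf.std(ddof=1)) if n_runs > 1 else 0.0,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_runs > 1 else 0.0,
        "p": float((null >= observed).mean()),
        "n_runs": n_runs,
        "n_loops": n_loops,
    }


# ---------------------------------------------------------------------------
# category pruning (maximum independent set under conflict constraints)

def conflict_graph(
    members,
    conflicting_schemes: list[CategoryScheme],
    twin_sets: dict[str, frozenset],
) -> nx.Graph:
    """Edges join objects that may not co-occur in a pruned category."""
    members = sorted(members)
    g = nx.Graph()
    g.add_nodes_from(members)
    twin_of = {}
    for tid, s in twin_sets.items():
        for o in s:
            twin_of[o] = tid
    cat_of: dict = {o: set() for o in members}
    for scheme in conflicting_schemes:
        for name, cat in scheme.categories.items():
            tag = (scheme.scheme_kind, name)
            for o in cat:
                if o in cat_of:
                    cat_of[o].add(tag)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if twin_of.get(a) is not None and twin_of.get(a) == twin_of.get(b):
                g.add_edge(a, b)
            elif cat_of[a] & cat_of[b]:
                g.add_edge(a, b)
    return g


def _max_independent_set(
    g: nx.Graph, rng: np.random.Generator
) -> frozenset:
    """Exact maximum independent set, ties sampled via noisy weights.

    Solved as a maximum-weight clique on the complement graph with integer
    weights ``1000 + eps`` (eps in [0, 10)); the noise never changes the
    cardinality of the optimum but randomizes which optimum is returned.
    """
    if g.number_of_nodes() == 0:
        return frozenset()
    comp = nx.complement(g)
    for node in comp.nodes:
        comp.nodes[node]["weight"] = 1000 + int(rng.integers(10))
    clique, _w = nx.max_weight_clique(comp, weight="weight")
    return frozenset(clique)


def prune_category(
    target,
    conflicting_schemes: list[CategoryScheme],
    twin_sets: dict[str, frozenset],
    universe,
    seed: int = 0,
    min_size: int = 3,
) -> PrunedCategory:
    """Largest constraint-satisfying subsets of a category and its complement.

    Constraints (within the positive set and, separately, the negative
    set): no two objects share a category of any conflicting scheme, and at
    most one object per twin set.  The solution is maximal in cardinality;
    the seeded objective noise samples among the maximal solutions.
    """
    target = frozenset(target)
    universe = frozenset(universe)
    if not target <= universe:
        raise ValueError("target category must lie within the universe")
    rng = np.random.default_rng(seed)
    log: list[str] = []
    pos = _max_independent_set(
        conflict_graph(target, conflicting_schemes, twin_sets), rng
    )
    neg = _max_independent_set(
        conflict_graph(universe - target, conflicting_schemes, twin_sets),
        rng,
    )
    too_small = len(pos) < min_size or len(neg) < min_size
    if too_small:
        log.append(
            f"too few objects for the linear classifier analysis "
            f"(positive {len(pos)}, negative {len(neg)}, min {min_size})"
        )
        logger.warning(log[-1])
    return PrunedCategory(
        positive=pos, negative=neg, too_small=too_small, log=log
    )


def _constrained_sample(
    universe: list,
    size: int,
    conflicting_schemes: list[CategoryScheme],
    twin_sets: dict[str, frozenset],
    rng: np.random.Generator,
    exclude: frozenset = frozenset(),
) -> frozenset | None:
    """Random constraint-satisfying subset of exactly ``size`` objects."""
    g = conflict_graph(
        [o for o in universe if o not in exclude],
        conflicting_schemes, twin_sets,
    )
    order = list(g.nodes)
    rng.shuffle(order)
    chosen: set = set()
    for o in order:
        if len(chosen) == size:
            break
        if not any(g.has_edge(o, c) for c in chosen):
            chosen.add(o)
    return frozenset(chosen) if len(chosen) == size else None


def build_null_pruned(
    conflicting_schemes: list[CategoryScheme],
    twin_sets: dict[str, frozenset],
    pos_size: int,
    neg_size: int,
    universe,
    seed: int = 0,
    max_retries: int = 200,
) -> PrunedCategory:
    """Null categories: twin indices shuffled, then constrained sampling.

    The twin-set structure is randomly re-assigned over the whole object
    set, and disjoint positive / negative sets of the exact requested sizes
    are sampled under the same constraint families as the pruned
    categories.  Retries with fresh shuffles a bounded number of times.
    """
    universe = sorted(universe)
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        perm = rng.permutation(len(universe))
        relabel = {universe[i]: universe[perm[i]] for i in range(len(universe))}
        shuffled_twins = {
            tid: frozenset(relabel[o] for o in s if o in relabel)
            for tid, s in twin_sets.items()
        }
        pos = _constrained_sample(
            universe, pos_size, conflicting_schemes, shuffled_twins, rng
        )
        if pos is None:
            continue
        neg = _constrained_sample(
            universe, neg_size, conflicting_schemes, shuffled_twins, rng,
            exclude=pos,
        )
        if neg is None:
            continue
        return PrunedCategory(positive=pos, negative=neg)
    raise RuntimeError(
        f"could not sample null categories of sizes "
        f"({pos_size}, {neg_size}) in {max_retries} attempts"
    )
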