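"""Population representation space: similarity structure and its analysis.

Mean firing rates per (neuron, object) are z-scored per neuron across the
object set; each object is then a population vector whose pairwise Pearson
correlations define the similarity matrix (dissimilarity d = 1 - r).  On
top of this representation the module provides PCA with property
correlations, average-linkage hierarchical clustering with a top-branch
chi-square test, k-means with BIC/AIC model selection, a k=2
animate-segregation permutation test, and a per-neuron face selectivity
index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .neurogen import ResponseDataset

__all__ = [
    "PopulationMatrix",
    "SimilarityMatrix",
    "normalize_responses",
    "similarity_matrix",
    "pca_property_correlation",
    "hierarchical_branch_test",
    "select_k",
    "animate_segregation_test",
    "face_selectivity_index",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationMatrix:
    """Objects x neurons matrix of per-neuron z-scored mean rates."""

    values: np.ndarray
    object_ids: list
    neuron_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expected a 2-D objects x neurons matrix")

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.object_ids, columns=self.neuron_ids
        )


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson correlation r and dissimilarity d = 1 - r."""

    r: np.ndarray
    object_ids: list

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return 1.0 - self.r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.object_ids,
                            columns=self.object_ids)


def normalize_responses(ds: ResponseDataset) -> PopulationMatrix:
    """Mean rates per (neuron, object), z-scored per neuron (sample SD).

    Neurons with zero across-object variance are non-informative and are
    dropped with a warning.
    """
    if ds.n_objects < 2:
        raise ValueError("need at least 2 objects to normalize")
    rates = ds.mean_rates()  # neurons x objects
    sd = rates.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(ds.neuron_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance neuron(s): {dropped}",
            stacklevel=2,
        )
    rates = rates[keep]
    sd = sd[keep]
    z = (rates - rates.mean(axis=1, keepdims=True)) / sd[:, None]
    return PopulationMatrix(
        values=z.T,
        object_ids=list(ds.object_ids),
        neuron_ids=[n for n, k in zip(ds.neuron_ids, keep) if k],
    )


def similarity_matrix(pm: PopulationMatrix) -> SimilarityMatrix:
    """Pearson correlation between the population vectors of all objects."""
    if pm.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    X = pm.values
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    if degenerate.any():
        logger.warning(
            "%d population vector(s) with zero variance; correlations "
            "flagged nan", int(degenerate.sum()),
        )
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    return SimilarityMatrix(r=r, object_ids=list(pm.object_ids))


def pca_property_correlation(
    pm: PopulationMatrix,
    props: pd.DataFrame,
    n_components: int = 3,
) -> pd.DataFrame:
    """PCA of the population matrix and property-vs-PC-rank correlations.

    For each component and each property column, the Pearson correlation
    between the property value and the rank of the object's score along the
    component is reported (with its t-test p-value), together with the
    component's explained variance ratio.  Component sign follows the SVD
    convention of the PCA solver; both signed r and |r| are returned.
    """
    if n_components > min(pm.n_objects, pm.n_neurons):
        raise ValueError("more components than min(objects, neurons)")
    if pm.n_objects < 2:
        raise ValueError("need at least 2 objects")
    props = props.loc[pm.object_ids]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(pm.values)
    rows = []
    for c in range(n_components):
        rank = stats.rankdata(scores[:, c])
        for prop in props.columns:
            v = props[prop].to_numpy(dtype=float)
            ok = np.isfinite(v)
            r, p = stats.pearsonr(v[ok], rank[ok])
            rows.append({
                "component": c + 1,
                "property": prop,
                "explained_variance_ratio":
                    float(pca.explained_variance_ratio_[c]),
                "r": float(r),
                "abs_r": float(abs(r)),
                "p": float(p),
            })
    return pd.DataFrame(rows)


def _leaf_order_larger_first(Z: np.ndarray, n: int) -> list[int]:
    """Reproducible display order: recurse into the larger branch first."""
    sizes = {}

    def size(node):
        if node < n:
            return 1
        if node not in sizes:
            left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
            sizes[node] = size(left) + size(right)
        return sizes[node]

    out = []

    def walk(node):
        if node < n:
            out.append(node)
            return
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        first, second = (
            (left, right) if size(left) >= size(right) else (right, left)
        )
        walk(first)
        walk(second)

    walk(2 * n - 2)
    return out


def hierarchical_branch_test(
    sm: SimilarityMatrix, labels: dict | pd.Series
) -> dict:
    """Average-linkage tree on d; chi-square test on its first two branches.

    ``labels`` maps object id to a binary label.  Returns the linkage
    matrix, a display leaf order, the root-cut branch assignment, the 2x2
    contingency table and the Pearson chi-square statistic and p-value
    (nan-flagged when the table is degenerate, e.g. a single label class).
    """
    labels = pd.Series(labels).loc[sm.object_ids]
    if labels.isna().any():
        raise ValueError("labels must cover all objects")
    d = sm.d.copy()
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    n = len(sm.object_ids)
    branches = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    table = pd.crosstab(branches, labels.to_numpy())
    if table.shape != (2, 2):
        logger.warning("degenerate branch x label table; chi2 undefined")
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p, _, _ = stats.chi2_contingency(
            table.to_numpy(), correction=False
        )
    return {
        "linkage": Z,
        "leaf_order": [
            sm.object_ids[i] for i in _leaf_order_larger_first(Z, n)
        ],
        "branches": pd.Series(branches, index=sm.object_ids),
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
    }


def to_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist:.6g}"
        left = walk(node.get_left())
        right = walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return f"({walk(tree.get_left())},{walk(tree.get_right())});"


def _gaussian_loglik(X: np.ndarray, labels: np.ndarray,
                     centers: np.ndarray) -> tuple[float, int]:
    """Identical-spherical-variance mixture log-likelihood (X-means style)."""
    n, dim = X.shape
    k = centers.shape[0]
    rss = float(((X - centers[labels]) ** 2).sum())
    if n <= k:
        return -np.inf, k
    var = rss / (dim * (n - k))
    var = max(var, 1e-12)
    ll = 0.0
    for c in range(k):
        n_c = int((labels == c).sum())
        if n_c == 0:
            return -np.inf, k
        ll += n_c * np.log(n_c / n)
    ll -= n * dim / 2.0 * np.log(2.0 * np.pi * var)
    ll -= dim * (n - k) / 2.0
    return ll, k


def select_k(
    pm: PopulationMatrix | np.ndarray,
    k_range=range(1, 31),
    n_restarts: int = 20,
    seed: int = 0,
) -> dict:
    """Choose the k-means cluster count by BIC and AIC.

    For each k the best of ``n_restarts`` seeded k-means fits (by inertia)
    is scored with a shared-spherical-variance Gaussian log-likelihood;
    BIC = -2 logL + p log n and AIC = -2 logL + 2 p with
    p = k * dim + k + 1.
    """
    X = pm.values if isinstance(pm, PopulationMatrix) else np.asarray(pm)
    n, dim = X.shape
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        if not 1 <= k <= n - 1:
            raise ValueError("k_range must lie within [1, n_objects - 1]")
        best = None
        for r in range(n_restarts):
            km = KMeans(n_clusters=k, n_init=1,
                        random_state=int(rng.integers(2**31))).fit(X)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        ll, _ = _gaussian_loglik(X, best.labels_, best.cluster_centers_)
        if not np.isfinite(ll):
            logger.warning("k=%d skipped (degenerate fit)", k)
            continue
        p_free = k * dim + k + 1
        rows.append({
            "k": k,
            "loglik": ll,
            "bic": -2.0 * ll + p_free * np.log(n),
            "aic": -2.0 * ll + 2.0 * p_free,
        })
    table = pd.DataFrame(rows)
    return {
        "k_bic": int(table.loc[table["bic"].idxmin(), "k"]),
        "k_aic": int(table.loc[table["aic"].idxmin(), "k"]),
        "table": table,
    }


def animate_segregation_test(
    pm: PopulationMatrix,
    animate_labels: dict | pd.Series,
    n_runs: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """k=2 segregation of a binary label, against a label-shuffle null.

    The statistic is the mean over ``n_runs`` k-means (k=2) partitions of
    the absolute difference between the fraction of positively-labelled
    objects in the two clusters.  The null shuffles the labels over objects
    and recomputes the same statistic on the same partitions.
    """
    labels = pd.Series(animate_labels).loc[pm.object_ids].astype(bool)
    lab = labels.to_numpy()
    if lab.all() or not lab.any():
        raise ValueError("both label classes must be non-empty")
    rng = np.random.default_rng(seed)
    partitions = []
    attempts = 0
    while len(partitions) < n_runs:
        km = KMeans(n_clusters=2, n_init=1,
                    random_state=int(rng.integers(2**31))).fit(pm.values)
        sizes = np.bincount(km.labels_, minlength=2)
        if (sizes == 0).any():
            attempts += 1
            logger.info("empty k=2 cluster; rerunning (%d)", attempts)
            continue
        partitions.append(km.labels_.copy())
    parts = np.array(partitions)  # runs x objects

    def statistic(lab_vec: np.ndarray) -> float:
        in1 = parts == 1
        n1 = in1.sum(axis=1)
        n0 = (~in1).sum(axis=1)
        f1 = (in1 & lab_vec).sum(axis=1) / n1
        f0 = (~in1 & lab_vec).sum(axis=1) / n0
        return float(np.abs(f1 - f0).mean())

    observed = statistic(lab)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = statistic(rng.permutation(lab))
    p = float((null >= observed).mean())
    return {
        "statistic": observed,
        "null_mean": float(null.mean()),
        "p": p,
        "n_runs": n_runs,
        "n_perm": n_perm,
    }


def face_selectivity_index(
    ds: ResponseDataset, face_ids
) -> pd.Series:
    """Per-neuron (faces - non-faces) / (faces + non-faces) on mean rates."""
    face_ids = set(face_ids)
    is_face = np.array([oid in face_ids for oid in ds.object_ids])
    if not is_face.any() or is_face.all():
        raise ValueError("face and non-face sets must both be non-empty")
    rates = ds.mean_rates()
    mf = rates[:, is_face].mean(axis=1)
    mn = rates[:, ~is_face].mean(axis=1)
    denom = mf + mn
    with np.errstate(invalid="ignore", divide="ignore"):
        fsi = np.where(denom != 0, (mf - mn) / denom, np.nan)
    return pd.Series(fsi, index=ds.neuron_ids, name="fsi")
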