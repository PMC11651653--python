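"""Response-profile clustering of neurons.

Each neuron is summarised by its trial-averaged hit trace followed by its
miss trace (2 x 193 = 386 features), reduced to the first nine principal
components, and clustered with spectral clustering on a nearest-neighbour
affinity graph. The number of neighbours and clusters are chosen by grid
search maximising the mean silhouette score

    s_i = (b_i - a_i) / max(a_i, b_i)

where a_i is the mean distance from sample i to the other members of its
cluster and b_i the mean distance to the nearest other cluster. Cluster
composition (lesioned vs non-lesioned animals) is compared to the overall
population with a two-sided one-proportion Z-test, with display proportions
normalised so a 50/50 split means "same mix as the population".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from scipy.stats import norm
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .signals import OutcomeAverages

log = logging.getLogger(__name__)

__all__ = [
    "build_features",
    "pca_reduce",
    "suggest_elbow",
    "spectral_cluster",
    "silhouette_mean",
    "SilhouetteBreakdown",
    "hyperparameter_search",
    "ClusterModel",
    "composition_test",
]


def build_features(averages: OutcomeAverages | list[OutcomeAverages]) -> np.ndarray:
    """Concatenate per-neuron hit then miss averaged traces into a feature matrix.

    With the default L = 193 this yields 386 columns per neuron. Accepts a
    single :class:`OutcomeAverages` or a list (one per session), which must
    share L.
    """
    if isinstance(averages, OutcomeAverages):
        averages = [averages]
    Ls = {a.L for a in averages}
    if len(Ls) != 1:
        raise ValueError(f"sessions disagree on trace length L: {sorted(Ls)}")
    rows = [np.hstack([a.hit_avg, a.miss_avg]) for a in averages]
    X = np.vstack(rows)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    return X


def pca_reduce(X: np.ndarray, n_components: int = 9) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Column-centred PCA to ``n_components`` dimensions.

    Returns ``(scores, explained_variance_ratio, fitted_pca)``; the variance
    ratios feed the scree plot used to pick the dimensionality.
    """
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(X.shape)}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_, pca


def suggest_elbow(explained_variance_ratio: np.ndarray) -> int:
    """Advisory elbow suggestion: component count at the largest second
    difference of the scree curve (1-based)."""
    evr = np.asarray(explained_variance_ratio, dtype=float)
    if evr.size < 3:
        return evr.size
    second = np.diff(evr, 2)
    return int(np.argmax(second)) + 2


def spectral_cluster(
    scores: np.ndarray, n_neighbors: int, n_clusters: int, seed: int = 0
) -> np.ndarray:
    """Spectral clustering on a symmetrised kNN affinity graph.

    The affinity graph keeps an edge whenever either point is among the
    other's nearest neighbours; the Laplacian embedding is partitioned by
    k-means with a fixed seed. Raises if the graph has more connected
    components than clusters (raise ``n_neighbors`` in that case).
    """
    scores = np.asarray(scores, dtype=float)
    if n_neighbors < 1 or n_clusters < 2:
        raise ValueError("need n_neighbors >= 1 and n_clusters >= 2")
    conn = kneighbors_graph(scores, n_neighbors=min(n_neighbors, scores.shape[0] - 1))
    n_comp, _ = connected_components(conn.maximum(conn.T), directed=False)
    if n_comp > n_clusters:
        raise ValueError(
            f"kNN graph has {n_comp} components for {n_clusters} clusters; raise n_neighbors"
        )
    model = SpectralClustering(
        n_clusters=n_clusters,
        affinity="nearest_neighbors",
        n_neighbors=n_neighbors,
        assign_labels="kmeans",
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not fully connected.*")
        return model.fit_predict(scores)


@dataclass
class SilhouetteBreakdown:
    """Per-sample silhouette ingredients: intra (a), nearest-other (b), s."""

    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    labels: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.s.mean())


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> tuple[float, SilhouetteBreakdown]:
    """Mean silhouette score with the full per-sample breakdown.

    Euclidean distances in the given (typically PCA-score) space. For a
    sample in a singleton cluster, a_i is undefined and s_i is set to 0 by
    convention.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    D = squareform(pdist(X))
    n = X.shape[0]
    a = np.zeros(n)
    b = np.full(n, np.inf)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    for c in uniq:
        in_c = labels == c
        for i in np.flatnonzero(in_c):
            if sizes[c] > 1:
                a[i] = D[i, in_c].sum() / (sizes[c] - 1)
        for cj in uniq:
            if cj == c:
                continue
            mean_to_cj = D[np.ix_(in_c, labels == cj)].mean(axis=1)
            b[in_c] = np.minimum(b[in_c], mean_to_cj)
    s = np.zeros(n)
    for i in range(n):
        if sizes[labels[i]] > 1:
            denom = max(a[i], b[i])
            s[i] = (b[i] - a[i]) / denom if denom > 0 else 0.0
    br = SilhouetteBreakdown(a=a, b=b, s=s, labels=labels.copy())
    return br.mean, br


@dataclass
class ClusterModel:
    """Fitted response-profile clustering: PCA basis + spectral labels."""

    labels: np.ndarray
    n_clusters: int
    n_neighbors: int
    mean_silhouette: float
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    grid: pd.DataFrame  # n_neighbors, n_clusters, mean_silhouette (NaN where failed)
    n_components: int = 9
    seed: int = 0

    def labels_frame(self, session_ids=None, groups=None) -> pd.DataFrame:
        out = pd.DataFrame({"neuron_id": np.arange(self.labels.size), "cluster_id": self.labels})
        if session_ids is not None:
            out["session_id"] = np.asarray(session_ids)
        if groups is not None:
            out["group"] = np.asarray(groups)
        return out


def hyperparameter_search(
    X: np.ndarray,
    n_neighbors_grid=(5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    n_clusters_grid=tuple(range(2, 16)),
    n_components: int = 9,
    seed: int = 0,
    silhouette_space: str = "scores",
) -> ClusterModel:
    """Grid search over (n_neighbors, n_clusters) maximising mean silhouette.

    Features are PCA-reduced to ``n_components`` first; silhouettes are
    computed in the same score space the clustering sees (configurable to
    the raw feature space via ``silhouette_space='features'``). Ties break
    to fewer clusters, then fewer neighbours. Grid cells that fail (e.g. a
    disconnected graph) are recorded as NaN; if every cell fails an error
    is raised.
    """
    X = np.asarray(X, dtype=float)
    n_components = min(n_components, min(X.shape))
    scores, evr, _ = pca_reduce(X, n_components=n_components)
    space = scores if silhouette_space == "scores" else X

    rows = []
    best = None
    for k in sorted(n_clusters_grid):
        for nn in sorted(n_neighbors_grid):
            try:
                labels = spectral_cluster(scores, n_neighbors=nn, n_clusters=k, seed=seed)
                if np.unique(labels).size < 2:
                    raise ValueError("degenerate single-cluster labelling")
                ms, _ = silhouette_mean(space, labels)
            except ValueError as e:
                log.debug("grid cell (nn=%d, k=%d) failed: %s", nn, k, e)
                rows.append({"n_neighbors": nn, "n_clusters": k, "mean_silhouette": np.nan})
                continue
            rows.append({"n_neighbors": nn, "n_clusters": k, "mean_silhouette": ms})
            # strict > : earlier (fewer clusters, then fewer neighbours) wins ties
            if best is None or ms > best[0]:
                best = (ms, k, nn, labels)
    grid = pd.DataFrame(rows)
    if best is None:
        raise ValueError("every grid cell failed (graph disconnected?); raise n_neighbors")
    ms, k, nn, labels = best
    return ClusterModel(
        labels=labels,
        n_clusters=k,
        n_neighbors=nn,
        mean_silhouette=ms,
        scores=scores,
        explained_variance_ratio=evr,
        grid=grid,
        n_components=n_components,
        seed=seed,
    )


def composition_test(labels: np.ndarray, lesioned: np.ndarray) -> pd.DataFrame:
    """Per-cluster lesioned/non-lesioned composition vs the population.

    For each cluster the observed lesioned proportion is tested against the
    population proportion with a two-sided one-proportion Z-test, and a
    normalised display proportion is reported: the lesioned share each
    cluster would show if both groups had equal overall size, so 0.5 means
    the cluster mirrors the population mix.
    """
    labels = np.asarray(labels)
    lesioned = np.asarray(lesioned, dtype=bool)
    p_pop = lesioned.mean()
    if p_pop in (0.0, 1.0):
        raise ValueError("both groups must be present in the population")
    rows = []
    for c in np.unique(labels):
        in_c = labels == c
        n = int(in_c.sum())
        if n == 0:
            log.info("composition_test: empty cluster %s skipped", c)
            continue
        x = int(lesioned[in_c].sum())
        p_hat = x / n
        se = np.sqrt(p_pop * (1 - p_pop) / n)
        z = (p_hat - p_pop) / se
        p = 2 * norm.sf(abs(z))
        if p_hat in (0.0, 1.0):
            norm_prop = p_hat
        else:
            ratio = (p_hat / p_pop) / (p_hat / p_pop + (1 - p_hat) / (1 - p_pop))
            norm_prop = ratio
        rows.append(
            {
                "cluster_id": c,
                "n": n,
                "n_lesioned": x,
                "prop_lesioned": p_hat,
                "normalized_prop": norm_prop,
                "z": float(z),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
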