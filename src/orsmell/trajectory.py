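"""Embedding, graph clustering and geodesic pseudotime.

Pseudotime here is deliberately simple: a k-nearest-neighbor graph is
built on a PCA embedding of standardized log2(TPM+1), communities come from
greedy modularity maximization, the root cluster is the one with maximal
mean stemness (the biologically least differentiated population), and
pseudotime is the shortest-path (Dijkstra) distance from the root cluster's
medoid, rescaled to [0, 1].  The downstream claims depend only on an
ordering rooted at maximal stemness, which this construction provides with
far less machinery than principal-graph methods; cells disconnected from the
root get NaN pseudotime and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import cdist, squareform, pdist
from sklearn.decomposition import PCA

from ._stats import CorrelationResult, shapiro_gated_correlation
from .errors import ValidationError
from .io_catalog import ExpressionMatrix
from .repertoire import RepertoireProfile


@dataclass
class TrajectoryResult:
    sample_ids: list[str]
    embedding: np.ndarray          # cells x n_pcs
    clusters: np.ndarray           # integer labels
    root_cluster: int | None = None
    root_cell: int | None = None
    pseudotime: np.ndarray | None = None   # NaN where unreachable
    correlations: pd.DataFrame | None = None


def _knn_graph(embedding: np.ndarray, k_nn: int) -> scipy.sparse.csr_matrix:
    """Symmetrized kNN adjacency with Euclidean edge weights.

    An edge exists when either endpoint lists the other among its k nearest
    neighbors (union symmetrization).  Requiring mutuality instead shatters
    noisy continuous clouds into dozens of tiny components, which makes
    rooted geodesics useless; union keeps those traversable while leaving
    genuinely separated populations disconnected.
    """
    n = embedding.shape[0]
    dist = cdist(embedding, embedding)
    np.fill_diagonal(dist, np.inf)
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k_nn]
    is_nbr = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_nn)
    is_nbr[rows, nn.ravel()] = True
    keep = is_nbr | is_nbr.T
    weights = np.where(keep, dist, 0.0)
    return scipy.sparse.csr_matrix(weights)


def embed_and_cluster(
    matrix: ExpressionMatrix,
    n_pcs: int = 30,
    k_nn: int = 15,
    seed: int = 0,
    resolution: float = 2.0,
) -> TrajectoryResult:
    """PCA embedding plus graph-community clustering.

    log2(TPM+1) values are standardized per gene (zero-variance genes are
    dropped), reduced with full-SVD PCA for determinism, and clustered by
    greedy modularity maximization on the mutual kNN graph.  Cluster ids are
    renumbered by each community's smallest member index, so labels are
    stable under reruns.  A disconnected graph is allowed (components are
    clustered independently) but flagged with a warning.
    """
    if matrix.n_samples <= n_pcs:
        raise ValidationError("need more cells than principal components")
    x = matrix.log2_tpm1().values.T  # cells x genes
    sd = x.std(axis=0)
    # floor guards float fuzz: np.std of a constant column can be ~1e-16,
    # and standardizing by it would blow the column up to pure noise
    keep = sd > 1e-12
    if not keep.any():
        raise ValidationError("all genes have zero variance; nothing to embed")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_pcs_eff = min(n_pcs, x.shape[1])
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    embedding = pca.fit_transform(x)

    adj = _knn_graph(embedding, k_nn)
    graph = nx.from_scipy_sparse_array(adj)
    n_comp = nx.number_connected_components(graph)
    if n_comp > 1:
        warnings.warn(
            f"mutual kNN graph has {n_comp} connected components; "
            "they are clustered independently",
            stacklevel=2,
        )
    communities = nx.algorithms.community.greedy_modularity_communities(
        graph, weight=None, resolution=resolution
    )
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels = np.empty(matrix.n_samples, dtype=int)
    for cid, members in enumerate(communities):
        labels[list(members)] = cid
    return TrajectoryResult(list(matrix.sample_ids), embedding, labels)


def select_root(
    result: TrajectoryResult, stemness: np.ndarray
) -> TrajectoryResult:
    """Pick the root cluster (max mean stemness) and its embedding medoid.

    Exact ties between cluster means go to the smaller cluster id, with a
    warning.
    """
    stemness = np.asarray(stemness, dtype=float)
    if len(stemness) != len(result.sample_ids):
        raise ValidationError("stemness vector does not match cells")
    ids = np.unique(result.clusters)
    means = np.array([stemness[result.clusters == c].mean() for c in ids])
    best = means.max()
    winners = ids[means == best]
    if len(winners) > 1:
        warnings.warn(
            f"stemness tie between clusters {list(winners)}; taking the smallest id",
            stacklevel=2,
        )
    root_cluster = int(winners.min())
    members = np.nonzero(result.clusters == root_cluster)[0]
    sub = result.embedding[members]
    total = squareform(pdist(sub)).sum(axis=1) if len(members) > 1 else np.zeros(1)
    root_cell = int(members[int(np.argmin(total))])  # argmin is index-order stable
    result.root_cluster = root_cluster
    result.root_cell = root_cell
    return result


def compute_pseudotime(
    result: TrajectoryResult, k_nn: int = 15
) -> TrajectoryResult:
    """Geodesic pseudotime from the root cell, rescaled to [0, 1].

    Cells unreachable from the root keep NaN and a warning is emitted.
    """
    if result.root_cell is None:
        raise ValidationError("select_root must run before compute_pseudotime")
    adj = _knn_graph(result.embedding, k_nn)
    dist = dijkstra(adj, directed=False, indices=result.root_cell)
    unreachable = ~np.isfinite(dist)
    if unreachable.any():
        warnings.warn(
            f"{int(unreachable.sum())} cells unreachable from the root; "
            "their pseudotime is undefined",
            stacklevel=2,
        )
    finite_max = np.nanmax(np.where(unreachable, np.nan, dist))
    pt = np.where(unreachable, np.nan, dist / finite_max if finite_max > 0 else dist)
    result.pseudotime = pt
    return result


def pseudotime_correlations(
    result: TrajectoryResult,
    stemness: np.ndarray,
    profile: RepertoireProfile,
) -> pd.DataFrame:
    """Correlate pseudotime with stemness, OR count and mean OR expression.

    Rows: (pseudotime, stemness), (pseudotime, or_count),
    (pseudotime, mean_or_expression), (stemness, or_count); each is
    Shapiro-Wilk gated Pearson/Spearman over cells with defined pseudotime.
    Zero-variance pairs are flagged rather than raising.
    """
    if result.pseudotime is None:
        raise ValidationError("pseudotime has not been computed")
    pt = result.pseudotime
    ok = np.isfinite(pt)
    if int(ok.sum()) < 10:
        raise ValidationError("need at least 10 cells with defined pseudotime")
    stemness = np.asarray(stemness, dtype=float)
    pairs = [
        ("pseudotime", pt[ok], "stemness", stemness[ok]),
        ("pseudotime", pt[ok], "or_count", profile.or_count[ok].astype(float)),
        ("pseudotime", pt[ok], "mean_or_expression", profile.mean_or_expression[ok]),
        ("stemness", stemness[ok], "or_count", profile.or_count[ok].astype(float)),
    ]
    rows = []
    for name_x, x, name_y, y in pairs:
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"x": name_x, "y": name_y, "r": np.nan, "p": np.nan,
                         "test_used": "skipped_zero_variance"})
            continue
        res: CorrelationResult = shapiro_gated_correlation(x, y)
        rows.append({"x": name_x, "y": name_y, "r": res.r, "p": res.p,
                     "test_used": res.test_used})
    table = pd.DataFrame(rows, columns=["x", "y", "r", "p", "test_used"])
    result.correlations = table
    return table
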