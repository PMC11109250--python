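"""Region-level correspondence and clustering-parameter selection.

Tools for the spatial side of the analysis: the (unadjusted) Rand index
between cluster and anatomical-region partitions of the same spots,
region pseudobulk profiles that let the cross-species cell-type machinery
run on anatomical regions, integer post-processing of deconvolution
abundance estimates, and bootstrap co-clustering silhouette selection of
clustering parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import sklearn.metrics

from .core_data import ExpressionDataset
from .markers import log_normalize

__all__ = [
    "ClusterEvaluation",
    "rand_index",
    "adjusted_rand_index",
    "region_pseudobulk",
    "pseudobulk_dataset",
    "abundance_postprocess",
    "graph_cluster",
    "cluster_param_select",
]


def _check_partitions(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("partitions must be 1-d and of equal length")
    if pd.isna(x).any() or pd.isna(y).any():
        raise ValueError("partitions must not contain missing labels")
    return x, y


def rand_index(labels_x, labels_y) -> float:
    """Unadjusted Rand index: the fraction of item pairs on which two
    partitions agree (co-clustered in both or separated in both)."""
    x, y = _check_partitions(labels_x, labels_y)
    return float(sklearn.metrics.rand_score(x, y))


def adjusted_rand_index(labels_x, labels_y) -> float:
    """Chance-corrected variant of the Rand index."""
    x, y = _check_partitions(labels_x, labels_y)
    return float(sklearn.metrics.adjusted_rand_score(x, y))


def region_pseudobulk(ds: ExpressionDataset) -> pd.DataFrame:
    """Sum counts over spots per region: a regions x genes matrix.

    Downstream, regions play the role of cell-types so the correlation and
    kNN mapping pipelines apply unchanged (see :func:`pseudobulk_dataset`).
    Spots without a region label are excluded with a warning.
    """
    if ds.region is None:
        raise ValueError("dataset has no region labels")
    labeled = ~pd.isna(ds.region)
    if not labeled.all():
        warnings.warn(f"excluding {(~labeled).sum()} unlabeled spots", stacklevel=2)
    regions = sorted(set(map(str, ds.region[labeled])))
    out = np.zeros((len(regions), ds.n_genes), dtype=np.int64)
    for i, r in enumerate(regions):
        cols = np.flatnonzero(labeled & (ds.region == r))
        out[i] = np.asarray(ds.counts[:, cols].sum(axis=1)).ravel()
    return pd.DataFrame(out, index=regions, columns=ds.gene_ids)


def pseudobulk_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    """Region pseudobulk repackaged as a dataset with one 'cell' per region."""
    pb = region_pseudobulk(ds)
    return ExpressionDataset(
        species_tag=f"{ds.species_tag}_regions",
        gene_ids=list(pb.columns),
        cell_ids=list(pb.index),
        counts=sp.csr_matrix(pb.to_numpy().T),
        cell_type=np.array(pb.index, dtype=object),
    )


def abundance_postprocess(
    A: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Round deconvolution abundances; empty spots get one cell at the argmax type.

    Entries are rounded half-to-even; any spot whose row rounds to all
    zeros is assigned a single cell of its pre-rounding most-abundant type
    (first type if the raw row is all-zero too, with a warning).  Returns
    the integer matrix and spot summaries: mean cells/spot, mean distinct
    types/spot, fraction of spots with more than one type.
    """
    raw = A.to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError("abundances must be non-negative")
    rounded = np.rint(raw).astype(np.int64)
    empty = np.flatnonzero(rounded.sum(axis=1) == 0)
    for i in empty:
        if raw[i].max() <= 0:
            warnings.warn(
                f"spot {A.index[i]!r} has all-zero abundances; assigned to first type",
                stacklevel=2,
            )
            rounded[i, 0] = 1
        else:
            rounded[i, int(np.argmax(raw[i]))] = 1
    types_per_spot = (rounded > 0).sum(axis=1)
    summaries = {
        "mean_cells_per_spot": float(rounded.sum(axis=1).mean()),
        "mean_types_per_spot": float(types_per_spot.mean()),
        "frac_spots_multi_type": float((types_per_spot > 1).mean()),
    }
    return pd.DataFrame(rounded, index=A.index, columns=A.columns), summaries


# ---------------------------------------------------------------------------
# clustering-parameter selection by bootstrap co-clustering silhouettes
# ---------------------------------------------------------------------------

@dataclass
class ClusterEvaluation:
    """Robustness metrics for one (n_neighbors, resolution) combination."""

    n_neighbors: int
    resolution: float
    n_clusters: int
    cluster_silhouettes: dict[int, float]  # per full-data cluster; NaN = singleton
    median_silhouette: float
    ci_low: float  # 2.5% bootstrap quantile of the median


def _pca(dense: np.ndarray, n_dims: int) -> np.ndarray:
    X = dense - dense.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    d = min(n_dims, S.size)
    return U[:, :d] * S[:d]


def graph_cluster(
    dense_lognorm: np.ndarray,
    n_neighbors: int,
    resolution: float,
    seed: int,
    n_pcs: int = 30,
) -> np.ndarray:
    """kNN-graph modularity clustering of cells in principal-component space.

    Builds an exact symmetrized kNN graph over the top principal
    components and partitions it with the Leiden algorithm under the
    resolution-scaled modularity objective.  ``dense_lognorm`` is
    cells x genes log-normalized expression.
    """
    import igraph
    import leidenalg

    coords = _pca(dense_lognorm, n_pcs)
    n = coords.shape[0]
    kk = min(n_neighbors, n - 1)
    sq = (coords**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :kk]
    edges = {(min(i, int(j)), max(i, int(j))) for i in range(n) for j in order[i]}
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def _coclustering_silhouettes(
    full_labels: np.ndarray,
    boot_samples: list[tuple[np.ndarray, np.ndarray]],
) -> dict[int, float]:
    """Per-cluster silhouette on the 1 - co-clustering-frequency dissimilarity.

    Frequencies are computed over bootstraps in which both cells of a pair
    were sampled; pairs never co-sampled get frequency 0.  Each cluster's
    score is the median silhouette width of its cells; singleton clusters
    are recorded as NaN.
    """
    n = full_labels.size
    both = np.zeros((n, n))
    same = np.zeros((n, n))
    for idx, labs in boot_samples:
        sampled = np.zeros(n, dtype=bool)
        sampled[idx] = True
        lab_full = np.full(n, -1)
        lab_full[idx] = labs
        pair_sampled = np.outer(sampled, sampled)
        both += pair_sampled
        eq = lab_full[:, None] == lab_full[None, :]
        same += pair_sampled & eq
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(both > 0, same / np.maximum(both, 1), 0.0)
    np.fill_diagonal(freq, 1.0)
    dissim = 1.0 - freq

    clusters = np.unique(full_labels)
    if clusters.size < 2:
        return {int(c): float("nan") for c in clusters}
    widths = sklearn.metrics.silhouette_samples(dissim, full_labels, metric="precomputed")
    out = {}
    for c in clusters:
        members = full_labels == c
        out[int(c)] = (
            float(np.median(widths[members])) if members.sum() > 1 else float("nan")
        )
    return out


def cluster_param_select(
    ds: ExpressionDataset,
    grid: list[tuple[int, float]],
    n_boot: int = 100,
    subsample: float = 0.8,
    seed: int = 0,
    n_pcs: int = 30,
) -> tuple[list[ClusterEvaluation], tuple[int, float]]:
    """Choose clustering parameters by bootstrap co-clustering robustness.

    For each ``(n_neighbors, resolution)`` combination the full data are
    clustered, then ``n_boot`` bootstraps each cluster an ``subsample``
    fraction of the cells identically (PCA recomputed per bootstrap, so
    bootstraps are fully independent).  Cell-pair co-clustering
    frequencies over the bootstraps define a dissimilarity ``1 - freq``
    from which per-cluster silhouette scores are computed.  Selection: let
    ``T`` be the highest lower 95% confidence bound (2.5% bootstrap
    quantile of the median silhouette) across combinations; the chosen
    combination maximizes the number of clusters whose silhouette exceeds
    ``T`` (ties: fewest clusters, then grid order).
    """
    if n_boot < 10:
        raise ValueError("n_boot must be >= 10")
    if not 0.0 < subsample < 1.0:
        raise ValueError("subsample must lie strictly between 0 and 1")
    dense = np.asarray(log_normalize(ds).todense()).T  # cells x genes
    n = dense.shape[0]
    rng = np.random.default_rng(seed)
    evals: list[ClusterEvaluation] = []
    for n_neighbors, resolution in grid:
        full = graph_cluster(dense, n_neighbors, resolution, seed=seed, n_pcs=n_pcs)
        boots = []
        for b in range(n_boot):
            idx = np.sort(
                rng.choice(n, size=max(2, int(round(subsample * n))), replace=False)
            )
            labs = graph_cluster(
                dense[idx], n_neighbors, resolution, seed=seed + b + 1, n_pcs=n_pcs
            )
            boots.append((idx, labs))
        per_cluster = _coclustering_silhouettes(full, boots)
        scores = np.array([v for v in per_cluster.values() if np.isfinite(v)])
        if scores.size:
            median = float(np.median(scores))
            boot_medians = np.median(
                rng.choice(scores, size=(1000, scores.size), replace=True), axis=1
            )
            ci_low = float(np.quantile(boot_medians, 0.025))
        else:
            median = float("nan")
            ci_low = float("nan")
        evals.append(
            ClusterEvaluation(
                n_neighbors=n_neighbors,
                resolution=resolution,
                n_clusters=int(np.unique(full).size),
                cluster_silhouettes=per_cluster,
                median_silhouette=median,
                ci_low=ci_low,
            )
        )
    finite = [e.ci_low for e in evals if np.isfinite(e.ci_low)]
    threshold = max(finite) if finite else float("-inf")
    best = max(
        range(len(evals)),
        key=lambda i: (
            sum(
                1
                for v in evals[i].cluster_silhouettes.values()
                if np.isfinite(v) and v > threshold
            ),
            -evals[i].n_clusters,
            -i,
        ),
    )
    chosen = (evals[best].n_neighbors, evals[best].resolution)
    return evals, chosen
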