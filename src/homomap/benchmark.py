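"""Downsampling self-comparison benchmark for cross-species mapping methods.

A dataset is compared against a degraded copy of itself: 10% of each
cell's UMIs are removed (exact multivariate-hypergeometric thinning) and a
few cell-types are dropped entirely so the comparison is not one-to-one.
Because the true correspondence is known, each method's score matrix can
be compared to the identity indicator (1 where the downsampled and
original cell-type labels match, 0 elsewhere) by squared Pearson
correlation: a method is better the closer its R^2 is to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import ExpressionDataset
from .correlation_map import (
    combine_significance,
    correlate_profiles,
    shared_deg_space,
)
from .knn_map import build_knn, joint_embed, similarity_scores
from .markers import average_expression, find_markers, normalize_profile
from .orthology import ResolvedMap

__all__ = [
    "BenchmarkResult",
    "downsample_umis",
    "drop_random_types",
    "evaluate_method",
    "correlation_method",
    "knn_method",
    "BUILTIN_METHODS",
]

MappingMethod = Callable[
    [ExpressionDataset, ExpressionDataset, ResolvedMap], pd.DataFrame
]


@dataclass
class BenchmarkResult:
    """Per-method identity-recovery score for the self-comparison protocol."""

    method_name: str
    r_squared: float  # NaN when the score matrix is constant
    score_matrix: pd.DataFrame  # downsampled types x original types
    removed_types: list[str]


def downsample_umis(
    ds: ExpressionDataset, fraction: float, seed: int
) -> ExpressionDataset:
    """Remove exactly ``round(fraction * total)`` UMIs from each cell.

    Removal is uniform over the cell's individual UMIs (a multivariate
    hypergeometric draw over genes), with half-to-even rounding of the
    removal count.  The gene set is unchanged.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    csc = sp.csc_matrix(ds.counts)
    out = csc.copy()
    for c in range(ds.n_cells):
        start, end = csc.indptr[c], csc.indptr[c + 1]
        col = csc.data[start:end].astype(np.int64)
        total = int(col.sum())
        n_keep = total - round(fraction * total)
        if n_keep == total:
            continue
        kept = rng.multivariate_hypergeometric(col, n_keep, method="marginals")
        out.data[start:end] = kept
    out.eliminate_zeros()
    from dataclasses import replace

    return replace(ds, counts=sp.csr_matrix(out))


def drop_random_types(
    ds: ExpressionDataset, n_drop: int, seed: int
) -> tuple[ExpressionDataset, list[str]]:
    """Remove all cells of ``n_drop`` uniformly chosen cell-types."""
    types = sorted(set(map(str, ds.cell_type)))
    if n_drop >= len(types):
        raise ValueError(f"cannot drop {n_drop} of {len(types)} types")
    if n_drop == 0:
        return ds, []
    rng = np.random.default_rng(seed)
    removed = sorted(rng.choice(types, size=n_drop, replace=False))
    keep = np.flatnonzero(~np.isin(ds.cell_type.astype(str), removed))
    return ds.subset_cells(keep), list(removed)


def evaluate_method(
    method: MappingMethod,
    original: ExpressionDataset,
    fraction: float = 0.1,
    n_drop: int = 3,
    seed: int = 0,
    method_name: str = "method",
) -> BenchmarkResult:
    """Score a mapping method by self-comparison against the identity matrix.

    Builds the degraded dataset (UMI thinning, then type removal), runs
    ``method(downsampled, original, identity_map)`` to obtain a
    downsampled-types x original-types score matrix, and returns the
    squared Pearson correlation between the flattened scores and the
    flattened identity indicator.  A constant score matrix yields NaN.
    """
    from dataclasses import replace

    down = downsample_umis(original, fraction, seed)
    down, removed = drop_random_types(down, n_drop, seed)
    # distinct species tag so graph-based methods see two datasets
    down = replace(down, species_tag=f"{original.species_tag}_down")
    identity_map = ResolvedMap.identity(list(original.gene_ids))
    scores = method(down, original, identity_map)

    ident = np.array(
        [[1.0 if r == c else 0.0 for c in scores.columns] for r in scores.index]
    )
    flat = scores.to_numpy().ravel()
    if np.ptp(flat) == 0 or np.ptp(ident) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(flat, ident.ravel())[0, 1] ** 2)
    return BenchmarkResult(
        method_name=method_name,
        r_squared=r2,
        score_matrix=scores,
        removed_types=removed,
    )


# ---------------------------------------------------------------------------
# built-in methods, adapted to the (ds_a, ds_b, map) -> score matrix contract
# ---------------------------------------------------------------------------

def correlation_method(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    mapping: ResolvedMap,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Shared-DEG Spearman mapping; returns the rho matrix (a-types x b-types)."""
    ma = find_markers(ds_a)
    mb = find_markers(ds_b)
    pairs = shared_deg_space(ma, mb, mapping)
    pa = normalize_profile(average_expression(ds_a))
    pb = normalize_profile(average_expression(ds_b))
    rho, _ = correlate_profiles(pa, pb, pairs)
    return rho


def knn_method(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    mapping: ResolvedMap,
    k: int = 20,
    n_dims: int = 30,
) -> pd.DataFrame:
    """Joint-embedding kNN mapping; returns the similarity score matrix."""
    emb = joint_embed(ds_a, ds_b, mapping, n_dims=n_dims)
    graph = build_knn(emb, k=k)
    return similarity_scores(graph, emb.labels)


BUILTIN_METHODS: dict[str, MappingMethod] = {
    "corr": correlation_method,
    "knn": knn_method,
}
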