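"""Normalization, one-vs-rest marker detection, and expression profiles.

Marker genes (DEGs) are detected per group with a two-sided Wilcoxon
rank-sum test (normal approximation with tie and continuity correction)
on log-normalized expression, Bonferroni-corrected over all genes x groups
tested.  Group average-expression profiles are normalized as
``log(x + 1) + 0.1`` followed by division by each gene's mean across
groups, which makes profiles comparable across species before rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .core_data import ExpressionDataset
from .orthology import ResolvedMap

__all__ = [
    "MarkerSet",
    "DEFAULT_THRESHOLDS",
    "CONSERVED_THRESHOLDS",
    "log_normalize",
    "find_markers",
    "average_expression",
    "normalize_profile",
    "conserved_markers",
    "shared_marker_fraction",
]

# (max adjusted p, min log2 fold change, min fraction expressing)
DEFAULT_THRESHOLDS = (0.05, 0.25, 0.1)
# relaxed thresholds used when intersecting markers across many species
CONSERVED_THRESHOLDS = (0.05, 0.0, 0.1)
_EPS = 1e-9


@dataclass
class MarkerSet:
    """Per-(group, gene) differential expression statistics.

    ``table`` columns: group, gene, log2_fc, pct_in, pct_out, p_raw, p_adj,
    is_marker.  Only rows passing the configured thresholds are flagged.
    """

    table: pd.DataFrame
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS

    def markers_of(self, group: str) -> pd.DataFrame:
        sub = self.table[(self.table["group"] == group) & self.table["is_marker"]]
        if sub.empty and group not in set(self.table["group"]):
            raise KeyError(f"unknown group {group!r}")
        return sub

    def marker_genes(self, group: str) -> list[str]:
        return list(self.markers_of(group)["gene"])

    def all_marker_genes(self) -> set[str]:
        return set(self.table.loc[self.table["is_marker"], "gene"])


def log_normalize(ds: ExpressionDataset, scale_total: float = 10_000.0):
    """Scale each cell to ``scale_total`` counts, then log1p.

    Returns a sparse genes x cells matrix; all-zero cells stay all-zero.
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = ds.cell_totals().astype(float)
    scale = np.divide(scale_total, totals, out=np.zeros_like(totals), where=totals > 0)
    mat = sp.csr_matrix(ds.counts, dtype=float)
    mat = mat @ sp.diags(scale)
    mat.data = np.log1p(mat.data)
    return sp.csr_matrix(mat)


def _rank_matrix(dense: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mid-ranks across cells plus the rank-sum tie correction term."""
    ranks = scipy.stats.rankdata(dense, axis=1)
    n = dense.shape[1]
    tie_term = np.zeros(dense.shape[0])
    for g in range(dense.shape[0]):
        _, counts = np.unique(dense[g], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie_term[g] = np.sum(t**3 - t)
    return ranks, tie_term


def find_markers(
    ds: ExpressionDataset,
    grouping: str = "cell_type",
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    positive_only: bool = True,
    min_cells: int = 3,
) -> MarkerSet:
    """One-vs-rest Wilcoxon marker detection per group.

    For each group, genes expressed in at least ``min_pct`` of either the
    in-group or out-group cells are tested with a two-sided rank-sum test
    on log-normalized expression.  ``log2_fc`` compares in/out means of
    de-logged normalized values.  p-values are Bonferroni-corrected over
    every (gene, group) test performed.
    """
    labels = _group_labels(ds, grouping)
    groups = sorted(set(map(str, labels)))
    if len(groups) < 2:
        raise ValueError("find_markers needs at least two groups")
    p_max, fc_min, min_pct = thresholds

    lognorm = log_normalize(ds)
    dense = np.asarray(lognorm.todense())
    expressed = np.asarray((ds.counts > 0).todense())
    delogged = np.expm1(dense)

    n = ds.n_cells
    ranks, tie_term = _rank_matrix(dense)
    rows = []
    for group in groups:
        in_mask = labels == group
        n1 = int(in_mask.sum())
        n2 = n - n1
        if n1 < min_cells or n2 < min_cells:
            continue
        pct_in = expressed[:, in_mask].mean(axis=1)
        pct_out = expressed[:, ~in_mask].mean(axis=1)
        testable = (pct_in >= min_pct) | (pct_out >= min_pct)

        w = ranks[:, in_mask].sum(axis=1)
        mu = n1 * (n + 1) / 2.0
        var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
        z = np.where(var > 0, z, 0.0)
        p_raw = 2.0 * scipy.stats.norm.sf(np.abs(z))
        p_raw = np.minimum(p_raw, 1.0)

        mean_in = delogged[:, in_mask].mean(axis=1)
        mean_out = delogged[:, ~in_mask].mean(axis=1)
        log2_fc = np.log2((mean_in + _EPS) / (mean_out + _EPS))

        idx = np.flatnonzero(testable)
        rows.append(
            pd.DataFrame(
                {
                    "group": group,
                    "gene": [ds.gene_ids[i] for i in idx],
                    "log2_fc": log2_fc[idx],
                    "pct_in": pct_in[idx],
                    "pct_out": pct_out[idx],
                    "p_raw": p_raw[idx],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    n_tests = len(table)
    table["p_adj"] = np.minimum(1.0, table["p_raw"] * n_tests)
    table["is_marker"] = (
        (table["p_adj"] < p_max)
        & (table["log2_fc"] > fc_min)
        & (np.maximum(table["pct_in"], table["pct_out"]) > min_pct)
    )
    if positive_only:
        table["is_marker"] &= table["log2_fc"] > 0
    return MarkerSet(table=table, thresholds=thresholds)


def _group_labels(ds: ExpressionDataset, grouping: str) -> np.ndarray:
    if grouping == "cell_type":
        return np.asarray(ds.cell_type, dtype=object)
    if grouping == "region":
        if ds.region is None:
            raise ValueError("dataset has no region labels")
        return np.asarray(ds.region, dtype=object)
    raise ValueError(f"unknown grouping {grouping!r}")


def average_expression(ds: ExpressionDataset, grouping: str = "cell_type") -> pd.DataFrame:
    """Per-group mean of library-size-normalized (linear-scale) expression.

    Returns a groups x genes DataFrame.  Empty groups cannot occur (labels
    define the groups); all-zero cells contribute zero vectors.
    """
    labels = _group_labels(ds, grouping)
    totals = ds.cell_totals().astype(float)
    scale = np.divide(10_000.0, totals, out=np.zeros_like(totals), where=totals > 0)
    norm = ds.counts @ sp.diags(scale)
    groups = sorted(set(map(str, labels)))
    out = np.zeros((len(groups), ds.n_genes))
    for i, g in enumerate(groups):
        cols = np.flatnonzero(labels == g)
        out[i] = np.asarray(norm[:, cols].mean(axis=1)).ravel()
    return pd.DataFrame(out, index=groups, columns=ds.gene_ids)


def normalize_profile(avg: pd.DataFrame) -> pd.DataFrame:
    """``log(x + 1) + 0.1`` then divide each gene column by its mean over groups.

    Natural log.  An all-zero gene column becomes the constant 0.1 and so
    maps to all-ones: correlation-neutral.  After scaling, every gene
    column's mean over groups equals 1.
    """
    if (avg.to_numpy() < 0).any():
        raise ValueError("average expression must be non-negative")
    y = np.log(avg.to_numpy() + 1.0) + 0.1
    return pd.DataFrame(
        y / y.mean(axis=0, keepdims=True), index=avg.index, columns=avg.columns
    )


def _as_lut(mapping: "ResolvedMap | dict[str, str] | None") -> dict[str, str] | None:
    """Accept a resolved one-to-one map or a plain (possibly many-to-one) dict."""
    if mapping is None:
        return None
    if isinstance(mapping, dict):
        return mapping
    return mapping.to_dict()


def _best_per_symbol(
    markers: MarkerSet,
    group: str,
    mapping: "ResolvedMap | dict[str, str] | None",
    thresholds: tuple[float, float, float],
) -> tuple[dict[str, pd.Series], dict[str, pd.Series]]:
    """Per human symbol, the group's best-FC marker row and best-FC upregulated row."""
    sub = markers.table[markers.table["group"] == group]
    if sub.empty:
        raise KeyError(f"unknown group {group!r}")
    lut = _as_lut(mapping)
    p_max, fc_min, min_pct = thresholds
    strict: dict[str, pd.Series] = {}
    up: dict[str, pd.Series] = {}
    for _, row in sub.iterrows():
        symbol = lut.get(row["gene"]) if lut is not None else row["gene"]
        if symbol is None:
            continue
        if row["log2_fc"] > 0 and (
            symbol not in up or row["log2_fc"] > up[symbol]["log2_fc"]
        ):
            up[symbol] = row
        ok = (
            row["p_adj"] < p_max
            and row["log2_fc"] > fc_min
            and row["pct_in"] > min_pct
        )
        if ok and (symbol not in strict or row["log2_fc"] > strict[symbol]["log2_fc"]):
            strict[symbol] = row
    return strict, up


def conserved_markers(
    marker_sets: list[MarkerSet],
    maps: "list[ResolvedMap | dict[str, str] | None]",
    group_tuple: tuple[str, ...],
    relaxed: bool = False,
    thresholds: tuple[float, float, float] = CONSERVED_THRESHOLDS,
) -> list[str]:
    """Human symbols up-regulated as markers of one group in every species.

    Per species, marker genes of the named group are translated to human
    symbols (``None`` in ``maps`` means the species' gene ids already are
    human symbols; a plain dict may be many-to-one, since several query
    genes can legitimately share one human ortholog here); when several
    genes share a symbol, the gene with the
    greatest log2 fold change represents it.  The strict list intersects
    full marker calls (adjusted p < 0.05, log2FC > 0, expressed in >10% of
    cells) across species; ``relaxed`` adds symbols up-regulated
    (log2FC > 0) in all species but failing full criteria in at least one.
    """
    if not (len(marker_sets) == len(maps) == len(group_tuple)):
        raise ValueError("need one marker set, map, and group per species")
    strict_sets, up_sets = [], []
    for ms, mp, grp in zip(marker_sets, maps, group_tuple):
        strict, up = _best_per_symbol(ms, grp, mp, thresholds)
        strict_sets.append(set(strict))
        up_sets.append(set(up))
    conserved = set.intersection(*strict_sets)
    if relaxed:
        conserved |= set.intersection(*up_sets)
    return sorted(conserved)


def shared_marker_fraction(
    pair: tuple[str, str],
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    mapping: ResolvedMap | None,
) -> float:
    """Fraction of group_a's markers whose ortholog is a marker of group_b.

    Directional (a -> b).  Returns NaN when group_a has no markers.
    """
    group_a, group_b = pair
    genes_a = markers_a.marker_genes(group_a)
    if not genes_a:
        return float("nan")
    lut = _as_lut(mapping)
    symbols_a = [lut.get(g) for g in genes_a] if lut else list(genes_a)
    genes_b = set(markers_b.marker_genes(group_b))
    return sum(1 for s in symbols_a if s is not None and s in genes_b) / len(genes_a)
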