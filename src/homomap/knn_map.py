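"""Graph-based cross-species cell-type similarity.

The two species are embedded in a joint principal-component space over
shared ortholog features, an exact Euclidean kNN graph is built over the
union of cells, and each cross-species cell-type pair is scored by the
mean number of k-nearest neighbors its cells contribute to each other.
Significance is a label-permutation test: a pair whose observed score
exceeds all permuted scores (q_perm = 0) is significant, and reciprocal
top hits mark pairs that are each other's best partner.

The joint embedding is a plain PCA over jointly log-normalized,
standardized shared-ortholog features (optionally weighted per gene
pair); an externally computed cross-species graph can be imported from a
TSV edge list and scored identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import ExpressionDataset
from .correlation_map import shared_deg_space
from .markers import MarkerSet
from .orthology import ResolvedMap

__all__ = [
    "CrossSpeciesGraph",
    "JointEmbedding",
    "joint_embed",
    "build_knn",
    "similarity_scores",
    "score_permutation_test",
    "reciprocal_top_hits",
    "driving_genes",
    "read_graph_tsv",
    "write_graph_tsv",
]

DEFAULT_K = 20


@dataclass
class CrossSpeciesGraph:
    """kNN neighbor lists over the union of two datasets' cells.

    ``neighbors[i]`` holds exactly ``k`` node indices (no self-edges);
    ``species[i]`` tags each node with its dataset of origin.
    """

    node_ids: list[str]
    species: np.ndarray
    neighbors: np.ndarray
    k: int

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        if self.neighbors.shape != (n, self.k):
            raise ValueError("neighbors must be (n_nodes, k)")
        if self.neighbors.min(initial=0) < 0 or self.neighbors.max(initial=-1) >= n:
            raise ValueError("neighbor index out of range")
        if (self.neighbors == np.arange(n)[:, None]).any():
            raise ValueError("self-edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class JointEmbedding:
    """Per-cell coordinates of both species in the shared feature space."""

    coords: np.ndarray
    species: np.ndarray
    node_ids: list[str]
    labels: np.ndarray


def joint_embed(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    mapping: ResolvedMap | None,
    weights: dict[tuple[str, str], float] | None = None,
    n_dims: int = 30,
    scale_total: float = 10_000.0,
) -> JointEmbedding:
    """Project both species into a joint PCA space over shared orthologs.

    Species-a genes are translated through ``mapping`` into species-b's
    namespace (``None`` when they already share one).  Cells of both
    species are jointly library-size log-normalized, features standardized
    (and optionally scaled by per-pair ``weights``), and projected onto the
    top ``n_dims`` principal axes by a full SVD with a fixed sign
    convention (the largest-magnitude loading of each axis is positive),
    so the embedding is deterministic given input order.
    """
    lut = mapping.to_dict() if mapping is not None else {g: g for g in ds_a.gene_ids}
    pos_b = {g: i for i, g in enumerate(ds_b.gene_ids)}
    pairs = [
        (g, lut[g]) for g in ds_a.gene_ids if g in lut and lut[g] in pos_b
    ]
    if len(pairs) < n_dims:
        raise ValueError(f"only {len(pairs)} shared ortholog pairs for n_dims={n_dims}")
    pos_a = {g: i for i, g in enumerate(ds_a.gene_ids)}
    ia = [pos_a[p[0]] for p in pairs]
    ib = [pos_b[p[1]] for p in pairs]

    def norm_cells(ds: ExpressionDataset, rows: list[int]) -> np.ndarray:
        totals = ds.cell_totals().astype(float)
        scale = np.divide(
            scale_total, totals, out=np.zeros_like(totals), where=totals > 0
        )
        mat = ds.counts[rows, :] @ sp.diags(scale)
        return np.log1p(np.asarray(mat.todense())).T  # cells x features

    X = np.vstack([norm_cells(ds_a, ia), norm_cells(ds_b, ib)])
    X -= X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    X = np.divide(X, sd, out=np.zeros_like(X), where=sd > 0)
    if weights is not None:
        w = np.array([float(weights.get(p, 0.0)) for p in pairs])
        if not (w > 0).any():
            raise ValueError("all feature weights are zero: degenerate feature space")
        X = X * w[None, :]

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    d = min(n_dims, S.size)
    for c in range(d):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            U[:, c] = -U[:, c]
            Vt[c] = -Vt[c]
    coords = U[:, :d] * S[:d]

    species = np.array(
        [ds_a.species_tag] * ds_a.n_cells + [ds_b.species_tag] * ds_b.n_cells,
        dtype=object,
    )
    node_ids = [f"{ds_a.species_tag}:{c}" for c in ds_a.cell_ids] + [
        f"{ds_b.species_tag}:{c}" for c in ds_b.cell_ids
    ]
    labels = np.concatenate([ds_a.cell_type, ds_b.cell_type])
    return JointEmbedding(coords=coords, species=species, node_ids=node_ids, labels=labels)


def build_knn(emb: JointEmbedding, k: int = DEFAULT_K) -> CrossSpeciesGraph:
    """Exact Euclidean kNN over the union of both species' cells.

    Distance ties are broken by node index order; self-edges excluded.
    """
    n = emb.coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be below n={n}")
    sq = (emb.coords**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (emb.coords @ emb.coords.T)
    np.fill_diagonal(d2, np.inf)
    # stable argsort on distance breaks ties by index order
    order = np.argsort(d2, axis=1, kind="stable")
    return CrossSpeciesGraph(
        node_ids=emb.node_ids,
        species=emb.species,
        neighbors=order[:, :k],
        k=k,
    )


def _species_split(g: CrossSpeciesGraph) -> tuple[str, str, np.ndarray]:
    tags = list(dict.fromkeys(g.species))
    if len(tags) != 2:
        raise ValueError(f"graph must contain exactly two species, got {tags}")
    return tags[0], tags[1], np.asarray(g.species == tags[0])


def similarity_scores(
    g: CrossSpeciesGraph,
    labels: np.ndarray,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Mean number of cross-species k-nearest neighbors per cell-type pair.

    ``S(a, b)`` sums, over cells of type ``a`` (first species), their
    neighbors in type ``b`` of the second species and vice versa, divided
    by ``|a| + |b|``.  Within-species neighbors are never counted.  With
    ``symmetric=False`` only neighbors of first-species cells are counted
    and the denominator is ``|a|``.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != g.n_nodes:
        raise ValueError("labels must cover every node")
    tag_a, tag_b, is_a = _species_split(g)
    types_a = sorted(set(map(str, labels[is_a])))
    types_b = sorted(set(map(str, labels[~is_a])))
    code_a = {t: i for i, t in enumerate(types_a)}
    code_b = {t: i for i, t in enumerate(types_b)}
    codes_a = np.array([code_a.get(str(t), -1) for t in labels])
    codes_b = np.array([code_b.get(str(t), -1) for t in labels])

    src = np.repeat(np.arange(g.n_nodes), g.k)
    dst = g.neighbors.ravel()
    M_ab = np.zeros((len(types_a), len(types_b)))
    mask = is_a[src] & ~is_a[dst]
    np.add.at(M_ab, (codes_a[src[mask]], codes_b[dst[mask]]), 1)
    M_ba = np.zeros_like(M_ab)
    mask = ~is_a[src] & is_a[dst]
    np.add.at(M_ba, (codes_a[dst[mask]], codes_b[src[mask]]), 1)

    n_a = np.array([(labels[is_a] == t).sum() for t in types_a], dtype=float)
    n_b = np.array([(labels[~is_a] == t).sum() for t in types_b], dtype=float)
    if symmetric:
        S = (M_ab + M_ba) / (n_a[:, None] + n_b[None, :])
    else:
        S = M_ab / n_a[:, None]
    return pd.DataFrame(S, index=types_a, columns=types_b)


def score_permutation_test(
    g: CrossSpeciesGraph,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    symmetric: bool = True,
    null: str = "per-pair",
) -> pd.DataFrame:
    """Fraction of label permutations whose score meets or exceeds the observed.

    Labels are permuted independently within each species with the graph
    fixed.  ``null="per-pair"`` compares each pair to its own permuted
    distribution; ``null="pooled-row"`` compares each observed score to the
    permuted row maxima of its first-species type.  A pair is significant
    when ``q_perm = 0``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if null not in ("per-pair", "pooled-row"):
        raise ValueError(f"unknown null mode {null!r}")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    obs = similarity_scores(g, labels, symmetric=symmetric)
    S_obs = obs.to_numpy()
    exceed = np.zeros_like(S_obs)
    idx_a = np.flatnonzero(g.species == g.species[0])
    idx_b = np.flatnonzero(g.species != g.species[0])
    for _ in range(n_perm):
        perm = labels.copy()
        perm[idx_a] = perm[idx_a[rng.permutation(idx_a.size)]]
        perm[idx_b] = perm[idx_b[rng.permutation(idx_b.size)]]
        S_perm = similarity_scores(g, perm, symmetric=symmetric).to_numpy()
        if null == "per-pair":
            exceed += S_perm >= S_obs
        else:
            exceed += S_perm.max(axis=1, keepdims=True) >= S_obs
    return pd.DataFrame(exceed / n_perm, index=obs.index, columns=obs.columns)


def reciprocal_top_hits(S: pd.DataFrame) -> pd.DataFrame:
    """Flag pairs that are each other's unique best-scoring partner.

    A pair is flagged only when it is the strict argmax of both its row
    and its column; ties yield no flag.
    """
    if S.size == 0:
        raise ValueError("empty score matrix")
    M = S.to_numpy()
    flags = np.zeros(M.shape, dtype=bool)
    for i in range(M.shape[0]):
        row = M[i]
        j = int(np.argmax(row))
        if (row == row[j]).sum() > 1:
            continue
        col = M[:, j]
        if (col == col.max()).sum() > 1:
            continue
        if int(np.argmax(col)) == i:
            flags[i, j] = True
    return pd.DataFrame(flags, index=S.index, columns=S.columns)


def driving_genes(
    pair: tuple[str, str],
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    mapping: ResolvedMap | None,
) -> list[tuple[str, str, float]]:
    """Ortholog pairs driving a cell-type pair's cross-species correlation.

    Over the shared DEG space, a gene pair qualifies when the species-a
    gene is a marker of ``type_a``, the species-b gene a marker of
    ``type_b``, and its rank-product contribution to the pair's Spearman
    rho is positive: ``(rank_a - mean_rank) * (rank_b - mean_rank) > 0``.
    All qualifying pairs are returned, sorted by decreasing contribution.
    """
    import scipy.stats

    type_a, type_b = pair
    pairs = shared_deg_space(markers_a, markers_b, mapping)
    if not pairs:
        raise ValueError("empty shared DEG space")
    genes_a = [p[0] for p in pairs]
    genes_b = [p[1] for p in pairs]
    va = profile_a.loc[type_a, genes_a].to_numpy(dtype=float)
    vb = profile_b.loc[type_b, genes_b].to_numpy(dtype=float)
    ra = scipy.stats.rankdata(va)
    rb = scipy.stats.rankdata(vb)
    contrib = (ra - ra.mean()) * (rb - rb.mean())

    deg_a = set(markers_a.marker_genes(type_a))
    deg_b = set(markers_b.marker_genes(type_b))
    out = [
        (ga, gb, float(c))
        for ga, gb, c in zip(genes_a, genes_b, contrib)
        if c > 0 and ga in deg_a and gb in deg_b
    ]
    return sorted(out, key=lambda t: (-t[2], t[0]))


# ---------------------------------------------------------------------------
# graph interchange (TSV edge list: source_id, target_id, rank)
# ---------------------------------------------------------------------------

def write_graph_tsv(g: CrossSpeciesGraph, path: str | Path) -> None:
    rows = []
    for i, neigh in enumerate(g.neighbors):
        for rank, j in enumerate(neigh, start=1):
            rows.append((g.node_ids[i], g.node_ids[int(j)], rank))
    pd.DataFrame(rows, columns=["source_id", "target_id", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_graph_tsv(path: str | Path, species_of: dict[str, str]) -> CrossSpeciesGraph:
    """Import an externally computed kNN graph from a TSV edge list.

    ``species_of`` maps node ids to species tags so externally integrated
    graphs can be scored exactly like internally built ones.
    """
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    node_ids = list(dict.fromkeys(df["source_id"]))
    extra = [t for t in dict.fromkeys(df["target_id"]) if t not in set(node_ids)]
    node_ids += extra
    pos = {nid: i for i, nid in enumerate(node_ids)}
    per_node: dict[int, list[tuple[int, int]]] = {}
    for s, t, r in zip(df["source_id"], df["target_id"], df["rank"]):
        per_node.setdefault(pos[s], []).append((int(r), pos[t]))
    ks = {len(v) for v in per_node.values()}
    if len(ks) != 1:
        raise ValueError("every source node must have the same number of neighbors")
    if len(per_node) != len(node_ids):
        warnings.warn("some nodes have no outgoing edges; they are dropped", stacklevel=2)
        node_ids = [nid for nid in node_ids if pos[nid] in per_node]
        return read_graph_tsv_from_frame(df[df["source_id"].isin(node_ids)], species_of)
    k = ks.pop()
    neighbors = np.empty((len(node_ids), k), dtype=np.int64)
    for i, edges in per_node.items():
        neighbors[i] = [j for _, j in sorted(edges)]
    species = np.array([species_of[nid] for nid in node_ids], dtype=object)
    return CrossSpeciesGraph(node_ids=node_ids, species=species, neighbors=neighbors, k=k)


def read_graph_tsv_from_frame(
    df: pd.DataFrame, species_of: dict[str, str]
) -> CrossSpeciesGraph:  # pragma: no cover - thin recursion helper
    import io

    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_graph_tsv(buf, species_of)
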