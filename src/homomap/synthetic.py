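"""Synthetic two-species data with known cell-type homology.

The generators emulate the statistical structure that cross-species
cell-type comparison assumes: two species whose cell-types share a subset
of expression programs, linked through a noisy, partially duplicated
ortholog map; a bipartite cross-species kNN graph with controllable
within-homolog preference; and a toy spatial grid whose spots are count
mixtures of several cells.

Model sketch
------------
Ancestral per-gene baseline means are log-normal.  Each cell-type
up-regulates its own marker block by ``2**log2_effect``.  Species B reuses
species A's programs for the first ``n_shared`` types through the true
one-to-one ortholog map, with an independent log-normal perturbation per
(type, gene), so "homologous" has a crisp ground truth.  UMI counts are
negative-binomial (gamma-Poisson) around per-cell log-normal library
sizes.  A fraction of species-A genes carries a second, lowly-expressed
co-ortholog (teleost-style retained duplicate) whose annotation sources
are patchier, which is what makes one-to-one resolution non-trivial.

All generators are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import ExpressionDataset
from .knn_map import CrossSpeciesGraph
from .orthology import SOURCE_COLUMNS, OrthologTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_species_pair",
    "simulate_ortholog_table",
    "simulate_bipartite_knn",
    "simulate_spatial_grid",
]

# expression level of a retained duplicate relative to its primary copy;
# small enough that the UMI tie-break deterministically favors the primary
_DUPLICATE_BASELINE_FACTOR = 0.05
# per-(type, gene) log-normal sigma applied when species B reuses a program
_PROGRAM_NOISE_SIGMA = 0.25
# species-level log-normal sigma on baseline means
_BASELINE_SIGMA = 1.0
_SPECIES_BASELINE_NOISE = 0.2
_MEAN_LIBRARY_SIZE = 3000.0


@dataclass
class SimulationConfig:
    """Study conditions for the paired-species simulation.

    Defaults are the conditions every downstream default test runs under:
    10 types per species of which 7 are shared, 100 cells per type, 40
    markers per type at 4-fold (log2 effect 2) up-regulation, moderate
    negative-binomial overdispersion, and 30% duplicated ortholog entries.
    """

    n_genes: int = 2000
    n_types_a: int = 10
    n_types_b: int = 10
    n_shared: int = 7
    cells_per_type: int = 100
    markers_per_type: int = 40
    log2_effect: float = 2.0
    dispersion: float = 10.0
    library_size_cv: float = 0.3
    dup_fraction: float = 0.3
    source_noise: float = 0.05
    paralog_annotation_dropout: float = 0.3
    grid_side: int = 30
    n_regions: int = 4
    cells_per_spot_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_types_a, self.n_types_b):
            raise ValueError("n_shared exceeds the number of types")
        for name in ("n_genes", "n_types_a", "n_types_b", "cells_per_type",
                     "markers_per_type", "grid_side", "n_regions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("dup_fraction", "source_noise", "paralog_annotation_dropout"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        needed = (self.n_types_a + self.n_types_b - self.n_shared) * self.markers_per_type
        if needed > self.n_genes:
            raise ValueError(
                f"{needed} marker genes needed but only n_genes={self.n_genes} available"
            )


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    homolog_pairs: list[tuple[str, str]]
    true_ortholog_map: dict[str, str]  # primary species-A gene -> human symbol
    true_markers: dict[tuple[str, str], set[str]]  # (species_tag, type) -> genes
    a_gene_symbol: dict[str, str] = field(default_factory=dict)  # incl. duplicates
    umi_totals: dict[str, int] = field(default_factory=dict)  # per species-A gene
    region_composition: dict[str, dict[str, float]] | None = None
    # configured expected counts per cell (genes x types, at the mean library
    # size), keyed by species tag -- the quantity empirical means converge to
    expected_means: dict[str, pd.DataFrame] = field(default_factory=dict)


def _library_sizes(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.full(n, _MEAN_LIBRARY_SIZE)
    sigma2 = np.log1p(cv**2)
    mu = np.log(_MEAN_LIBRARY_SIZE) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _sample_counts(
    rng: np.random.Generator,
    mean_per_type: np.ndarray,  # genes x types, relative expression
    type_codes: np.ndarray,
    libsizes: np.ndarray,
    dispersion: float,
) -> sp.csr_matrix:
    """Gamma-Poisson counts with per-cell library sizes; Poisson at dispersion=inf."""
    probs = mean_per_type / mean_per_type.sum(axis=0, keepdims=True)
    n_genes = probs.shape[0]
    out = np.empty((n_genes, type_codes.size), dtype=np.int64)
    for t in np.unique(type_codes):
        cols = np.flatnonzero(type_codes == t)
        mu = probs[:, t][:, None] * libsizes[cols][None, :]
        if np.isfinite(dispersion):
            lam = rng.gamma(dispersion, mu / dispersion)
        else:
            lam = mu
        out[:, cols] = rng.poisson(lam)
    return sp.csr_matrix(out)


def simulate_species_pair(
    cfg: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Generate paired species datasets with known homologous cell-types.

    Species B gene ids are the shared human symbols; species A gene ids are
    query-species names (with duplicates suffixed ``.p2``), so the resolved
    ortholog map translates A into B's namespace.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    symbols = [f"HUM{j:05d}" for j in range(G)]
    primary_a = [f"ga{j:05d}" for j in range(G)]
    baseline = rng.lognormal(0.0, _BASELINE_SIGMA, size=G)

    # assign disjoint marker blocks: A types first, then B-only types
    order = rng.permutation(G)
    types_a = [f"A{t}" for t in range(cfg.n_types_a)]
    types_b = [f"B{t}" for t in range(cfg.n_types_b)]
    blocks_a = {
        types_a[t]: order[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type]
        for t in range(cfg.n_types_a)
    }
    off = cfg.n_types_a * cfg.markers_per_type
    blocks_b: dict[str, np.ndarray] = {}
    for i, t in enumerate(range(cfg.n_shared, cfg.n_types_b)):
        blocks_b[types_b[t]] = order[
            off + i * cfg.markers_per_type : off + (i + 1) * cfg.markers_per_type
        ]
    for t in range(cfg.n_shared):
        blocks_b[types_b[t]] = blocks_a[types_a[t]]

    effect = 2.0**cfg.log2_effect
    fold_a = np.ones((G, cfg.n_types_a))
    for t, tb in enumerate(types_a):
        fold_a[blocks_a[tb], t] = effect
    fold_b = np.ones((G, cfg.n_types_b))
    for t, tb in enumerate(types_b):
        fold_b[blocks_b[tb], t] = effect
        if t < cfg.n_shared and cfg.log2_effect != 0:
            fold_b[blocks_b[tb], t] *= rng.lognormal(
                0.0, _PROGRAM_NOISE_SIGMA, size=len(blocks_b[tb])
            )

    baseline_b = baseline * rng.lognormal(0.0, _SPECIES_BASELINE_NOISE, size=G)

    # species A duplicates: lowly expressed second co-ortholog, no program
    is_dup = rng.random(G) < cfg.dup_fraction
    dup_idx = np.flatnonzero(is_dup)
    dup_names = [f"{primary_a[j]}.p2" for j in dup_idx]
    genes_a = primary_a + dup_names
    mean_a = np.vstack(
        [
            baseline[:, None] * fold_a,
            (_DUPLICATE_BASELINE_FACTOR * baseline[dup_idx])[:, None]
            * np.ones((dup_idx.size, cfg.n_types_a)),
        ]
    )
    mean_b = baseline_b[:, None] * fold_b

    def build(tag, genes, mean, types, n_types):
        codes = np.repeat(np.arange(n_types), cfg.cells_per_type)
        libs = _library_sizes(rng, codes.size, cfg.library_size_cv)
        counts = _sample_counts(rng, mean, codes, libs, cfg.dispersion)
        return ExpressionDataset(
            species_tag=tag,
            gene_ids=genes,
            cell_ids=[f"{tag}_c{i:05d}" for i in range(codes.size)],
            counts=counts,
            cell_type=np.array([types[c] for c in codes], dtype=object),
        )

    ds_a = build("a", genes_a, mean_a, types_a, cfg.n_types_a)
    ds_b = build("b", list(symbols), mean_b, types_b, cfg.n_types_b)

    truth = GroundTruth(
        homolog_pairs=[(types_a[t], types_b[t]) for t in range(cfg.n_shared)],
        true_ortholog_map={primary_a[j]: symbols[j] for j in range(G)},
        true_markers={
            **{
                ("a", tb): {primary_a[j] for j in blocks_a[tb]} for tb in types_a
            },
            **{("b", tb): {symbols[j] for j in blocks_b[tb]} for tb in types_b},
        },
        a_gene_symbol={
            **{primary_a[j]: symbols[j] for j in range(G)},
            **{f"{primary_a[j]}.p2": symbols[j] for j in dup_idx},
        },
        umi_totals=dict(
            zip(genes_a, np.asarray(ds_a.counts.sum(axis=1)).ravel().astype(int))
        ),
        expected_means={
            "a": pd.DataFrame(
                mean_a / mean_a.sum(axis=0, keepdims=True) * _MEAN_LIBRARY_SIZE,
                index=genes_a,
                columns=types_a,
            ),
            "b": pd.DataFrame(
                mean_b / mean_b.sum(axis=0, keepdims=True) * _MEAN_LIBRARY_SIZE,
                index=list(symbols),
                columns=types_b,
            ),
        },
    )
    return ds_a, ds_b, truth


def simulate_ortholog_table(cfg: SimulationConfig, truth: GroundTruth) -> OrthologTable:
    """Emit a five-source candidate table with noisy, partially duplicated rows.

    Every species-A gene (primary and duplicate) claims its true human
    symbol in all five sources; duplicate rows first lose each source with
    probability ``paralog_annotation_dropout`` (patchy paralog annotation),
    then every source field is independently corrupted (blanked or
    mislabeled, half/half) with probability ``source_noise``.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    symbols = sorted(set(truth.a_gene_symbol.values()))
    rows = []
    for gene in sorted(truth.a_gene_symbol):
        symbol = truth.a_gene_symbol[gene]
        is_dup = gene not in truth.true_ortholog_map
        row: dict[str, object] = {"query_gene": gene}
        for col in SOURCE_COLUMNS:
            value: str | None = symbol
            if is_dup and rng.random() < cfg.paralog_annotation_dropout:
                value = None
            if value is not None and rng.random() < cfg.source_noise:
                if rng.random() < 0.5:
                    value = None
                else:
                    value = symbols[int(rng.integers(len(symbols)))]
            row[col] = value
        row["umi_total"] = int(truth.umi_totals.get(gene, 0))
        rows.append(row)
    return OrthologTable(pd.DataFrame(rows))


def simulate_bipartite_knn(
    n_a: int,
    n_b: int,
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    k: int,
    within_type_bias: float,
    seed: int,
) -> tuple[CrossSpeciesGraph, np.ndarray]:
    """Planted bipartite kNN graph: every neighbor is a cross-species cell.

    Each of a cell's ``k`` distinct neighbors is drawn from its homologous
    partner type (the same label in the other species) with probability
    ``within_type_bias``, else uniformly from the other species.  Returns
    the graph and the node label array (A labels then B labels).
    """
    labels_a = np.asarray(labels_a, dtype=object)
    labels_b = np.asarray(labels_b, dtype=object)
    if len(labels_a) != n_a or len(labels_b) != n_b:
        raise ValueError("label arrays must match n_a / n_b")
    # neighbors are strictly cross-species, so each side bounds the other's k
    if k < 1 or k > min(n_a, n_b):
        raise ValueError(f"k={k} impossible for a bipartite graph on {n_a}+{n_b} cells")
    rng = np.random.default_rng(seed)

    by_label_a = {lab: np.flatnonzero(labels_a == lab) for lab in set(labels_a)}
    by_label_b = {lab: np.flatnonzero(labels_b == lab) + n_a for lab in set(labels_b)}
    all_a = np.arange(n_a)
    all_b = np.arange(n_a, n_a + n_b)

    neighbors = np.empty((n_a + n_b, k), dtype=np.int64)
    for i in range(n_a + n_b):
        if i < n_a:
            partner = by_label_b.get(labels_a[i], np.empty(0, dtype=int))
            pool = all_b
        else:
            partner = by_label_a.get(labels_b[i - n_a], np.empty(0, dtype=int))
            pool = all_a
        picks: list[int] = []
        for _ in range(k):
            src = partner if (rng.random() < within_type_bias and partner.size) else pool
            avail = src[~np.isin(src, picks)] if picks else src
            if avail.size == 0:  # partner type exhausted, fall back to the pool
                avail = pool[~np.isin(pool, picks)]
            picks.append(int(avail[rng.integers(avail.size)]))
        neighbors[i] = picks

    node_ids = [f"a:{i}" for i in range(n_a)] + [f"b:{j}" for j in range(n_b)]
    species = np.array(["a"] * n_a + ["b"] * n_b, dtype=object)
    graph = CrossSpeciesGraph(node_ids=node_ids, species=species, neighbors=neighbors, k=k)
    labels = np.concatenate([labels_a, labels_b])
    return graph, labels


def simulate_spatial_grid(
    cfg: SimulationConfig,
    reference: ExpressionDataset,
    region_composition: dict[str, dict[str, float]] | None = None,
) -> ExpressionDataset:
    """Toy spatial slide: grid spots summing counts of a few reference cells.

    The ``grid_side x grid_side`` grid is split into ``n_regions`` contiguous
    column bands; each region draws a Dirichlet mixture over the reference
    cell-types (unless ``region_composition`` supplies explicit weights).
    Each spot receives ``Poisson(cells_per_spot_mean)`` cells sampled from
    its region's mixture and sums their raw counts.  The returned dataset
    carries region labels (also used as ``cell_type``), integer grid
    coordinates, and the true spots x types abundance in
    ``true_abundance``.
    """
    side = cfg.grid_side
    if cfg.n_regions > side * side:
        raise ValueError("more regions than spots")
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    types = sorted(set(map(str, reference.cell_type)))
    cells_by_type = {
        t: np.flatnonzero(reference.cell_type == t) for t in types
    }
    regions = [f"R{r}" for r in range(cfg.n_regions)]

    if region_composition is None:
        region_composition = {
            r: dict(zip(types, rng.dirichlet(np.full(len(types), 2.0))))
            for r in regions
        }
    comp = {
        r: np.array([region_composition[r].get(t, 0.0) for t in types])
        for r in regions
    }
    for r in regions:
        total = comp[r].sum()
        if total <= 0:
            raise ValueError(f"region {r} has empty composition")
        comp[r] = comp[r] / total

    # contiguous column bands
    bounds = np.linspace(0, side, cfg.n_regions + 1).astype(int)
    col_region = np.empty(side, dtype=int)
    for r in range(cfg.n_regions):
        col_region[bounds[r] : bounds[r + 1]] = r

    counts_csc = sp.csc_matrix(reference.counts)
    spot_ids, spot_region, coords, abundance, spot_cols = [], [], [], [], []
    for row in range(side):
        for col in range(side):
            r = regions[col_region[col]]
            n_cells = int(rng.poisson(cfg.cells_per_spot_mean))
            tallies = np.zeros(len(types), dtype=int)
            picked = []
            if n_cells > 0:
                drawn = rng.choice(len(types), size=n_cells, p=comp[r])
                for t_idx in drawn:
                    members = cells_by_type[types[t_idx]]
                    picked.append(int(members[rng.integers(members.size)]))
                    tallies[t_idx] += 1
            if picked:
                vec = np.asarray(counts_csc[:, picked].sum(axis=1)).ravel()
            else:
                vec = np.zeros(reference.n_genes, dtype=int)
            spot_cols.append(vec)
            spot_ids.append(f"spot_{row:03d}_{col:03d}")
            spot_region.append(r)
            coords.append((row, col))
            abundance.append(tallies)

    ds = ExpressionDataset(
        species_tag=f"{reference.species_tag}_spots",
        gene_ids=list(reference.gene_ids),
        cell_ids=spot_ids,
        counts=sp.csr_matrix(np.column_stack(spot_cols)),
        cell_type=np.array(spot_region, dtype=object),
        region=np.array(spot_region, dtype=object),
        spot_coords=np.array(coords, dtype=int),
        true_abundance=pd.DataFrame(abundance, index=spot_ids, columns=types),
    )
    ds.true_abundance.attrs["region_composition"] = region_composition
    return ds
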