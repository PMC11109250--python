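"""Cross-species cell-type mapping by Spearman correlation of shared DEGs.

Cell-type (or region) profiles from the two species are restricted to
ortholog pairs that are differentially expressed in both, rank-correlated,
and called significant only when both a one-sided correlation test and a
gene-wise permutation test survive Bonferroni correction over all
cell-type pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .markers import MarkerSet
from .orthology import ResolvedMap

__all__ = [
    "CorrelationResult",
    "shared_deg_space",
    "correlate_profiles",
    "correlation_permutation_test",
    "combine_significance",
]

MIN_SHARED_GENES = 5


@dataclass
class CorrelationResult:
    """Pairwise rho with dual Bonferroni-adjusted significance.

    All frames are groups_a x groups_b; ``significant`` requires both
    adjusted p-values below alpha.
    """

    rho: pd.DataFrame
    p_cor_adj: pd.DataFrame
    p_perm_adj: pd.DataFrame
    significant: pd.DataFrame
    n_shared_degs: int


def shared_deg_space(
    markers_a: MarkerSet,
    markers_b: MarkerSet,
    mapping: ResolvedMap | None,
) -> list[tuple[str, str]]:
    """Ortholog pairs that are markers of at least one group in each species.

    ``mapping`` translates species-a gene ids to species-b's namespace
    (``None`` if both already share one).  Returned pairs ``(gene_a,
    gene_b)`` are sorted by ``gene_b`` for determinism.
    """
    degs_a = markers_a.all_marker_genes()
    degs_b = markers_b.all_marker_genes()
    lut = mapping.to_dict() if mapping is not None else {g: g for g in degs_a}
    pairs = [
        (g, lut[g]) for g in degs_a if g in lut and lut[g] in degs_b
    ]
    return sorted(pairs, key=lambda p: (p[1], p[0]))


def _restrict(profile: pd.DataFrame, genes: list[str]) -> np.ndarray:
    missing = [g for g in genes if g not in profile.columns]
    if missing:
        raise ValueError(f"profile lacks genes: {missing[:5]}")
    return profile[genes].to_numpy()


def _rho_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between every row of ``a`` and every row of ``b``."""
    ra = scipy.stats.rankdata(a, axis=1)
    rb = scipy.stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra**2).sum(axis=1))
    nb = np.sqrt((rb**2).sum(axis=1))
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra @ rb.T) / denom
    return np.where(denom > 0, rho, 0.0)


def correlate_profiles(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and one-sided (greater) p per group pair over shared DEGs.

    Profiles are normalized groups x genes matrices; ``pairs`` aligns
    species-a gene columns with species-b gene columns.  The p-value uses
    the t approximation with ``n_genes - 2`` degrees of freedom.
    """
    if len(pairs) < MIN_SHARED_GENES:
        raise ValueError(f"need >= {MIN_SHARED_GENES} shared DEGs, got {len(pairs)}")
    a = _restrict(profile_a, [p[0] for p in pairs])
    b = _restrict(profile_b, [p[1] for p in pairs])
    rho = _rho_matrix(a, b)
    n = len(pairs)
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    t = np.where(np.abs(r) < 1.0, t, np.inf * np.sign(r))
    p = scipy.stats.t.sf(t, df=n - 2)
    idx, cols = profile_a.index, profile_b.index
    return (
        pd.DataFrame(rho, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def correlation_permutation_test(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    smoothing: bool = False,
) -> pd.DataFrame:
    """Permutation p-values by shuffling species-a values across groups.

    Each permutation independently shuffles every gene column of the
    species-a profile across its groups and recomputes the rho matrix;
    ``p = #(perm rho > observed rho) / n_perm`` (strict inequality, so the
    minimum attainable p is 0).  ``smoothing`` switches to the
    ``(count + 1)/(n_perm + 1)`` variant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    a = _restrict(profile_a, [p[0] for p in pairs])
    b = _restrict(profile_b, [p[1] for p in pairs])
    obs = _rho_matrix(a, b)
    exceed = np.zeros_like(obs)
    n_groups = a.shape[0]
    for _ in range(n_perm):
        perm = a.copy()
        for j in range(a.shape[1]):
            perm[:, j] = perm[rng.permutation(n_groups), j]
        exceed += _rho_matrix(perm, b) > obs
    if smoothing:
        p = (exceed + 1.0) / (n_perm + 1.0)
    else:
        p = exceed / n_perm
    return pd.DataFrame(p, index=profile_a.index, columns=profile_b.index)


def combine_significance(
    rho: pd.DataFrame,
    p_cor: pd.DataFrame,
    p_perm: pd.DataFrame,
    alpha: float = 0.05,
    n_shared_degs: int = 0,
) -> CorrelationResult:
    """Bonferroni-adjust both criteria over all pairs and flag joint significance."""
    if not (rho.shape == p_cor.shape == p_perm.shape):
        raise ValueError("rho and p-value matrices must share a shape")
    n_pairs = rho.size
    p_cor_adj = np.minimum(1.0, p_cor * n_pairs)
    p_perm_adj = np.minimum(1.0, p_perm * n_pairs)
    significant = (p_cor_adj < alpha) & (p_perm_adj < alpha)
    return CorrelationResult(
        rho=rho,
        p_cor_adj=p_cor_adj,
        p_perm_adj=p_perm_adj,
        significant=significant,
        n_shared_degs=n_shared_degs,
    )
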