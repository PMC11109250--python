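"""Downstream statistics on cross-species cell-type pairs.

Welch two-sample t tests contrast significant (q_perm = 0) against
non-significant cell-type pairs on per-pair metrics such as the shared
marker fraction or the number of driving genes, and a Pearson chi-squared
test asks whether the functional composition (transcription factors,
neuromodulatory ligands, receptors) of driving genes differs between
comparison strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_data import GENE_CLASSES, GeneClassTable

__all__ = [
    "WelchResult",
    "welch_t",
    "compare_sig_vs_nonsig",
    "gene_class_composition",
    "chisq_composition",
]


@dataclass
class WelchResult:
    """Welch two-sample t test with Welch-Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int


def welch_t(x, y, alternative: str = "two-sided") -> WelchResult:
    """Welch's unequal-variance t test of ``mean(x) - mean(y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t undefined")
    res = scipy.stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        n_x=int(x.size),
        n_y=int(y.size),
    )


def compare_sig_vs_nonsig(
    q_perm: pd.DataFrame,
    metric: pd.DataFrame,
    alternative: str = "two-sided",
) -> WelchResult:
    """Welch test of a per-pair metric between significant and other pairs.

    ``q_perm`` and ``metric`` are aligned cell-type-pair matrices; the
    significant stratum is ``q_perm == 0``.  NaN metric entries are
    dropped.  ``mean_x`` is the significant stratum's mean, so the sign of
    ``t`` reports the direction.
    """
    if q_perm.shape != metric.shape:
        raise ValueError("q_perm and metric must be aligned")
    q = q_perm.to_numpy().ravel()
    m = metric.to_numpy(dtype=float).ravel()
    ok = np.isfinite(m)
    sig = m[ok & (q == 0)]
    non = m[ok & (q > 0)]
    if sig.size < 2:
        raise ValueError("significant stratum has fewer than 2 pairs")
    if non.size < 2:
        raise ValueError("non-significant stratum has fewer than 2 pairs")
    if sig.var(ddof=1) == 0 and non.var(ddof=1) == 0 and sig.mean() == non.mean():
        # a metric constant across all pairs carries no signal: t = 0
        return WelchResult(
            t=0.0, df=float(sig.size + non.size - 2), p=1.0,
            mean_x=float(sig.mean()), mean_y=float(non.mean()),
            n_x=int(sig.size), n_y=int(non.size),
        )
    return welch_t(sig, non, alternative=alternative)


def gene_class_composition(
    driving_sets: dict[str, list[str]],
    classes: GeneClassTable,
    strata: dict[str, str],
) -> pd.DataFrame:
    """Mean per-pair gene-class counts per comparison stratum.

    ``driving_sets`` maps a pair name to the human symbols of its driving
    genes (callers fall back to the query-species ortholog symbol when no
    human symbol applies); ``strata`` maps each pair name to its stratum.
    Returns a strata x gene-class table of mean counts per pair, with the
    descriptive ``"other"`` column included.
    """
    rows = []
    for pair, genes in driving_sets.items():
        counts = dict.fromkeys(GENE_CLASSES, 0)
        for g in genes:
            counts[classes.lookup(g)] += 1
        counts["stratum"] = strata.get(pair, "all")
        rows.append(counts)
    if not rows:
        return pd.DataFrame(columns=list(GENE_CLASSES))
    df = pd.DataFrame(rows)
    return df.groupby("stratum")[list(GENE_CLASSES)].mean()


def chisq_composition(
    table: pd.DataFrame, use_means: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-squared test of gene-class composition across strata.

    Restricted to transcription factors, neuromodulatory ligands and
    receptors ("other" is descriptive only).  ``use_means`` rounds the
    per-stratum mean counts (half-to-even) to satisfy the count
    requirement; with ``use_means=False`` the table is taken as raw summed
    counts.  Returns ``(chi2, df, p)`` with ``df = (r - 1)(c - 1)``.
    """
    cols = [c for c in GENE_CLASSES if c != "other" and c in table.columns]
    if len(cols) < 2 or len(table) < 2:
        raise ValueError("need >= 2 strata and >= 2 informative gene classes")
    counts = table[cols].to_numpy(dtype=float)
    if use_means:
        counts = np.rint(counts)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in composition table")
    chi2, p, df, _ = scipy.stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)
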