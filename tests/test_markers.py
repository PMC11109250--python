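import numpy as np
import pandas as pd
import pytest

from _oracles import exact_ranksum_p
from homomap import (
    MarkerSet,
    ResolvedMap,
    SimulationConfig,
    average_expression,
    conserved_markers,
    find_markers,
    log_normalize,
    normalize_profile,
    shared_marker_fraction,
    simulate_species_pair,
)
from tests_common import dataset_from_dense


class TestLogNormalize:
    def test_closed_form_single_cell(self):
        ds = dataset_from_dense([[10], [0]], ["t"])
        out = np.asarray(log_normalize(ds).todense())
        assert np.isclose(out[0, 0], np.log(10_001))
        assert out[1, 0] == 0.0

    def test_all_zero_cell_stays_zero(self):
        ds = dataset_from_dense([[1, 0], [2, 0]], ["t", "t"])
        out = np.asarray(log_normalize(ds).todense())
        assert (out[:, 1] == 0).all()

    def test_depth_invariance(self):
        ds = dataset_from_dense([[3, 6], [7, 14]], ["t", "t"])
        out = np.asarray(log_normalize(ds).todense())
        assert np.allclose(out[:, 0], out[:, 1])


class TestFindMarkers:
    def test_exclusive_gene_is_marker(self):
        dense = np.ones((3, 12))
        dense[0, :] = 0
        dense[0, :6] = 50  # gene 0 only in group A
        ds = dataset_from_dense(dense, ["A"] * 6 + ["B"] * 6)
        ms = find_markers(ds)
        row = ms.table[(ms.table.group == "A") & (ms.table.gene == "g0")].iloc[0]
        assert row.is_marker
        assert row.pct_in == 1.0 and row.pct_out == 0.0

    def test_identical_distribution_not_a_marker(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(5, size=(20, 40))
        ds = dataset_from_dense(dense, ["A"] * 20 + ["B"] * 20)
        ms = find_markers(ds)
        assert not ms.table.is_marker.any()

    def test_p_matches_exact_enumeration(self):
        # groups of 8 vs 8: normal approximation vs full 12870-arrangement
        # enumeration of the rank-sum null across the whole p range
        rng = np.random.default_rng(7)
        for trial in range(8):
            x = rng.integers(15, 60, size=8)
            y = rng.integers(0, 45, size=8)
            dense = np.vstack([np.concatenate([x, y]), rng.integers(5, 15, size=16)])
            ds = dataset_from_dense(dense, ["A"] * 8 + ["B"] * 8)
            ms = find_markers(ds, thresholds=(0.05, 0.25, 0.0))
            got = ms.table[(ms.table.group == "A") & (ms.table.gene == "g0")].iloc[0].p_raw
            lognorm = np.asarray(log_normalize(ds).todense())[0]
            expected = exact_ranksum_p(lognorm[:8], lognorm[8:])
            assert abs(got - expected) < 0.02

    def test_single_group_rejected(self):
        ds = dataset_from_dense(np.ones((3, 4)), ["A"] * 4)
        with pytest.raises(ValueError):
            find_markers(ds)

    def test_bonferroni_is_monotone_and_bounded(self, species_pair):
        ms = find_markers(species_pair[0])
        t = ms.table
        assert (t.p_adj >= t.p_raw - 1e-15).all()
        assert (t.p_adj <= 1.0).all()
        assert (t.sort_values("p_raw").p_adj.diff().dropna() >= -1e-12).all()

    def test_planted_markers_recovered(self):
        cfg = SimulationConfig(
            n_genes=600, n_types_a=5, n_types_b=5, n_shared=3, cells_per_type=100,
            markers_per_type=30, seed=21,
        )
        ds_a, _, truth = simulate_species_pair(cfg)
        ms = find_markers(ds_a)
        recalled = 0
        planted = 0
        flagged = set()
        for t in sorted(set(ds_a.cell_type)):
            found = set(ms.marker_genes(t))
            flagged |= {(t, g) for g in found}
            true = truth.true_markers[("a", t)]
            planted += len(true)
            recalled += len(found & true)
        false_hits = sum(
            1 for t, g in flagged if g not in truth.true_markers[("a", t)]
        )
        assert recalled / planted >= 0.8
        assert false_hits / max(1, len(flagged)) <= 0.05


class TestAverageExpression:
    def test_single_cell_groups_equal_their_vectors(self):
        dense = np.array([[10, 0], [30, 5]])
        ds = dataset_from_dense(dense, ["A", "B"])
        avg = average_expression(ds)
        norm = dense / dense.sum(axis=0) * 10_000
        assert np.allclose(avg.loc["A"], norm[:, 0])
        assert np.allclose(avg.loc["B"], norm[:, 1])

    def test_duplicated_cell_changes_nothing(self):
        ds1 = dataset_from_dense([[4, 1], [6, 9]], ["A", "B"])
        ds2 = dataset_from_dense([[4, 4, 1], [6, 6, 9]], ["A", "A", "B"])
        assert np.allclose(average_expression(ds1), average_expression(ds2))

    def test_matches_bruteforce_dense_means(self, species_pair):
        ds = species_pair[0]
        avg = average_expression(ds)
        dense = np.asarray(ds.counts.todense(), dtype=float)
        norm = dense / dense.sum(axis=0, keepdims=True) * 10_000
        for t in sorted(set(ds.cell_type)):
            cols = np.flatnonzero(ds.cell_type == t)
            assert np.allclose(avg.loc[t], norm[:, cols].mean(axis=1))


class TestNormalizeProfile:
    def test_pointwise_closed_forms(self):
        avg = pd.DataFrame([[0.0], [np.e - 1.0]], index=["A", "B"], columns=["g"])
        y = np.log(avg.to_numpy() + 1) + 0.1
        assert np.isclose(y[0, 0], 0.1)
        assert np.isclose(y[1, 0], 1.1)

    def test_constant_column_becomes_ones(self):
        avg = pd.DataFrame({"g1": [3.0, 3.0], "g2": [0.0, 0.0]}, index=["A", "B"])
        prof = normalize_profile(avg)
        assert np.allclose(prof, 1.0)

    def test_gene_means_are_exactly_one(self, species_pair):
        prof = normalize_profile(average_expression(species_pair[0]))
        assert np.abs(prof.mean(axis=0) - 1.0).max() < 1e-12


def marker_set_from(groups: dict[str, dict[str, float]]) -> MarkerSet:
    """Build a MarkerSet where every listed gene is a marker with the given log2FC."""
    rows = []
    for group, genes in groups.items():
        for gene, fc in genes.items():
            rows.append(
                dict(group=group, gene=gene, log2_fc=fc, pct_in=0.9, pct_out=0.05,
                     p_raw=1e-8, p_adj=1e-6, is_marker=True)
            )
    return MarkerSet(pd.DataFrame(rows))


class TestConservedMarkers:
    def test_disjoint_marker_sets_yield_nothing(self):
        ms1 = marker_set_from({"T": {"a1": 1.0}})
        ms2 = marker_set_from({"T": {"b1": 1.0}})
        out = conserved_markers([ms1, ms2], [None, None], ("T", "T"))
        assert out == []

    def test_shared_symbol_across_five_species(self):
        sets, maps = [], []
        for s in range(5):
            ms = marker_set_from({"T": {f"sp{s}_gene": 1.0, "NOISE%d" % s: 0.5}})
            sets.append(ms)
            maps.append(ResolvedMap.from_dict({f"sp{s}_gene": "X", "NOISE%d" % s: f"N{s}"}))
        assert conserved_markers(sets, maps, tuple("T" * 5)) == ["X"]

    def test_duplicate_pair_keeps_greatest_fold_change(self):
        ms1 = marker_set_from({"T": {"dupA": 1.2, "dupB": 2.5}})
        ms2 = marker_set_from({"T": {"X": 3.0}})
        # many-to-one dict map: both duplicates map to X; the 2.5 gene
        # represents the symbol, so X survives the intersection
        m1 = {"dupA": "X", "dupB": "X"}
        out = conserved_markers([ms1, ms2], [m1, None], ("T", "T"))
        assert out == ["X"]

    def test_relaxed_mode_adds_upregulated_nonmarkers(self):
        ms1 = marker_set_from({"T": {"g": 1.0}})
        weak = pd.DataFrame(
            [dict(group="T", gene="g", log2_fc=0.4, pct_in=0.5, pct_out=0.2,
                  p_raw=0.5, p_adj=1.0, is_marker=False)]
        )
        ms2 = MarkerSet(weak)
        strict = conserved_markers([ms1, ms2], [None, None], ("T", "T"))
        relaxed = conserved_markers([ms1, ms2], [None, None], ("T", "T"), relaxed=True)
        assert strict == []
        assert relaxed == ["g"]

    def test_unknown_group_rejected(self):
        ms = marker_set_from({"T": {"g": 1.0}})
        with pytest.raises(KeyError):
            conserved_markers([ms], [None], ("missing",))


class TestSharedMarkerFraction:
    def test_identical_sets_give_one(self):
        ms = marker_set_from({"T": {"g1": 1.0, "g2": 1.0}})
        assert shared_marker_fraction(("T", "T"), ms, ms, None) == 1.0

    def test_disjoint_sets_give_zero(self):
        ms1 = marker_set_from({"T": {"g1": 1.0}})
        ms2 = marker_set_from({"T": {"g2": 1.0}})
        assert shared_marker_fraction(("T", "T"), ms1, ms2, None) == 0.0

    def test_partial_overlap_fraction(self):
        ms1 = marker_set_from({"T": {f"g{i}": 1.0 for i in range(10)}})
        ms2 = marker_set_from({"T": {f"g{i}": 1.0 for i in range(4)}})
        assert shared_marker_fraction(("T", "T"), ms1, ms2, None) == pytest.approx(0.4)

    def test_no_markers_is_nan(self):
        ms1 = MarkerSet(pd.DataFrame(
            [dict(group="T", gene="g", log2_fc=0.0, pct_in=0.1, pct_out=0.1,
                  p_raw=1.0, p_adj=1.0, is_marker=False)]
        ))
        ms2 = marker_set_from({"T": {"g": 1.0}})
        assert np.isnan(shared_marker_fraction(("T", "T"), ms1, ms2, None))
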