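"""SAM statistic, fudge factor, permutation FDR and cross-series intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphosig import SamConfig, ValidationError
from phosphosig.sam import (
    estimate_s0,
    fold_change,
    intersect_series,
    sam_permutation_fdr,
    sam_statistic,
    significant_table,
)


def _two_group(values, n_a, n_b, probes=None):
    values = np.asarray(values, dtype=float)
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    m = pd.DataFrame(values, columns=cols, index=probes or [f"p{i}" for i in range(values.shape[0])])
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
    return m, labels


class TestSamStatistic:
    def test_hand_computed_pooled_se(self):
        m, labels = _two_group([[2, 4, 1, 1]], 2, 2)
        out = sam_statistic(m, labels, s0=0.0)
        assert out.loc["p0", "numerator"] == pytest.approx(2.0)
        assert out.loc["p0", "s"] == pytest.approx(1.0)
        assert out.loc["p0", "d"] == pytest.approx(2.0)

    def test_identical_means_give_zero(self):
        m, labels = _two_group([[1, 2, 1, 2]], 2, 2)
        assert sam_statistic(m, labels, s0=0.0).loc["p0", "d"] == 0.0

    def test_huge_s0_shrinks_d_to_zero(self):
        rng = np.random.default_rng(0)
        m, labels = _two_group(rng.normal(size=(20, 10)), 5, 5)
        d = sam_statistic(m, labels, s0=1e9)["d"]
        assert np.abs(d).max() < 1e-6

    def test_d_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        m, labels = _two_group(rng.normal(size=(30, 12)), 6, 6)
        d_ab = sam_statistic(m, labels, s0=0.1, numerator="A")["d"]
        d_ba = sam_statistic(m, labels, s0=0.1, numerator="B")["d"]
        np.testing.assert_allclose(d_ab.values, -d_ba.values)

    def test_equals_pooled_t_with_zero_s0(self):
        """Classical oracle: with s0=0 and equal group sizes, d is the pooled t."""
        rng = np.random.default_rng(2)
        m, labels = _two_group(rng.normal(size=(10, 16)), 8, 8)
        d = sam_statistic(m, labels, s0=0.0)["d"].values
        t = stats.ttest_ind(m.values[:, :8], m.values[:, 8:], axis=1).statistic
        np.testing.assert_allclose(d, t, rtol=1e-10)

    def test_small_group_rejected(self):
        m, labels = _two_group([[1, 2, 3]], 1, 2)
        with pytest.raises(ValidationError):
            sam_statistic(m, labels, s0=0.0)


class TestEstimateS0:
    def test_all_s_equal_returns_zero(self):
        assert estimate_s0(np.random.default_rng(0).normal(size=50), np.full(50, 2.0)) == 0.0

    def test_s0_is_a_percentile_of_s_and_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5000, 20))
        m, labels = _two_group(x, 10, 10)
        base = sam_statistic(m, labels, s0=0.0)
        s0 = estimate_s0(base["numerator"].values, base["s"].values)
        candidates = np.percentile(base["s"].values, np.arange(0, 101, 5))
        assert np.min(np.abs(candidates - s0)) < 1e-12
        assert estimate_s0(base["numerator"].values, base["s"].values) == s0

    def test_heteroscedastic_small_s_dominating_gives_positive_s0(self):
        rng = np.random.default_rng(4)
        scales = np.concatenate([np.full(500, 0.01), np.full(4500, 1.0)])
        x = rng.normal(size=(5000, 20)) * scales[:, None]
        m, labels = _two_group(x, 10, 10)
        base = sam_statistic(m, labels, s0=0.0)
        s0 = estimate_s0(base["numerator"].values, base["s"].values)
        assert s0 > 0


class TestFoldChange:
    def test_closed_form_and_symmetry(self):
        m, labels = _two_group([[3, 3, 1, 1], [2, 2, 2, 2]], 2, 2)
        fc = fold_change(m, labels, numerator="A")
        assert fc["p0"] == pytest.approx(4.0)
        assert fc["p1"] == pytest.approx(1.0)
        fc_rev = fold_change(m, labels, numerator="B")
        np.testing.assert_allclose(fc_rev.values, 1.0 / fc.values)


class TestPermutationFdr:
    def test_determinism_per_seed(self):
        rng = np.random.default_rng(5)
        m, labels = _two_group(rng.normal(size=(200, 14)), 7, 7)
        cfg = SamConfig(n_permutations=50, seed=9)
        q1 = sam_permutation_fdr(m, labels, cfg).table["q"]
        q2 = sam_permutation_fdr(m, labels, cfg).table["q"]
        pd.testing.assert_series_equal(q1, q2)

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(6)
        m, labels = _two_group(rng.normal(size=(300, 12)), 6, 6)
        res = sam_permutation_fdr(m, labels, SamConfig(n_permutations=60, seed=1))
        tbl = res.table.reindex(res.table["d"].abs().sort_values(ascending=False).index)
        assert (np.diff(tbl["q"].values) >= -1e-12).all()
        assert res.table["q"].between(0, 1).all()

    def test_exhaustive_enumeration_small_n(self):
        """With 3+3 samples there are only C(6,3)=20 label splits."""
        rng = np.random.default_rng(7)
        m, labels = _two_group(rng.normal(size=(50, 6)), 3, 3)
        r1 = sam_permutation_fdr(m, labels, SamConfig(n_permutations=200, seed=1))
        r2 = sam_permutation_fdr(m, labels, SamConfig(n_permutations=200, seed=2))
        pd.testing.assert_frame_equal(r1.table, r2.table)  # seed-free when exhaustive

    def test_planted_effects_detected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.2, size=(500, 24))
        x[:20, :12] += 2.0
        m, labels = _two_group(x, 12, 12)
        res = sam_permutation_fdr(m, labels, SamConfig(n_permutations=100, seed=3))
        assert (res.table["q"].values[:20] < 0.05).sum() >= 19

    def test_label_swap_leaves_q_invariant(self):
        rng = np.random.default_rng(9)
        m, labels = _two_group(rng.normal(size=(100, 10)), 5, 5)
        cfg = SamConfig(n_permutations=252, seed=4)  # exhaustive for 5+5
        qa = sam_permutation_fdr(m, labels, cfg, numerator="A").table["q"]
        qb = sam_permutation_fdr(m, labels, cfg, numerator="B").table["q"]
        np.testing.assert_allclose(qa.values, qb.values, atol=1e-12)


class TestSignificantTable:
    def _annotation(self, probes, symbols):
        return pd.DataFrame({"probe_id": probes, "symbol": symbols, "description": "d"})

    def test_empty_result(self):
        rng = np.random.default_rng(10)
        m, labels = _two_group(rng.normal(size=(20, 10)), 5, 5)
        res = sam_permutation_fdr(m, labels, SamConfig(n_permutations=50, seed=0))
        res.table["q"] = 1.0
        table = significant_table(res, self._annotation(m.index, ["G"] * 20), 0.05)
        assert table.attrs["probe_count"] == 0 and table.attrs["gene_count"] == 0

    def test_probe_vs_gene_counts_and_sorting(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 0.1, size=(40, 20))
        x[:2, :10] += 3.0  # two probes of the same gene
        m, labels = _two_group(x, 10, 10)
        res = sam_permutation_fdr(m, labels, SamConfig(n_permutations=100, seed=1))
        symbols = ["GENE1", "GENE1"] + [f"G{i}" for i in range(38)]
        table = significant_table(res, self._annotation(m.index, symbols), 0.05)
        assert table.attrs["probe_count"] == 2
        assert table.attrs["gene_count"] == 1
        assert (table["fold_change"].diff().dropna() <= 0).all()

    def test_planted_38_probes_34_genes(self):
        """Count structure of a typical screen: 38 probes over 34 genes."""
        rng = np.random.default_rng(12)
        x = rng.normal(0, 0.1, size=(300, 24))
        x[:38, :12] += rng.uniform(1, 2, size=38)[:, None]
        m, labels = _two_group(x, 12, 12)
        res = sam_permutation_fdr(m, labels, SamConfig(n_permutations=100, seed=2))
        symbols = [f"SIG{i % 34}" for i in range(38)] + [f"BG{i}" for i in range(262)]
        table = significant_table(res, self._annotation(m.index, symbols), 0.05)
        assert table.attrs["probe_count"] == 38
        assert table.attrs["gene_count"] == 34


class TestIntersectSeries:
    def _table(self, ids, fcs):
        return pd.DataFrame({"symbol": ids, "fold_change": fcs})

    def test_self_intersection_is_identity(self):
        t = self._table(["A", "B"], [2.0, 0.5])
        out = intersect_series([t, t])
        assert list(out["symbol"]) == ["A", "B"]
        assert list(out["direction"]) == ["up in A", "up in B"]

    def test_discordant_direction_excluded(self):
        t1 = self._table(["A", "B"], [2.0, 2.0])
        t2 = self._table(["A", "B"], [2.0, 0.4])
        out = intersect_series([t1, t2])
        assert list(out["symbol"]) == ["A"]

    def test_three_series_with_decoys(self):
        concordant = [f"C{i}" for i in range(10)]
        tables = []
        rng = np.random.default_rng(13)
        for k in range(3):
            ids = concordant + [f"D{k}{i}" for i in range(5)] + ["FLIP"]
            fcs = list(rng.uniform(1.5, 3, 10)) + list(rng.uniform(1.2, 2, 5)) + [
                2.0 if k == 0 else 0.5
            ]
            tables.append(self._table(ids, fcs))
        out = intersect_series(tables)
        assert sorted(out["symbol"]) == sorted(concordant)
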