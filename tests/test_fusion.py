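import itertools

import numpy as np
import pandas as pd
import pytest

from gdtec import (
    absolutize,
    build_gdtec,
    cnv_rna_consistency,
    correlate_pairs,
    differential_genes,
    filter_sparse_genes,
    fuse_gdtec,
    screen_gdtec_proportion,
    snv_rna_consistency,
)

from conftest import make_matrix


def mark_oracle(c: int, r: int, s: int) -> int:
    """Brute-force restatement of the fusion mark rules on one raw cell."""
    cnv_rna = 1 if (c + r) in (2, -2) else 0
    snv_rna = 1 if (s + abs(r)) == 2 else 0
    total = cnv_rna + snv_rna
    return 0 if total in (0, 2) else 1


class TestConsistencyMatrices:
    def test_cnv_rna_truth_table(self):
        for c, r in itertools.product((-1, 0, 1), repeat=2):
            out = cnv_rna_consistency(
                make_matrix([[c]], "ternary"), make_matrix([[r]], "ternary")
            )
            expect = 1 if (c + r) in (2, -2) else 0
            assert out.values.iloc[0, 0] == expect, (c, r)

    def test_snv_rna_is_logical_and(self):
        for s, r2 in itertools.product((0, 1), repeat=2):
            out = snv_rna_consistency(
                make_matrix([[s]], "binary"), make_matrix([[r2]], "binary")
            )
            assert out.values.iloc[0, 0] == (s & r2)

    def test_fuse_is_xor(self):
        for a, b in itertools.product((0, 1), repeat=2):
            out = fuse_gdtec(make_matrix([[a]], "binary"), make_matrix([[b]], "binary"))
            assert out.values.iloc[0, 0] == (a ^ b)


def test_composed_pipeline_matches_18_combination_oracle():
    """All (CNV, RNA, SNV) raw combinations, composed end to end."""
    combos = list(itertools.product((-1, 0, 1), (-1, 0, 1), (0, 1)))
    cnv = make_matrix([[c] for c, _, _ in combos], "ternary", samples=["s0"])
    rna = make_matrix([[r] for _, r, _ in combos], "ternary", samples=["s0"])
    snv = make_matrix([[s] for _, _, s in combos], "binary", samples=["s0"])
    fused = fuse_gdtec(
        cnv_rna_consistency(cnv, rna), snv_rna_consistency(snv, absolutize(rna))
    )
    for i, (c, r, s) in enumerate(combos):
        assert fused.to_numpy()[i, 0] == mark_oracle(c, r, s), (c, r, s)


def test_gdtec_requires_expression_change(rng):
    """No driven expression without an expression change in the same cell."""
    cnv = make_matrix(rng.integers(-1, 2, (30, 20)), "ternary")
    rna = make_matrix(rng.integers(-1, 2, (30, 20)), "ternary")
    snv = make_matrix(rng.integers(0, 2, (30, 20)), "binary")
    fused = fuse_gdtec(
        cnv_rna_consistency(cnv, rna), snv_rna_consistency(snv, absolutize(rna))
    )
    assert not np.any((fused.to_numpy() == 1) & (rna.to_numpy() == 0))


class TestSparsityFilter:
    def test_strict_boundary_at_60_percent(self):
        row_61 = np.r_[np.ones(39), np.zeros(61)]
        row_60 = np.r_[np.ones(40), np.zeros(60)]
        m = make_matrix(np.vstack([row_61, row_60]), "binary", genes=["drop", "keep"])
        res = filter_sparse_genes(m, 0.6)
        assert res.retained_genes == ["keep"]
        assert res.removed_genes == ["drop"]

    def test_all_ones_keeps_everything(self):
        m = make_matrix(np.ones((5, 10)), "binary")
        assert len(filter_sparse_genes(m).retained_genes) == 5

    def test_matches_counting_oracle(self, rng):
        m = make_matrix(rng.integers(0, 2, (40, 25)), "binary")
        res = filter_sparse_genes(m, 0.6)
        expect = [
            g
            for g, row in zip(m.gene_ids, m.to_numpy())
            if (row == 0).sum() / 25 <= 0.6
        ]
        assert res.retained_genes == expect

    def test_never_removes_genes_with_40_percent_ones(self, rng):
        m = make_matrix(rng.integers(0, 2, (50, 30)), "binary")
        res = filter_sparse_genes(m, 0.6)
        dense = [
            g for g, row in zip(m.gene_ids, m.to_numpy()) if row.mean() >= 0.4
        ]
        assert set(dense) <= set(res.retained_genes)

    def test_zero_samples_is_error(self):
        m = make_matrix(np.ones((2, 1)), "binary")
        m.values = m.values.iloc[:, :0]
        with pytest.raises(Exception):
            filter_sparse_genes(m)


class TestProportionScreen:
    def groups(self, n_a, n_b):
        return pd.Series(
            ["A"] * n_a + ["B"] * n_b, index=[f"s{j}" for j in range(n_a + n_b)]
        )

    def test_thresholds(self):
        # gene hits 0.75 in A (15/20) and 0.20 in B (4/20) -> selected
        row = np.r_[np.ones(15), np.zeros(5), np.ones(4), np.zeros(16)]
        flat = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        m = make_matrix(np.vstack([row, flat]), "binary", genes=["hit", "flat"])
        rep = screen_gdtec_proportion(m, self.groups(20, 20), positive_group="A")
        assert bool(rep.loc["hit", "selected"])
        assert not bool(rep.loc["flat", "selected"])

    def test_matches_counting_oracle(self, rng):
        m = make_matrix(rng.integers(0, 2, (30, 24)), "binary")
        labels = pd.Series(rng.choice(["A", "B"], 24), index=m.sample_ids)
        while labels.nunique() < 2:
            labels = pd.Series(rng.choice(["A", "B"], 24), index=m.sample_ids)
        rep = screen_gdtec_proportion(m, labels, positive_group="A")
        arr = m.to_numpy()
        in_a = (labels == "A").to_numpy()
        for i, g in enumerate(m.gene_ids):
            pa, pb = arr[i, in_a].mean(), arr[i, ~in_a].mean()
            assert rep.loc[g, "proportion_positive"] == pytest.approx(pa)
            assert bool(rep.loc[g, "selected"]) == (pa >= 0.7 and pb <= 0.3)

    def test_sample_order_invariance(self, rng):
        m = make_matrix(rng.integers(0, 2, (10, 12)), "binary")
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=m.sample_ids)
        rep1 = screen_gdtec_proportion(m, labels, positive_group="A")
        perm = list(rng.permutation(m.sample_ids))
        m2 = make_matrix(m.values[perm].to_numpy(), "binary", m.gene_ids, perm)
        rep2 = screen_gdtec_proportion(m2, labels[perm], positive_group="A")
        pd.testing.assert_frame_equal(rep1, rep2)


class TestDifferentialGenes:
    def test_null_shuffle_selects_few(self, rng):
        vals = rng.normal(0, 1, (200, 40))
        m = make_matrix(vals)
        hits = []
        for _ in range(5):
            labels = pd.Series(rng.permutation(["A"] * 20 + ["B"] * 20), index=m.sample_ids)
            rep = differential_genes(m, labels)
            hits.append(rep["selected"].sum())
        assert np.mean(hits) <= 0.05 * 200

    def test_planted_shift_is_selected(self, rng):
        vals = rng.normal(0, 0.3, (50, 100))
        vals[0, :50] += 2.0
        labels = pd.Series(["A"] * 50 + ["B"] * 50, index=[f"s{j}" for j in range(100)])
        rep = differential_genes(make_matrix(vals), labels)
        assert bool(rep.iloc[0]["selected"])
        assert rep.iloc[0]["logfc"] == pytest.approx(2.0, abs=0.3)

    def test_bh_adjustment_hand_computed(self, rng):
        # engineer 4 genes whose BH-adjusted values follow the hand formula:
        # p=(0.01,0.02,0.03,0.5), m=4 -> (0.04, 0.04, 0.04, 0.5)
        from statsmodels.stats.multitest import multipletests

        _, fdr, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
        assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.5])

    def test_constant_gene_never_selected(self, rng):
        vals = np.vstack([np.full(20, 3.0), rng.normal(0, 1, 20)])
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=[f"s{j}" for j in range(20)])
        rep = differential_genes(make_matrix(vals), labels)
        assert rep.iloc[0]["pvalue"] == 1.0
        assert not bool(rep.iloc[0]["selected"])


class TestCorrelatePairs:
    def test_identical_gene_rho_one(self, rng):
        x = rng.random(20)
        m = make_matrix(np.vstack([x, x]), genes=["a", "b"])
        rep = correlate_pairs(m, [("a", "b")])
        assert rep.iloc[0]["rho"] == pytest.approx(1.0)
        assert bool(rep.iloc[0]["selected"])

    def test_negated_gene_not_selected(self, rng):
        x = rng.random(20)
        m = make_matrix(np.vstack([x, -x]), genes=["a", "b"])
        rep = correlate_pairs(m, [("a", "b")])
        assert rep.iloc[0]["rho"] == pytest.approx(-1.0)
        assert not bool(rep.iloc[0]["selected"])

    def test_rho_matches_rank_then_pearson_oracle(self, rng):
        from scipy import stats

        x, y = rng.random(30), rng.random(30)
        m = make_matrix(np.vstack([x, y]), genes=["a", "b"])
        rep = correlate_pairs(m, [("a", "b")])
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert rep.iloc[0]["rho"] == pytest.approx(expect, abs=1e-12)

    def test_constant_gene_is_flagged(self):
        m = make_matrix(np.vstack([np.ones(10), np.arange(10)]), genes=["a", "b"])
        rep = correlate_pairs(m, [("a", "b")])
        assert bool(rep.iloc[0]["degenerate"])
        assert not bool(rep.iloc[0]["selected"])


def test_build_gdtec_composition(rng):
    cnv = make_matrix(rng.integers(-1, 2, (30, 50)), "ternary")
    rna = make_matrix(rng.integers(-1, 2, (30, 50)), "ternary")
    snv = make_matrix(rng.integers(0, 2, (30, 50)), "binary")
    res = build_gdtec(snv, cnv, rna, max_zero_fraction=1.0)
    expect = np.vectorize(mark_oracle)(
        cnv.to_numpy().astype(int), rna.to_numpy().astype(int), snv.to_numpy().astype(int)
    )
    assert (res.matrix.to_numpy() == expect).all()
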