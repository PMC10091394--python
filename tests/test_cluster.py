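import itertools

import numpy as np
import pandas as pd
import pytest

from gdtec import (
    ClusterConfig,
    consensus_cluster,
    matrix_overlap,
    pam,
    partition_overlap,
    robustness_battery,
    select_k,
)
from gdtec.omics_io import GdtecError
from gdtec.preprocess import binarize_mutations, collapse_cnv, compute_lfc

from conftest import make_matrix


def overlap_oracle(a, b) -> float:
    """Brute-force maximum over all one-to-one cluster matchings."""
    a = np.asarray(a)
    b = np.asarray(b)
    la, lb = np.unique(a), np.unique(b)
    size = max(len(la), len(lb))
    cont = np.zeros((size, size))
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            cont[i, j] = np.sum((a == x) & (b == y))
    best = max(
        sum(cont[i, p[i]] for i in range(size))
        for p in itertools.permutations(range(size))
    )
    return best / len(a)


def set_partitions_upto(n, max_blocks):
    """All set partitions of range(n) into at most max_blocks blocks,
    encoded as restricted-growth label vectors."""
    out = []

    def rec(labels, next_label):
        i = len(labels)
        if i == n:
            out.append(tuple(labels))
            return
        for lab in range(min(next_label + 1, max_blocks)):
            rec(labels + [lab], max(next_label, lab + 1))

    rec([], 0)
    return out


class TestPartitionOverlap:
    def series(self, labels):
        return pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])

    def test_identity_is_one(self):
        p = self.series([0, 0, 1, 1, 2])
        assert partition_overlap(p, p) == 1.0

    def test_label_permutation_is_one(self):
        p1 = self.series([0, 0, 1, 1, 2, 2])
        p2 = self.series([2, 2, 0, 0, 1, 1])
        assert partition_overlap(p1, p2) == 1.0

    def test_matches_brute_force_on_small_partitions(self):
        parts = set_partitions_upto(5, 3)
        for a, b in itertools.combinations(parts, 2):
            got = partition_overlap(self.series(a), self.series(b))
            assert got == pytest.approx(overlap_oracle(a, b)), (a, b)

    def test_lower_bound_largest_contingency_cell(self, rng):
        # any matching containing the largest joint cell is admissible, so the
        # optimum is at least that cell's share of the samples
        for _ in range(20):
            a = rng.integers(0, 3, 12)
            b = rng.integers(0, 3, 12)
            got = partition_overlap(self.series(a), self.series(b))
            cell = max(
                np.sum((a == x) & (b == y))
                for x in np.unique(a)
                for y in np.unique(b)
            )
            assert got >= cell / 12 - 1e-12

    def test_symmetry(self, rng):
        a = self.series(rng.integers(0, 4, 15))
        b = self.series(rng.integers(0, 3, 15))
        assert partition_overlap(a, b) == pytest.approx(partition_overlap(b, a))

    def test_differing_sample_sets_is_error(self):
        from gdtec import AlignmentError

        with pytest.raises(AlignmentError):
            partition_overlap(self.series([0, 1]), pd.Series([0, 1], index=["x", "y"]))


class TestMatrixOverlap:
    def test_identical(self, rng):
        m = make_matrix(rng.integers(0, 2, (10, 10)), "binary")
        assert matrix_overlap(m, m) == 1.0

    def test_disjoint_cells(self):
        a = make_matrix([[1, 0], [0, 0]], "binary")
        b = make_matrix([[0, 1], [0, 0]], "binary")
        assert matrix_overlap(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        z = make_matrix(np.zeros((3, 3)), "binary")
        assert matrix_overlap(z, z) == 1.0

    def test_matches_counting_oracle(self, rng):
        a = make_matrix(rng.integers(0, 2, (12, 9)), "binary")
        b = make_matrix(rng.integers(0, 2, (12, 9)), "binary")
        both = ((a.to_numpy() == 1) & (b.to_numpy() == 1)).sum()
        either = ((a.to_numpy() == 1) | (b.to_numpy() == 1)).sum()
        assert matrix_overlap(a, b) == pytest.approx(both / either)
        assert matrix_overlap(a, b) == pytest.approx(matrix_overlap(b, a))


class TestPam:
    def test_recovers_clean_clusters(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        labels = pam(D, 2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_deterministic(self, rng):
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(rng.random((30, 4))))
        assert (pam(D, 3) == pam(D, 3)).all()


class TestConsensusClustering:
    def test_perfect_blocks_give_exact_consensus(self, perfect_blocks):
        m, labels = perfect_blocks(4)
        cfg = ClusterConfig(k_range=(2, 6), reps=50, seed=1)
        run = consensus_cluster(m, cfg)
        M4 = run.consensus[4]
        same = labels[:, None] == labels[None, :]
        assert np.allclose(M4[same], 1.0)
        assert np.allclose(M4[~same], 0.0)
        assert partition_overlap(run.final_partition, pd.Series(labels, index=m.sample_ids)) == 1.0

    def test_seed_invariance_under_perfect_separation(self, perfect_blocks):
        m, _ = perfect_blocks(4)
        runs = [
            consensus_cluster(m, ClusterConfig(k_range=(2, 6), reps=50, seed=s))
            for s in (1, 2)
        ]
        assert partition_overlap(runs[0].final_partition, runs[1].final_partition) == 1.0

    def test_consensus_matrix_invariants(self, default_cohort):
        from gdtec import build_gdtec

        c = default_cohort
        lfc = compute_lfc(c.expr_tumor, c.expr_normal)
        from gdtec.preprocess import discretize_lfc

        res = build_gdtec(
            binarize_mutations(c.mutations, c.cnv.gene_ids, c.cnv.sample_ids)[0],
            collapse_cnv(c.cnv),
            discretize_lfc(lfc),
        )
        run = consensus_cluster(res.matrix, ClusterConfig(k_range=(2, 5), reps=40, seed=0))
        for k, M in run.consensus.items():
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert M.min() >= 0.0 and M.max() <= 1.0
        assert all(d >= 0 for d in run.deltas.values())
        assert set(run.final_partition.index) == set(res.matrix.sample_ids)

    def test_bit_reproducible_given_seed(self, perfect_blocks):
        m, _ = perfect_blocks(2)
        cfg = ClusterConfig(k_range=(2, 4), reps=30, seed=9)
        a = consensus_cluster(m, cfg)
        b = consensus_cluster(m, cfg)
        for k in a.consensus:
            assert (a.consensus[k] == b.consensus[k]).all()
        assert (a.final_partition == b.final_partition).all()

    def test_k_range_exceeding_samples_is_error(self, perfect_blocks):
        m, _ = perfect_blocks(2, n_samples=8)
        with pytest.raises(GdtecError):
            consensus_cluster(m, ClusterConfig(k_range=(2, 9), reps=5))

    def test_kmeans_requires_euclidean(self):
        with pytest.raises(GdtecError):
            ClusterConfig(base_method="kmeans", distance="binary")


class TestSelectK:
    @pytest.mark.parametrize("true_k", [2, 4])
    def test_perfect_blocks_select_true_k(self, perfect_blocks, true_k):
        m, _ = perfect_blocks(true_k)
        run = consensus_cluster(m, ClusterConfig(k_range=(2, 8), reps=50, seed=5))
        assert run.chosen_k == true_k

    def test_flat_curve_flags_degeneracy(self, perfect_blocks):
        m, _ = perfect_blocks(2)
        run = consensus_cluster(m, ClusterConfig(k_range=(2, 5), reps=30, seed=2))
        # force a flat curve: threshold above every delta
        k = select_k(run, elbow_threshold=10.0)
        assert k == 2
        assert run.degenerate_k


@pytest.fixture(scope="module")
def layers(default_cohort):
    c = default_cohort
    lfc = compute_lfc(c.expr_tumor, c.expr_normal)
    post_cnv = collapse_cnv(c.cnv)
    post_snv, _ = binarize_mutations(c.mutations, c.cnv.gene_ids, c.cnv.sample_ids)
    return post_snv, post_cnv, lfc


class TestRobustnessBattery:

    def test_single_config_self_overlap_is_one(self, layers):
        snv, cnv, lfc = layers
        cfg = ClusterConfig(k_range=(2, 5), reps=25, seed=1)
        rep = robustness_battery(snv, cnv, lfc, [(-1, 1), (-1.2, 1.2)], [cfg])
        assert rep["fraction_above_cutoff"] == 1.0
        assert np.allclose(rep["partition_overlap"].to_numpy(), 1.0)

    def test_threshold_nesting_monotonicity(self, layers):
        snv, cnv, lfc = layers
        cfg = ClusterConfig(k_range=(2, 5), reps=10, seed=1)
        rep = robustness_battery(
            snv, cnv, lfc, [(-1, 1), (-1.2, 1.2), (-3, 3)], [cfg]
        )
        t = rep["matrix_overlap"].to_numpy()
        near, far = t[0, 1], t[0, 2]
        assert near < 1.0
        assert near > far

    def test_separated_cohort_agrees_across_configs(self, layers):
        snv, cnv, lfc = layers
        configs = [
            ClusterConfig("pam", "binary", (2, 5), reps=25, seed=3),
            ClusterConfig("pam", "euclidean", (2, 5), reps=25, seed=3),
            ClusterConfig("hclust-average", "binary", (2, 5), reps=25, seed=3),
            ClusterConfig("hclust-complete", "manhattan", (2, 5), reps=25, seed=3),
            ClusterConfig("hclust-ward", "euclidean", (2, 5), reps=25, seed=3),
            ClusterConfig("kmeans", "euclidean", (2, 5), reps=25, seed=3),
        ]
        rep = robustness_battery(snv, cnv, lfc, [(-1, 1)], configs, overlap_cutoff=0.8)
        off_diag = rep["partition_overlap"].to_numpy()[
            ~np.eye(len(configs), dtype=bool)
        ]
        assert off_diag.min() >= 0.9
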