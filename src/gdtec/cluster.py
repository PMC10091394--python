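"""Resampling consensus clustering of the GDTEC matrix and robustness metrics.

Samples are repeatedly subsampled, each subsample is clustered at every k in
the configured range, and the consensus matrix records for every sample pair
the fraction of co-sampled repetitions in which the pair co-clustered.  The
number of clusters is chosen at the inflection of the delta-area curve of
the consensus CDFs, and the final partition is obtained by clustering
1 - consensus as a distance.

The adopted base configuration is PAM (partitioning around medoids) with a
binary (Jaccard) distance; k-medoids is implemented here (greedy BUILD
initialization followed by alternating assignment/medoid-update), since no
installed library provides it.  k-means and hierarchical linkages come from
scikit-learn / scipy.

Robustness utilities compare partitions (optimal-matching overlap, ARI) and
GDTEC matrices (Jaccard on 1-cells) across LFC thresholds, scoring schemes
and clustering configurations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .fusion import (
    build_gdtec,
    cnv_rna_consistency,
    fuse_gdtec,
    snv_rna_consistency,
)
from .omics_io import AlignmentError, GdtecError, GeneSampleMatrix
from .preprocess import DiscretizationScheme, LFCMatrix, absolutize, discretize_lfc

logger = logging.getLogger("gdtec")

__all__ = [
    "ClusterConfig",
    "ConsensusRun",
    "consensus_cluster",
    "select_k",
    "partition_overlap",
    "matrix_overlap",
    "robustness_battery",
    "pam",
]

BASE_METHODS = ("pam", "kmeans", "hclust-average", "hclust-complete", "hclust-ward")
DISTANCES = ("binary", "euclidean", "manhattan", "pearson")

_LINKAGE = {
    "hclust-average": "average",
    "hclust-complete": "complete",
    "hclust-ward": "ward",
}


@dataclass
class ClusterConfig:
    """Configuration of one consensus-clustering run."""

    base_method: str = "pam"
    distance: str = "binary"
    k_range: tuple[int, int] = (2, 10)
    reps: int = 1000
    subsample_fraction: float = 0.8
    seed: int = 0
    elbow_threshold: float = 0.08
    final_method: str = "hclust-average"  # or "pam"

    def __post_init__(self) -> None:
        if self.base_method not in BASE_METHODS:
            raise ValueError(f"unknown base method {self.base_method!r}")
        if self.distance not in DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.base_method == "kmeans" and self.distance != "euclidean":
            raise GdtecError("kmeans supports only the euclidean distance")
        if self.k_range[0] < 2 or self.k_range[0] > self.k_range[1]:
            raise GdtecError(f"invalid k_range {self.k_range}")
        if self.reps < 1:
            raise GdtecError("reps must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise GdtecError("subsample_fraction must be in (0, 1]")

    @property
    def ks(self) -> list[int]:
        return list(range(self.k_range[0], self.k_range[1] + 1))

    def label(self) -> str:
        return f"{self.base_method}-{self.distance}"


@dataclass
class ConsensusRun:
    """Per-k consensus matrices, CDF areas, chosen k and final partition."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    areas: dict[int, float]
    deltas: dict[int, float]
    chosen_k: int
    final_partition: pd.Series
    config: ClusterConfig
    degenerate_k: bool = False


def _distance_matrix(X: np.ndarray, distance: str) -> np.ndarray:
    if distance == "binary":
        D = squareform(pdist(X, metric="jaccard"))
    elif distance == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif distance == "manhattan":
        D = squareform(pdist(X, metric="cityblock"))
    elif distance == "pearson":
        sd = X.std(axis=1)
        Xc = X - X.mean(axis=1, keepdims=True)
        denom = np.outer(sd, sd) * X.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc @ Xc.T) / denom
        corr = np.where(np.isfinite(corr), corr, 0.0)  # constant rows: corr 0
        np.fill_diagonal(corr, 1.0)
        D = 1.0 - corr
    else:  # pragma: no cover
        raise ValueError(distance)
    return np.nan_to_num(D, nan=0.0)


def pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """k-medoids on a precomputed distance matrix; deterministic.

    Greedy BUILD initialization, then alternating assignment / medoid update
    until the medoid set is stable.  Ties break toward the lowest index.
    """
    n = D.shape[0]
    if k > n:
        raise GdtecError(f"k={k} exceeds {n} points")
    medoids = [int(np.argmin(D.sum(axis=1)))]
    for _ in range(k - 1):
        nearest = D[:, medoids].min(axis=1)
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids_arr], axis=1)
        new = medoids_arr.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new[c] = members[int(np.argmin(within))]
        new = np.sort(new)
        if np.array_equal(new, medoids_arr):
            break
        medoids_arr = new
    return np.argmin(D[:, medoids_arr], axis=1)


def _cluster_once(
    X: np.ndarray, D: np.ndarray | None, k: int, config: ClusterConfig, seed: int
) -> np.ndarray:
    method = config.base_method
    if method == "pam":
        return pam(D, k)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31 - 1))
        return km.fit_predict(X)
    # hierarchical methods operate on the condensed distance
    cond = squareform(D, checks=False)
    Z = linkage(cond, method=_LINKAGE[method])
    return fcluster(Z, t=k, criterion="maxclust") - 1


def consensus_cluster(matrix: GeneSampleMatrix, config: ClusterConfig) -> ConsensusRun:
    """Run resampling consensus clustering on a gene x sample matrix.

    Samples (columns) are the objects being clustered; genes are features.
    Bit-reproducible for a fixed config seed.
    """
    X_full = matrix.to_numpy().T  # samples x genes
    n = X_full.shape[0]
    ks = config.ks
    if max(ks) + 1 > n:
        raise GdtecError(f"k_range {config.k_range} too large for {n} samples")
    rng = np.random.default_rng(config.seed)
    sub_n = max(int(np.floor(config.subsample_fraction * n)), max(ks) + 1)
    # retrying a degenerate subsample only helps if the full matrix has
    # enough distinct sample profiles in the first place
    check_distinct = len(np.unique(X_full, axis=0)) >= max(ks)
    if not check_distinct:
        logger.warning(
            "matrix has fewer distinct sample profiles than max k=%d; "
            "clusters beyond the distinct profiles will be degenerate",
            max(ks),
        )
    hit = np.zeros((n, n))  # co-sampling counts (shared across k)
    co = {k: np.zeros((n, n)) for k in ks}
    for rep in range(config.reps):
        for _attempt in range(10):
            idx = np.sort(rng.choice(n, size=sub_n, replace=False))
            Xs = X_full[idx]
            if not check_distinct or len(np.unique(Xs, axis=0)) >= max(ks):
                break
            logger.warning("rep %d: fewer distinct points than k, retrying", rep)
        D = None
        if config.base_method != "kmeans":
            D = _distance_matrix(Xs, config.distance)
        grid = np.ix_(idx, idx)
        hit[grid] += 1.0
        rep_seed = int(rng.integers(0, 2**31 - 1))
        for k in ks:
            labels = _cluster_once(Xs, D, k, config, rep_seed)
            co[k][grid] += (labels[:, None] == labels[None, :]).astype(float)
    consensus: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    triu = np.triu_indices(n, k=1)
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(hit > 0, co[k] / np.where(hit > 0, hit, 1.0), 0.0)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        # area under the empirical CDF of off-diagonal consensus values
        areas[k] = float(1.0 - M[triu].mean())
    deltas: dict[int, float] = {}
    prev = None
    for k in ks:
        if prev is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = max(areas[k] - areas[prev], 0.0) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    run = ConsensusRun(
        sample_ids=matrix.sample_ids,
        consensus=consensus,
        areas=areas,
        deltas=deltas,
        chosen_k=ks[0],
        final_partition=pd.Series(dtype=int),
        config=config,
    )
    run.chosen_k = select_k(run)
    run.final_partition = _final_partition(run, run.chosen_k)
    return run


def select_k(run: ConsensusRun, elbow_threshold: float | None = None) -> int:
    """Inflection of the delta-area curve: largest k whose relative
    delta-area exceeds the elbow threshold.

    Monotone-flat curves (no k above threshold) return the smallest k and
    set ``run.degenerate_k``.
    """
    if len(run.deltas) < 3:
        raise GdtecError("select_k needs at least three evaluated values of k")
    thr = run.config.elbow_threshold if elbow_threshold is None else elbow_threshold
    ks = sorted(run.deltas)
    above = [k for k in ks if run.deltas[k] > thr]
    if not above:
        run.degenerate_k = True
        return ks[0]
    return max(above)


def _final_partition(run: ConsensusRun, k: int) -> pd.Series:
    M = run.consensus[k]
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    if run.config.final_method == "pam":
        labels = pam(D, k)
    else:
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return pd.Series(labels, index=run.sample_ids, name="cluster")


def partition_overlap(p1: pd.Series | dict, p2: pd.Series | dict) -> float:
    """Optimal-matching agreement of two partitions of the same samples.

    Maximum fraction of samples placed in matched clusters over all
    one-to-one cluster matchings (assignment-problem optimum); symmetric and
    invariant to label permutation.
    """
    s1, s2 = pd.Series(p1), pd.Series(p2)
    if set(s1.index) != set(s2.index):
        raise AlignmentError("partitions cover different sample sets")
    s2 = s2.reindex(s1.index)
    a = pd.factorize(s1.to_numpy())[0]
    b = pd.factorize(s2.to_numpy())[0]
    na, nb = a.max() + 1, b.max() + 1
    cont = np.zeros((na, nb))
    np.add.at(cont, (a, b), 1.0)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(a))


def matrix_overlap(m1: GeneSampleMatrix, m2: GeneSampleMatrix) -> float:
    """Jaccard index of the 1-cells of two binary matrices (1.0 if both empty)."""
    a1, a2 = m1.to_numpy() != 0, m2.to_numpy() != 0
    if a1.shape != a2.shape:
        raise AlignmentError(f"shape mismatch: {a1.shape} vs {a2.shape}")
    union = np.logical_or(a1, a2).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a1, a2).sum() / union)


def _gdtec_for_scheme(
    post_snv: GeneSampleMatrix,
    post_cnv: GeneSampleMatrix,
    lfc: LFCMatrix,
    scheme: DiscretizationScheme,
    max_zero_fraction: float,
):
    post_rnaseq = discretize_lfc(lfc, scheme)
    return build_gdtec(post_snv, post_cnv, post_rnaseq, max_zero_fraction)


def robustness_battery(
    post_snv: GeneSampleMatrix,
    post_cnv: GeneSampleMatrix,
    lfc: LFCMatrix,
    lfc_thresholds: list[tuple[float, float]],
    configs: list[ClusterConfig],
    overlap_cutoff: float = 0.8,
    max_zero_fraction: float = 0.6,
) -> dict:
    """Robustness assessment across LFC thresholds and clustering configurations.

    Rebuilds the GDTEC matrix for every threshold band and reports the
    Jaccard matrix-overlap table across thresholds; runs every clustering
    configuration on the GDTEC matrix of the first (reference) threshold and
    reports the pairwise partition-overlap table plus the fraction of
    configuration pairs at or above ``overlap_cutoff``.
    """
    if len(lfc_thresholds) < 2 and len(configs) < 2:
        raise GdtecError("battery needs >=2 thresholds or >=2 configs")
    schemes = [DiscretizationScheme(low=lo, high=hi) for lo, hi in lfc_thresholds]
    gdtecs = [
        _gdtec_for_scheme(post_snv, post_cnv, lfc, sch, max_zero_fraction)
        for sch in schemes
    ]
    # matrix overlap on the unfiltered fused matrices (shared gene universe)
    fused = []
    for sch in schemes:
        post_rnaseq = discretize_lfc(lfc, sch)
        cr = cnv_rna_consistency(post_cnv, post_rnaseq)
        sr = snv_rna_consistency(post_snv, absolutize(post_rnaseq))
        fused.append(fuse_gdtec(cr, sr))
    t = len(lfc_thresholds)
    mat_table = np.ones((t, t))
    for i, j in itertools.combinations(range(t), 2):
        mat_table[i, j] = mat_table[j, i] = matrix_overlap(fused[i], fused[j])

    reference = gdtecs[0].matrix
    partitions = []
    for cfg in configs:
        run = consensus_cluster(reference, cfg)
        partitions.append(run.final_partition)
    c = len(configs)
    part_table = np.ones((c, c))
    for i, j in itertools.combinations(range(c), 2):
        part_table[i, j] = part_table[j, i] = partition_overlap(
            partitions[i], partitions[j]
        )
    pairs = list(itertools.combinations(range(c), 2))
    if pairs:
        frac = float(np.mean([part_table[i, j] >= overlap_cutoff for i, j in pairs]))
    else:
        frac = 1.0
    return {
        "matrix_overlap": pd.DataFrame(
            mat_table,
            index=[str(th) for th in lfc_thresholds],
            columns=[str(th) for th in lfc_thresholds],
        ),
        "partition_overlap": pd.DataFrame(
            part_table,
            index=[c_.label() for c_ in configs],
            columns=[c_.label() for c_ in configs],
        ),
        "fraction_above_cutoff": frac,
        "overlap_cutoff": overlap_cutoff,
        "partitions": partitions,
        "retained_genes": [g.retained_genes for g in gdtecs],
    }


def default_config_grid(
    k_range: tuple[int, int] = (2, 6), reps: int = 100, seed: int = 0
) -> list[ClusterConfig]:
    """All valid method x distance combinations (kmeans only with euclidean)."""
    grid = []
    for m in BASE_METHODS:
        for d in DISTANCES:
            if m == "kmeans" and d != "euclidean":
                continue
            grid.append(
                ClusterConfig(
                    base_method=m, distance=d, k_range=k_range, reps=reps, seed=seed
                )
            )
    logger.info("configuration grid: %d combinations", len(grid))
    return grid
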