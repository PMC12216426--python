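"""Partition-comparison metrics and clustering benchmark protocols.

Adjusted Rand index (ARI) and adjusted mutual information (AMI) are the
two chance-corrected agreement scores used throughout: both equal 1 for
identical partitions (up to relabeling) and hover around 0 for
independent ones.  They are implemented here from their
contingency-table formulas — they carry the framework's central
consistency claims, so they are owned code, with an established library
serving only as a test oracle.

AMI uses the permutation-model expected mutual information and
max-normalization:

    AMI = (MI - E[MI]) / (max(H(a), H(b)) - E[MI]).

The benchmark protocols mirror how clustering quality is assessed:

* consistency: repeated k-means runs scored against expert labels,
  reporting mean and 95% CI of ARI/AMI across runs;
* stability: repeated runs scored against each other over all unordered
  run pairs, plus member overlap after greedy cluster alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .clustering import spherical_kmeans
from .embedding import EmbeddingMatrix


def _check_labels(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def contingency_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-tabulation of two label vectors (rows: a, cols: b)."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(a, b) -> float:
    """Chance-adjusted Rand index from the pair-counting formula."""
    a, b = _check_labels(a, b)
    table = contingency_table(a, b)
    n = table.sum()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    nz = table > 0
    nij = table[nz].astype(np.float64)
    ai = table.sum(axis=1, keepdims=True).astype(np.float64)
    bj = table.sum(axis=0, keepdims=True).astype(np.float64)
    outer = (ai @ bj)[nz]
    return float((nij / n * np.log(n * nij / outer)).sum())


def _expected_mutual_information(ai: np.ndarray, bj: np.ndarray, n: int) -> float:
    """E[MI] under the permutation (hypergeometric) null model."""
    emi = 0.0
    log_n = np.log(n)
    gln_n = gammaln(n + 1)
    for a in ai:
        for b in bj:
            lo = max(1, a + b - n)
            hi = min(a, b)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.float64)
            term = nij / n * (np.log(nij) + log_n - np.log(a) - np.log(b))
            log_p = (
                gammaln(a + 1)
                + gammaln(b + 1)
                + gammaln(n - a + 1)
                + gammaln(n - b + 1)
                - gln_n
                - gammaln(nij + 1)
                - gammaln(a - nij + 1)
                - gammaln(b - nij + 1)
                - gammaln(n - a - b + nij + 1)
            )
            emi += float((term * np.exp(log_p)).sum())
    return emi


def adjusted_mutual_information(a, b) -> float:
    """AMI with permutation-model E[MI] and max-normalization."""
    a, b = _check_labels(a, b)
    table = contingency_table(a, b)
    # canonical orientation so ami(a, b) == ami(b, a) bitwise despite
    # float summation order
    if (table.shape[0], table.tolist()) > (table.shape[1], table.T.tolist()):
        table = table.T.copy()
    ai = table.sum(axis=1)
    bj = table.sum(axis=0)
    n = int(table.sum())
    if len(ai) == 1 and len(bj) == 1:
        return 1.0
    # identical partitions up to relabeling score exactly 1
    if np.all((table > 0).sum(axis=0) == 1) and np.all((table > 0).sum(axis=1) == 1):
        return 1.0
    mi = _mutual_information(table)
    emi = _expected_mutual_information(ai, bj, n)
    denom = max(_entropy(ai), _entropy(bj)) - emi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi - emi) < 1e-15 else 0.0
    return float((mi - emi) / denom)


@dataclass
class PartitionPairScore:
    ari: float
    ami: float
    n: int


def score_partition_pair(a, b) -> PartitionPairScore:
    a, b = _check_labels(a, b)
    return PartitionPairScore(
        ari=adjusted_rand_index(a, b),
        ami=adjusted_mutual_information(a, b),
        n=a.size,
    )


@dataclass
class ClusterMapping:
    """Greedy alignment of cluster ids between two partitions.

    ``mapping`` sends a cluster id of partition A to its matched id in
    partition B; ``overlap_fraction`` is the fraction of all points
    lying in a matched (A, B) cell of the contingency table.
    """

    mapping: dict
    overlap_fraction: float


def greedy_cluster_mapping(a, b) -> ClusterMapping:
    """Repeatedly match the (A-cluster, B-cluster) pair sharing the most
    members among still-unmatched clusters, until one side exhausts.

    Greedy matching is not guaranteed optimal (a constructed
    counterexample lives in the test suite) but is the protocol used
    for aligning labels across clustering runs.  Ties break toward the
    lowest (A-id, B-id).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    a_ids = np.unique(a)
    b_ids = np.unique(b)
    table = contingency_table(a, b).astype(np.float64)
    mapping: dict = {}
    matched = 0
    free_a = list(range(len(a_ids)))
    free_b = list(range(len(b_ids)))
    while free_a and free_b:
        best = None
        for i in free_a:
            for j in free_b:
                cell = table[i, j]
                if best is None or cell > best[0]:
                    best = (cell, i, j)
        _, i, j = best
        mapping[a_ids[i].item()] = b_ids[j].item()
        matched += int(table[i, j])
        free_a.remove(i)
        free_b.remove(j)
    return ClusterMapping(mapping=mapping, overlap_fraction=matched / a.size)


def _mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=np.float64)
    mean = float(values.mean())
    if values.size < 2 or np.allclose(values, mean):
        return mean, mean, mean
    half = stats.t.ppf(0.5 + confidence / 2, values.size - 1) * stats.sem(values)
    return mean, mean - float(half), mean + float(half)


def consistency_benchmark(
    X: EmbeddingMatrix,
    expert: np.ndarray,
    k: int | None = None,
    runs: int = 10,
    inits_per_run: int = 10,
    seed: int = 0,
    mode: str = "spherical",
) -> dict:
    """Average agreement of repeated k-means runs with expert labels.

    ``k`` defaults to the number of expert clusters so that cluster
    count does not confound the comparison.  Each run is an independent
    best-of-``inits_per_run`` fit; the summary reports the mean and 95%
    CI of ARI and AMI across runs.
    """
    expert = np.asarray(expert)
    if expert.size != X.n:
        raise ValueError("expert labels must cover every row")
    if k is None:
        k = len(np.unique(expert))
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(runs)]
    aris, amis = [], []
    for run_seed in run_seeds:
        result = spherical_kmeans(X, k=k, n_init=inits_per_run, seed=run_seed, mode=mode)
        aris.append(adjusted_rand_index(result.assignment, expert))
        amis.append(adjusted_mutual_information(result.assignment, expert))
    ari_mean, ari_lo, ari_hi = _mean_ci(np.array(aris))
    ami_mean, ami_lo, ami_hi = _mean_ci(np.array(amis))
    return {
        "runs": runs,
        "k": k,
        "mode": mode,
        "ari": {"mean": ari_mean, "ci_low": ari_lo, "ci_high": ari_hi, "values": aris},
        "ami": {"mean": ami_mean, "ci_low": ami_lo, "ci_high": ami_hi, "values": amis},
    }


def stability_analysis(
    X: EmbeddingMatrix,
    k: int,
    runs: int = 10,
    inits_per_run: int = 100,
    seed: int = 0,
    mode: str = "spherical",
) -> dict:
    """Run-to-run stability of k-means clusterings.

    All runs(runs-1)/2 unordered run pairs are scored with ARI/AMI and
    with greedy-mapped member overlap; every run is also aligned to run
    0 so downstream labels can be compared across runs.
    """
    if runs < 2:
        raise ValueError("stability analysis needs at least 2 runs")
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(runs)]
    assignments = [
        spherical_kmeans(X, k=k, n_init=inits_per_run, seed=rs, mode=mode).assignment
        for rs in run_seeds
    ]
    pair_scores = []
    for i in range(runs):
        for j in range(i + 1, runs):
            score = score_partition_pair(assignments[i], assignments[j])
            overlap = greedy_cluster_mapping(assignments[i], assignments[j]).overlap_fraction
            pair_scores.append(
                {"run_a": i, "run_b": j, "ari": score.ari, "ami": score.ami, "overlap": overlap}
            )
    alignment_to_run0 = [
        greedy_cluster_mapping(assignments[r], assignments[0]).mapping
        for r in range(runs)
    ]
    return {
        "runs": runs,
        "n_pairs": len(pair_scores),
        "mean_ari": float(np.mean([p["ari"] for p in pair_scores])),
        "mean_ami": float(np.mean([p["ami"] for p in pair_scores])),
        "mean_overlap": float(np.mean([p["overlap"] for p in pair_scores])),
        "pairs": pair_scores,
        "assignments": assignments,
        "alignment_to_run0": alignment_to_run0,
    }
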