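"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: exhaustive
partition enumeration for k-means, pair counting for the Rand index,
and O(n^2) concordant/discordant counting for Kendall's tau-b.
"""

import numpy as np


def all_assignments(n: int, k: int):
    """All partitions of n items into at most k blocks, as canonical
    restricted-growth label vectors."""
    out = []

    def grow(prefix, used):
        if len(prefix) == n:
            out.append(list(prefix))
            return
        for label in range(min(used + 1, k)):
            prefix.append(label)
            grow(prefix, max(used, label + 1) if label == used else used)
            prefix.pop()

    grow([0], 1) if n else out.append([])
    return np.array(out, dtype=np.int64)


def best_partition_objective(X: np.ndarray, k: int, mode: str = "spherical") -> float:
    """Smallest total within-cluster distance over ALL partitions into
    at most k clusters, each scored with its optimal centroid update
    (member mean, re-normalized in spherical mode)."""
    n, d = X.shape
    assignments = all_assignments(n, k)
    best = np.inf
    for labels in assignments:
        obj = 0.0
        for j in np.unique(labels):
            members = X[labels == j]
            mean = members.mean(axis=0)
            if mode == "spherical":
                norm = np.linalg.norm(mean)
                if norm < 1e-12:
                    obj += float(members.shape[0])  # cosine distance 1 to any direction
                    continue
                c = mean / norm
                obj += float(np.sum(1.0 - members @ c))
            else:
                obj += float(np.sum((members - mean) ** 2))
        best = min(best, obj)
    return best


def rand_index_pair_counting(a, b) -> float:
    """Chance-adjusted Rand index by explicit pair enumeration."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    both = neither = same_a = same_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            same_a += sa
            same_b += sb
            both += sa and sb
            neither += (not sa) and (not sb)
    total = n * (n - 1) / 2
    expected = same_a * same_b / total
    max_index = 0.5 * (same_a + same_b)
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def kendall_tau_b(x, y) -> float:
    """tau-b by O(n^2) concordant/discordant pair counting with ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx == dy:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(v) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))


def best_cluster_matching_overlap(a, b) -> int:
    """Maximum total member overlap over all injective cluster
    matchings (exhaustive assignment search)."""
    from itertools import permutations

    a = np.asarray(a)
    b = np.asarray(b)
    a_ids = np.unique(a)
    b_ids = np.unique(b)
    table = np.zeros((len(a_ids), len(b_ids)), dtype=int)
    for i, ai in enumerate(a_ids):
        for j, bj in enumerate(b_ids):
            table[i, j] = np.sum((a == ai) & (b == bj))
    small, large = sorted([len(a_ids), len(b_ids)])
    best = 0
    for perm in permutations(range(large), small):
        if len(a_ids) <= len(b_ids):
            score = sum(table[i, perm[i]] for i in range(small))
        else:
            score = sum(table[perm[j], j] for j in range(small))
        best = max(best, score)
    return best
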