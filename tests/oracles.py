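"""Independent brute-force oracles used by the test suite.

Everything here is written straightforwardly (pure Python, exhaustive
enumeration) and never calls into the package's optimized paths.
"""

from __future__ import annotations

import itertools


def nw_semiglobal_identity(a: str, b: str) -> tuple[float, int]:
    """Needleman-Wunsch with free end gaps; match +1, mismatch/gap -1.

    Cell values are (score, matches, -columns) tuples compared
    lexicographically, so the optimum maximizes score, then matches, then
    minimizes aligned columns; identity = matches / columns of the aligned
    core ending at the best last-row/last-column cell.
    """
    n, m = len(a), len(b)
    H = [[(0, 0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            hit = a[i - 1] == b[j - 1]
            s, mt, nc = H[i - 1][j - 1]
            d = (s + (1 if hit else -1), mt + hit, nc - 1)
            s, mt, nc = H[i - 1][j]
            u = (s - 1, mt, nc - 1)
            s, mt, nc = H[i][j - 1]
            l = (s - 1, mt, nc - 1)
            H[i][j] = max(d, u, l)
    ends = [H[n][j] for j in range(m + 1)] + [H[i][m] for i in range(n + 1)]
    score, matches, neg_cols = max(ends)
    columns = -neg_cols
    return (matches / columns if columns else 0.0), columns


def window_trim_cut(quals, q_threshold, window_frac=0.1) -> int:
    """First index where the sliding-window mean quality drops below the
    threshold (= the cut position), else the read length."""
    n = len(quals)
    w = max(1, round(window_frac * n))
    for i in range(n - w + 1):
        if sum(quals[i : i + w]) / w < q_threshold:
            return i
    return n


def exact_synonymy_partition(sequences: dict[str, str], min_overlap=64):
    """Group ids by exact sequence equality (planted-duplicate oracle)."""
    by_seq: dict[str, list[str]] = {}
    for rid, seq in sequences.items():
        by_seq.setdefault(seq, []).append(rid)
    groups = [
        sorted(ids)
        for seq, ids in by_seq.items()
        if len(ids) >= 2 and len(seq) >= min_overlap
    ]
    return sorted(groups, key=lambda g: g[0])


def variable_columns(sequences: dict[str, str]) -> list[int]:
    """Column-by-column scan for columns with >= 2 observed states."""
    L = len(next(iter(sequences.values())))
    cols = []
    for j in range(L):
        if len({s[j] for s in sequences.values()}) >= 2:
            cols.append(j)
    return cols


def greedy_centroid_partition(reads, threshold):
    """Reference greedy clustering over (read_id, seq): dereplicate, order by
    (-count, min id), join the first centroid with Hamming identity >=
    threshold (equal-length planted reads only)."""
    groups: dict[str, list[str]] = {}
    for rid, seq in reads:
        groups.setdefault(seq, []).append(rid)
    order = sorted(groups, key=lambda s: (-len(groups[s]), min(groups[s])))
    centroids: list[str] = []
    partition: dict[int, list[str]] = {}
    for seq in order:
        placed = None
        for ci, cseq in enumerate(centroids):
            if len(cseq) == len(seq):
                same = sum(x == y for x, y in zip(cseq, seq))
                if same / len(seq) >= threshold:
                    placed = ci
                    break
        if placed is None:
            placed = len(centroids)
            centroids.append(seq)
        partition.setdefault(placed, []).extend(groups[seq])
    return [sorted(v) for _, v in sorted(partition.items())]


def rarefaction_enumeration(counts, depth) -> float:
    """Mean distinct-OTU count over every without-replacement subset."""
    pool = []
    for idx, c in enumerate(counts):
        pool.extend([idx] * c)
    labels = [
        len({pool[i] for i in sub})
        for sub in itertools.combinations(range(len(pool)), depth)
    ]
    return sum(labels) / len(labels)


def mannwhitney_permutation_p(x, y, n_perm=5000, seed=0) -> float:
    """Two-sided permutation p-value for the difference in rank sums."""
    import numpy as np

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = _rankdata(pooled)
    obs = abs(ranks[:nx].sum() - nx * (len(pooled) + 1) / 2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        stat = abs(ranks[perm[:nx]].sum() - nx * (len(pooled) + 1) / 2)
        if stat >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _rankdata(a):
    import numpy as np

    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a), dtype=float)
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks
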