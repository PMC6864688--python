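import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_pair_counts(partitions, same: bool) -> np.ndarray:
    """O(m·n²) reference: count pairs assigned to the same (or different)
    cluster, one element pair at a time."""
    partitions = [np.asarray(p) for p in partitions]
    n = len(partitions[0])
    counts = np.zeros((n, n), dtype=int)
    for labels in partitions:
        for i in range(n):
            for j in range(n):
                hit = labels[i] == labels[j]
                counts[i, j] += hit if same else not hit
    return counts


def brute_force_average_link(D: np.ndarray):
    """Reference agglomerator: recompute all pairwise mean inter-cluster
    distances at every step, merge the closest pair.  Returns the merge
    height sequence and the member sets merged at each step."""
    D = np.asarray(D, dtype=float)
    clusters = {i: [i] for i in range(len(D))}
    heights, merged_sets = [], []
    next_id = len(D)
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best:
                    best, pair = d, (a, b)
        a, b = pair
        members = sorted(clusters.pop(a) + clusters.pop(b))
        clusters[next_id] = members
        heights.append(best)
        merged_sets.append(frozenset(members))
        next_id += 1
    return np.array(heights), merged_sets
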