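"""Evidence accumulation over ensembles of K-means partitions.

The consensus-clustering core: generate many K-means partitions with a
random number of clusters, count for every element pair how often the
pair lands in the same cluster (positive evidence) or in different
clusters (negative evidence), combine the normalized counts into a
single evidence matrix, and extract the consensus partition from that
matrix with average-link hierarchical clustering.

Positive evidence lives in [0, 1] (fraction of co-occurrence votes),
negative evidence in [-1, 0] (minus the fraction of separation votes),
and the combined matrix in [-1, 1].  The matrix behaves like a
similarity matrix between elements; the final partition is read off an
average-link dendrogram either at a fixed number of clusters or at the
cluster count with the largest lifetime (the tallest plateau between
consecutive merge heights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = [
    "EvidenceMatrix",
    "k_range",
    "sample_k",
    "relabel",
    "generate_partition_ensemble",
    "co_occurrence_counts",
    "separation_counts",
    "accumulate_positive",
    "accumulate_negative",
    "combine_evidence",
    "evidence_to_dissimilarity",
    "average_link",
    "cut_k",
    "lifetime_select",
]


@dataclass
class EvidenceMatrix:
    """A symmetric n×n matrix of accumulated (normalized) votes.

    ``kind`` is ``"positive"`` (values in [0, 1], unit diagonal),
    ``"negative"`` (values in [-1, 0], zero diagonal) or ``"combined"``
    (values in [-1, 1]).
    """

    values: np.ndarray
    kind: str = "combined"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("evidence matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("evidence matrix must be symmetric")
        if self.kind not in ("positive", "negative", "combined"):
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def k_range(n: int) -> tuple[int, int]:
    """Bounds [⌈√n/2⌉, ⌊√n⌋] (clamped to ≥ 2) for the per-partition k."""
    if n < 4:
        raise ValueError(f"need at least 4 elements to draw k, got n={n}")
    root = np.sqrt(n)
    lo = max(2, int(np.ceil(root / 2.0)))
    hi = max(2, int(np.floor(root)))
    return lo, hi


def sample_k(n: int, rng: np.random.Generator) -> int:
    """Draw the number of clusters for one ensemble run uniformly from k_range."""
    lo, hi = k_range(n)
    return int(rng.integers(lo, hi + 1))


def relabel(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels onto 0..k-1 with every value occupied.

    K-means can in principle leave a requested cluster empty; consensus
    bookkeeping only needs contiguous labels, so gaps are squeezed out.
    """
    _, out = np.unique(np.asarray(labels), return_inverse=True)
    return out.astype(np.int64)


def generate_partition_ensemble(
    X: np.ndarray,
    m: int,
    rng: np.random.Generator,
    *,
    k_bounds: tuple[int, int] | None = None,
    max_iter: int = 100,
) -> list[np.ndarray]:
    """Run K-means ``m`` times with random k and random initialization.

    Each run draws k uniformly from ``k_bounds`` (default: ``k_range(n)``),
    uses a single random-point initialization (ensemble diversity is the
    point; restarts would reduce it) and at most ``max_iter`` Lloyd
    iterations.  Returns ``m`` contiguous label vectors.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains NaN or infinite values")
    if m < 1:
        raise ValueError("need at least one partition")
    n = X.shape[0]
    lo, hi = k_bounds if k_bounds is not None else k_range(n)
    partitions: list[np.ndarray] = []
    for _ in range(m):
        k = int(rng.integers(lo, hi + 1))
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=1, init="random", max_iter=max_iter,
                    random_state=seed)
        partitions.append(relabel(km.fit_predict(X)))
    return partitions


def _stack(partitions) -> np.ndarray:
    P = np.asarray(list(partitions))
    if P.ndim != 2:
        raise ValueError("partitions must all cover the same elements")
    return P


def co_occurrence_counts(partitions) -> np.ndarray:
    """q_ij: number of partitions assigning i and j to the same cluster."""
    P = _stack(partitions)
    counts = np.zeros((P.shape[1], P.shape[1]), dtype=np.int64)
    for labels in P:
        counts += labels[:, None] == labels[None, :]
    return counts

def separation_counts(partitions) -> np.ndarray:
    """o_ij: number of partitions assigning i and j to different clusters."""
    P = _stack(partitions)
    return len(P) - co_occurrence_counts(P)


def accumulate_positive(partitions) -> EvidenceMatrix:
    """Normalized positive evidence  G+(i,j) = q_ij / q."""
    P = _stack(partitions)
    if len(P) < 1:
        raise ValueError("need at least one positive partition")
    values = co_occurrence_counts(P) / len(P)
    return EvidenceMatrix(values, kind="positive")


def accumulate_negative(partitions) -> EvidenceMatrix:
    """Normalized negative evidence  G-(i,j) = -o_ij / o  (zero diagonal)."""
    P = _stack(partitions)
    if len(P) < 1:
        raise ValueError("need at least one negative partition")
    values = -separation_counts(P) / len(P)
    return EvidenceMatrix(values, kind="negative")


def combine_evidence(
    positive_counts: np.ndarray,
    positive_denominator: int,
    negative_counts: np.ndarray | None = None,
    negative_denominator: int | None = None,
) -> EvidenceMatrix:
    """Combine raw vote counts into the final evidence matrix G*.

    ``G* = positive_counts / positive_denominator
         - negative_counts / negative_denominator``

    Counts stay integers until this point so that strategy-specific
    denominators (q; (d·q)+b; d·q and o) are applied exactly once.
    ``negative_counts`` holds the (non-negative) separation counts; the
    sign flip happens here.  With no negative part this reduces to the
    plain normalized co-occurrence matrix.
    """
    pos = np.asarray(positive_counts, dtype=float)
    if positive_denominator < 1:
        raise ValueError("positive denominator must be >= 1")
    values = pos / float(positive_denominator)
    if negative_counts is not None:
        neg = np.asarray(negative_counts, dtype=float)
        if neg.shape != pos.shape:
            raise ValueError("positive and negative count matrices disagree in shape")
        if negative_denominator is None or negative_denominator < 1:
            raise ValueError("negative evidence requires a denominator >= 1")
        values = values - neg / float(negative_denominator)
    return EvidenceMatrix(values, kind="combined")


def evidence_to_dissimilarity(G, mode: str = "rows") -> np.ndarray:
    """Turn the evidence matrix into the dissimilarity fed to the linkage.

    mode="rows"
        Euclidean distance between rows of G*: two elements are close
        when they collected the same vote pattern against everyone.
        This is what applying a stock linkage routine directly to the
        matrix does, and the default here.
    mode="shift"
        max(G*) − G*(i,j): the classic one-minus-similarity reading,
        shifted so the result is non-negative when negative evidence
        pushes entries below zero.
    """
    values = G.values if isinstance(G, EvidenceMatrix) else np.asarray(G, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("evidence matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("evidence matrix must be symmetric")
    if mode == "rows":
        D = squareform(pdist(values, metric="euclidean"))
    elif mode == "shift":
        D = values.max() - values
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2.0
    else:
        raise ValueError(f"unknown dissimilarity mode {mode!r}")
    return D


def average_link(D: np.ndarray) -> np.ndarray:
    """Average-link (UPGMA) agglomeration of a dissimilarity matrix.

    Returns the linkage table in scipy format: one row per merge with
    the two merged cluster ids, the merge height (mean inter-cluster
    dissimilarity) and the new cluster size.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("dissimilarity matrix must be non-negative")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    condensed = squareform((D + D.T) / 2.0, checks=False)
    return hierarchy.linkage(condensed, method="average")


def cut_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Partition with exactly ``k`` clusters: undo the last k−1 merges."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    return relabel(hierarchy.cut_tree(Z, n_clusters=k).ravel())


def lifetime_select(Z: np.ndarray) -> tuple[int, dict[int, float]]:
    """Choose the cluster count with the largest dendrogram lifetime.

    The lifetime of k clusters is the height difference between the
    merge that reduces k to k−1 clusters and the merge that reduces
    k+1 to k.  Defined for k in 2..n−1; k = 1 is excluded because its
    lifetime is unbounded above.  Ties go to the smallest k (parsimony).
    """
    n = Z.shape[0] + 1
    if Z.shape[0] < 2:
        raise ValueError("lifetime criterion needs at least two merges (n >= 3)")
    heights = Z[:, 2]
    # merge row t (0-based) reduces n−t clusters to n−t−1
    lifetimes = {k: float(heights[n - k] - heights[n - k - 1]) for k in range(2, n)}
    best = max(sorted(lifetimes), key=lambda k: lifetimes[k])
    return best, lifetimes
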