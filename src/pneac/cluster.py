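"""Consensus clustering estimator with positive and negative evidence.

`EvidenceAccumulationClustering` is the user-facing estimator.  It takes
one feature matrix, a declaration of which column blocks form which data
sources and whether each source votes positively (elements seen together
should end up together) or negatively (elements seen apart should stay
apart), and produces a consensus partition.

The three heartbeat strategies are thin wrappers:

* strategy 1 — all features joined in one vector, q positive partitions;
* strategy 2 — one positive source per lead (q partitions each) plus a
  positive source from the RR features (b partitions);
* strategy 3 — as strategy 2, but the RR source votes negatively with o
  partitions, o chosen so negative votes are a fixed fraction (default
  1/3) of all votes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from . import ensemble as ev
from .features import BeatRepresentation

__all__ = [
    "SourceSpec",
    "EvidenceAccumulationClustering",
    "negative_partition_budget",
    "run_strategy",
    "cluster_heartbeats",
]


@dataclass(frozen=True)
class SourceSpec:
    """One data source: a block of feature columns and its vote polarity."""

    columns: tuple[int, ...]
    polarity: str = "positive"
    n_partitions: int | None = None  # None → estimator default

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")


def _as_spec(source) -> SourceSpec:
    if isinstance(source, SourceSpec):
        return source
    columns, polarity, *rest = source
    m = rest[0] if rest else None
    return SourceSpec(tuple(int(c) for c in np.atleast_1d(columns)), polarity, m)


def negative_partition_budget(d: int, q: int, fraction: float = 1.0 / 3.0) -> int:
    """Negative partitions needed so they make up ``fraction`` of all votes.

    With d positive sources of q partitions each, o negative partitions
    give a negative share of o/(d·q+o); solving for the target share
    yields o = d·q·fraction/(1−fraction) — i.e. o = d·q/2 for the usual
    one-third weighting.  Rounded to the nearest integer, ties upward.
    """
    if d < 1 or q < 1:
        raise ValueError("need d >= 1 sources and q >= 1 partitions per source")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    # epsilon guards half-integer targets against float round-down
    return int(np.floor(d * q * fraction / (1.0 - fraction) + 0.5 + 1e-9))


class EvidenceAccumulationClustering(ClusterMixin, BaseEstimator):
    """Ensemble K-means consensus clustering with signed evidence.

    Parameters
    ----------
    n_partitions : int, default=100
        K-means partitions generated per source (sources may override).
    sources : sequence or None
        Each entry is a ``SourceSpec`` or a ``(columns, polarity[, m])``
        tuple.  ``None`` treats all columns as a single positive source.
        At least one source must be positive: separation votes alone
        cannot say what belongs together.
    n_clusters : int or "lifetime", default="lifetime"
        Fixed consensus cluster count, or automatic selection by the
        largest dendrogram lifetime.
    dissimilarity : {"rows", "shift"}, default="rows"
        How the combined evidence matrix becomes a dissimilarity; see
        :func:`pneac.ensemble.evidence_to_dissimilarity`.
    k_bounds : (int, int) or None
        Override the per-partition k range (default [⌈√n/2⌉, ⌊√n⌋]).
    standardize : bool, default=True
        z-score each feature within its source before K-means, so
        sources mixing scales (Hermite coefficients vs. seconds) are
        not dominated by one feature.  Constant columns become zeros.
    kmeans_max_iter : int, default=100
        Lloyd iteration cap for every ensemble run.
    random_state : int, Generator or None
        Master seed; every ensemble run derives from it.

    Attributes
    ----------
    labels_ : consensus cluster index per element (0-based, contiguous)
    n_clusters_ : number of clusters in the consensus partition
    evidence_ : combined EvidenceMatrix G*
    linkage_ : scipy linkage table of the average-link dendrogram
    lifetimes_ : dict k → lifetime (only when n_clusters="lifetime")
    partition_counts_ : dict with q (positive) and o (negative) totals
    """

    def __init__(
        self,
        n_partitions: int = 100,
        sources=None,
        n_clusters="lifetime",
        dissimilarity: str = "rows",
        k_bounds=None,
        standardize: bool = True,
        kmeans_max_iter: int = 100,
        random_state=None,
    ):
        self.n_partitions = n_partitions
        self.sources = sources
        self.n_clusters = n_clusters
        self.dissimilarity = dissimilarity
        self.k_bounds = k_bounds
        self.standardize = standardize
        self.kmeans_max_iter = kmeans_max_iter
        self.random_state = random_state

    def _resolve_sources(self, n_features: int) -> list[SourceSpec]:
        if self.sources is None:
            return [SourceSpec(tuple(range(n_features)), "positive", self.n_partitions)]
        specs = [_as_spec(s) for s in self.sources]
        if not specs:
            raise ValueError("sources must not be empty")
        if all(s.polarity == "negative" for s in specs):
            raise ValueError(
                "negative evidence can only be used together with positive evidence"
            )
        for s in specs:
            if any(c < 0 or c >= n_features for c in s.columns):
                raise ValueError(f"source columns {s.columns} outside 0..{n_features - 1}")
        return specs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 4:
            raise ValueError("X must be 2-D with at least 4 rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN or infinite values")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        specs = self._resolve_sources(X.shape[1])

        pos_counts = np.zeros((n, n), dtype=np.int64)
        neg_counts = np.zeros((n, n), dtype=np.int64)
        q_total = o_total = 0
        for spec in specs:
            F = X[:, list(spec.columns)]
            if self.standardize:
                F = _zscore(F)
            m = spec.n_partitions if spec.n_partitions is not None else self.n_partitions
            parts = ev.generate_partition_ensemble(
                F, m, rng, k_bounds=self.k_bounds, max_iter=self.kmeans_max_iter
            )
            if spec.polarity == "positive":
                pos_counts += ev.co_occurrence_counts(parts)
                q_total += m
            else:
                neg_counts += ev.separation_counts(parts)
                o_total += m

        self.evidence_ = ev.combine_evidence(
            pos_counts, q_total,
            neg_counts if o_total else None, o_total if o_total else None,
        )
        D = ev.evidence_to_dissimilarity(self.evidence_, mode=self.dissimilarity)
        self.linkage_ = ev.average_link(D)
        if self.n_clusters == "lifetime":
            k, self.lifetimes_ = ev.lifetime_select(self.linkage_)
        else:
            k = int(self.n_clusters)
            if k < 2:
                raise ValueError("fixed n_clusters must be >= 2")
            self.lifetimes_ = None
        self.labels_ = ev.cut_k(self.linkage_, k)
        self.n_clusters_ = int(self.labels_.max()) + 1
        self.partition_counts_ = {"positive": q_total, "negative": o_total}
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    @property
    def consensus_matrix_(self) -> np.ndarray:
        check_is_fitted(self, "evidence_")
        return self.evidence_.values


def _zscore(F: np.ndarray) -> np.ndarray:
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns → centred zeros
    return (F - mu) / sd


def run_strategy(X, sources, *, n_partitions=100, n_clusters="lifetime",
                 dissimilarity="rows", k_bounds=None, standardize=True,
                 random_state=None):
    """Functional wrapper: fit an estimator and return (labels, G*, linkage)."""
    est = EvidenceAccumulationClustering(
        n_partitions=n_partitions, sources=sources, n_clusters=n_clusters,
        dissimilarity=dissimilarity, k_bounds=k_bounds, standardize=standardize,
        random_state=random_state,
    ).fit(X)
    return est.labels_, est.evidence_, est.linkage_


def heartbeat_sources(rep: BeatRepresentation, strategy: int, *,
                      q: int = 100, b: int | None = None, o: int | None = None,
                      negative_fraction: float = 1.0 / 3.0):
    """Build the (X, sources) pair for one of the three heartbeat strategies."""
    d = rep.n_leads
    blocks = rep.blocks()  # per-lead column index tuples + rr columns
    if strategy == 1:
        X = rep.joint
        return X, [SourceSpec(tuple(range(X.shape[1])), "positive", q)]
    if strategy == 2:
        specs = [SourceSpec(cols, "positive", q) for cols in blocks.leads]
        specs.append(SourceSpec(blocks.rr, "positive", 100 if b is None else b))
        return rep.joint, specs
    if strategy == 3:
        o = negative_partition_budget(d, q, negative_fraction) if o is None else o
        if o < 1:
            raise ValueError("strategy 3 requires at least one negative partition")
        specs = [SourceSpec(cols, "positive", q) for cols in blocks.leads]
        specs.append(SourceSpec(blocks.rr, "negative", o))
        return rep.joint, specs
    raise ValueError(f"strategy must be 1, 2 or 3, got {strategy}")


def cluster_heartbeats(rep: BeatRepresentation, strategy: int = 3, *,
                       q: int = 100, b: int | None = None, o: int | None = None,
                       negative_fraction: float = 1.0 / 3.0,
                       n_clusters="lifetime", dissimilarity="rows",
                       random_state=None) -> EvidenceAccumulationClustering:
    """Cluster one recording's beats with the chosen strategy; returns the fitted estimator."""
    X, specs = heartbeat_sources(rep, strategy, q=q, b=b, o=o,
                                 negative_fraction=negative_fraction)
    est = EvidenceAccumulationClustering(
        sources=specs, n_clusters=n_clusters, dissimilarity=dissimilarity,
        random_state=random_state,
    )
    return est.fit(X)
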