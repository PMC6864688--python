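"""Synthetic inputs with the structure the method assumes.

Two generators:

* :func:`toy_gaussians` — the six-Gaussian illustration of why negative
  evidence matters: three well-separated 2-D blobs, each of which is
  actually a pair of overlapping sub-clusters, with a third feature
  (means ∓1) that separates the two halves of every pair.  Clustering
  everything as positive evidence merges each pair (3 clusters); using
  the third feature as negative evidence splits them (6 clusters).
* :func:`synthetic_beats` — multilead beat series whose classes differ
  by QRS morphology (Hermite templates) and/or rhythm (premature or
  escape beats), for exercising the feature extraction and the
  heartbeat strategies end to end.  This is a structural emulation, not
  a physiological ECG model: no P/T waves, white noise only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import BeatSeries
from .hermite import DEFAULT_WINDOW, _raw_basis

__all__ = [
    "ToyConfig",
    "toy_gaussians",
    "BeatClass",
    "SyntheticECGConfig",
    "default_beat_classes",
    "class_window",
    "synthetic_beats",
]


@dataclass
class ToyConfig:
    """Frozen geometry for the six-Gaussian toy set.

    The printed description fixes only n = 600, six Gaussians and the
    third-feature means at ±1; the 2-D geometry here is a reconstruction
    chosen so the three qualitative outcomes (3 / 2 / 6 clusters for
    all-positive-joint / split-positive / positive+negative evidence)
    hold, and then frozen.
    """

    n: int = 600
    blob_centers: tuple = ((0.0, 0.0), (4.0, 0.0), (2.0, 3.5))
    pair_offset: float = 0.7   # sub-cluster separation within a blob (≈ sd2d)
    sd2d: float = 0.5          # spread of features 1–2
    f3_means: tuple = (-1.0, 1.0)
    f3_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n % 6:
            raise ValueError("n must be divisible by 6 (equal cluster sizes)")


def toy_gaussians(cfg: ToyConfig | None = None, seed=None):
    """Six Gaussian clusters in 3-D; returns (X of shape (n, 3), labels 0..5).

    Cluster 2b+s sits at blob b (features 1–2, sub-clusters offset by
    ``pair_offset`` along the first axis) with feature-3 mean
    ``f3_means[s]``.  Equal sizes n/6.
    """
    cfg = cfg or ToyConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    per = cfg.n // 6
    rows, labels = [], []
    for b, centre in enumerate(cfg.blob_centers):
        for s in range(2):
            cx = centre[0] + (s - 0.5) * cfg.pair_offset
            xy = rng.normal([cx, centre[1]], cfg.sd2d, size=(per, 2))
            f3 = rng.normal(cfg.f3_means[s], cfg.f3_sd, size=(per, 1))
            rows.append(np.hstack([xy, f3]))
            labels.append(np.full(per, 2 * b + s))
    return np.vstack(rows), np.concatenate(labels)


# Frozen demonstration pipeline for the three toy contrasts.  The
# consensus k-bounds are overridden to (2, 6) for the demo: the toy has
# at most six groups and the small bound keeps each K-means partition
# at the granularity of the structure being voted on.  Budgets total
# 300 partitions per contrast; the split and negative contrasts differ
# only in the polarity of the third-feature source.
TOY_KMEANS_BOUNDS = (2, 6)
TOY_DISSIMILARITY = "rows"
TOY_BUDGETS = {"joint": 300, "split": (100, 200), "negative": (100, 200)}


def run_toy_contrast(case: str, seed: int, n_clusters="lifetime",
                     cfg: ToyConfig | None = None):
    """Run one of the three evidence routings on the toy set.

    case="joint"    — positive evidence from all three features together;
    case="split"    — positive evidence from (f1, f2) and from f3 separately;
    case="negative" — positive from (f1, f2), negative from f3.

    Returns ``(fitted estimator, true labels)``.  With lifetime selection
    the three cases settle on 3, 2 and 6 clusters respectively: the
    joint routing merges each sub-cluster pair, the split-positive
    routing lets the third feature's two modes dominate, and only the
    negative routing separates all six groups.
    """
    from .cluster import EvidenceAccumulationClustering

    cfg = cfg or ToyConfig()
    X, labels = toy_gaussians(cfg, seed=seed)
    if case == "joint":
        sources = None
        n_partitions = TOY_BUDGETS["joint"]
    elif case in ("split", "negative"):
        q, m3 = TOY_BUDGETS[case]
        polarity = "positive" if case == "split" else "negative"
        sources = [((0, 1), "positive", q), ((2,), polarity, m3)]
        n_partitions = 100
    else:
        raise ValueError(f"unknown toy contrast {case!r}")
    est = EvidenceAccumulationClustering(
        n_partitions=n_partitions, sources=sources, n_clusters=n_clusters,
        dissimilarity=TOY_DISSIMILARITY, k_bounds=TOY_KMEANS_BOUNDS,
        random_state=seed,
    ).fit(X)
    return est, labels


@dataclass
class BeatClass:
    """One beat type: per-lead Hermite templates plus a rhythm role."""

    name: str
    coefficients: list[np.ndarray]  # one c-vector per lead
    sigmas: list[float]             # one σ (seconds) per lead
    prevalence: float
    rhythm: str = "regular"         # regular | premature | escape


def default_beat_classes(d: int = 2) -> list[BeatClass]:
    """Three stock classes: normal, wide ventricular, premature atrial.

    The premature class shares the normal morphology exactly — only the
    rhythm distinguishes it, which is what makes the RR features (and
    negative evidence extracted from them) earn their keep.
    """
    c_normal = np.zeros(16)
    c_normal[:4] = [1.0, 0.35, -0.25, 0.1]
    c_ventric = np.zeros(16)
    c_ventric[:4] = [0.4, 1.2, 0.5, -0.2]
    lead_scale = [1.0 if r % 2 == 0 else 0.75 for r in range(d)]

    def per_lead(c):
        return [c * s for s in lead_scale]

    return [
        BeatClass("N", per_lead(c_normal), [0.012] * d, 0.70, "regular"),
        BeatClass("V", per_lead(c_ventric), [0.030] * d, 0.15, "regular"),
        BeatClass("A", per_lead(c_normal), [0.012] * d, 0.15, "premature"),
    ]


@dataclass
class SyntheticECGConfig:
    classes: list[BeatClass] | None = None
    d: int = 2
    fs: float = 360.0
    n_beats: int = 200
    base_rr: float = 0.8        # seconds
    rr_jitter: float = 0.01     # sd of per-interval Gaussian jitter, seconds
    premature_factor: float = 0.6
    escape_factor: float = 1.5
    noise_sd: float = 0.02      # additive white noise, same units as templates
    seed: int | None = None

    def __post_init__(self):
        if self.classes is None:
            self.classes = default_beat_classes(self.d)
        total = sum(c.prevalence for c in self.classes)
        if not np.isclose(total, 1.0):
            raise ValueError(f"class prevalences must sum to 1, got {total}")
        if not self.premature_factor < 1.0 < self.escape_factor:
            raise ValueError("need premature_factor < 1 < escape_factor")


def class_window(cls: BeatClass, lead: int, fs: float,
                 width: float = DEFAULT_WINDOW) -> np.ndarray:
    """The noiseless template window of one class on one lead."""
    length = int(np.round(width * fs))
    t = (np.arange(length) - length // 2) / fs
    B = _raw_basis(len(cls.coefficients[lead]), cls.sigmas[lead], t)
    return B @ cls.coefficients[lead]


def synthetic_beats(cfg: SyntheticECGConfig | None = None, seed=None):
    """Generate a multilead beat series; returns (BeatSeries, class labels).

    Beat classes are drawn i.i.d. from the prevalences.  Intervals are
    base_rr + jitter; a premature beat shortens its preceding interval
    by ``premature_factor`` and is followed by a compensatory pause
    (the two intervals together still span two base cycles); an escape
    beat lengthens its preceding interval by ``escape_factor``.  Each
    lead is the sum of the class template at every beat position plus
    white noise.
    """
    cfg = cfg or SyntheticECGConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    classes = cfg.classes
    prevalences = [c.prevalence for c in classes]
    idx = rng.choice(len(classes), size=cfg.n_beats, p=prevalences)

    beat_times = np.empty(cfg.n_beats)
    t = 1.0  # lead-in so the first window does not hit the record edge
    for i, ci in enumerate(idx):
        interval = cfg.base_rr + rng.normal(0.0, cfg.rr_jitter)
        rhythm = classes[ci].rhythm
        if i > 0 and rhythm == "premature":
            interval *= cfg.premature_factor
        elif i > 0 and rhythm == "escape":
            interval *= cfg.escape_factor
        elif i > 0 and classes[idx[i - 1]].rhythm == "premature":
            # compensatory pause after a premature beat
            interval = 2.0 * cfg.base_rr - (beat_times[i - 1] - beat_times[i - 2]) \
                if i > 1 else cfg.base_rr * (2.0 - cfg.premature_factor)
        if i == 0:
            beat_times[i] = t
        else:
            beat_times[i] = beat_times[i - 1] + max(interval, 0.12)

    width = int(np.round(DEFAULT_WINDOW * cfg.fs))
    if np.any(np.diff(beat_times) < DEFAULT_WINDOW):
        warnings.warn("adjacent beats closer than the analysis window overlap")
    n_samples = int(np.ceil((beat_times[-1] + 1.0) * cfg.fs))
    signals = rng.normal(0.0, cfg.noise_sd, size=(n_samples, cfg.d)) \
        if cfg.noise_sd > 0 else np.zeros((n_samples, cfg.d))
    for r in range(cfg.d):
        templates = [class_window(c, r, cfg.fs) for c in classes]
        for i, ci in enumerate(idx):
            centre = int(np.round(beat_times[i] * cfg.fs))
            start = centre - width // 2
            signals[start:start + width, r] += templates[ci]

    labels = [classes[ci].name for ci in idx]
    series = BeatSeries(signals=signals, fs=cfg.fs, beat_times=beat_times,
                        beat_symbols=labels)
    return series, labels
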