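"""Per-beat feature representations: Hermite morphology + RR prematurity.

Each annotated heartbeat i on a d-lead record is described by

* one Hermite vector per lead, v_i^r = (c_0..c_{N-1}, σ)_r, r = 1..d;
* two rhythm features w_i = (R1, R2), where R1[i] = R[i] − R[i−1] is
  the preceding RR interval and R2 is the clipped prematurity statistic
  α[i] = (R1[i+1] − R1[i]) − (R1[i] − R1[i−1]),  R2[i] = u(α[i])·α[i],
  with u the Heaviside step.  A beat arriving early relative to both
  neighbours gets α > 0; the following compensatory pause gets α < 0
  and is clipped to zero.

The joint vector u_i concatenates all leads and the rhythm pair:
d·(N+1) + 2 features (36 for two leads, 206 for twelve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hermite import DEFAULT_N, DEFAULT_WINDOW, HermiteFit, extract_beat_window, fit_hermite

__all__ = [
    "BeatSeries",
    "RRFeatures",
    "BeatRepresentation",
    "heaviside",
    "rr_features",
    "assemble_representations",
    "featurize_record",
]


@dataclass
class BeatSeries:
    """A multilead ECG excerpt with beat annotations.

    signals: samples × d leads (physical units); fs in Hz; beat_times in
    seconds (strictly increasing, from the annotations); beat_symbols is
    the per-beat annotation code when available.
    """

    signals: np.ndarray
    fs: float
    beat_times: np.ndarray
    beat_symbols: list[str] | None = None
    lead_names: list[str] | None = None

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] < self.signals.shape[1]:
            # accept lead-major input but store sample-major
            self.signals = self.signals.T
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        duration = self.signals.shape[0] / self.fs
        if self.beat_times.size and (self.beat_times[0] < 0 or self.beat_times[-1] > duration):
            raise ValueError("beat annotations fall outside the record")

    @property
    def n_leads(self) -> int:
        return self.signals.shape[1]

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)


@dataclass
class RRFeatures:
    """Rhythm features per beat; all in seconds."""

    r1: np.ndarray     # preceding RR interval
    alpha: np.ndarray  # second-difference prematurity statistic
    r2: np.ndarray     # clipped prematurity, max(alpha, 0)

    @property
    def matrix(self) -> np.ndarray:
        """(n, 2) feature block (R1, R2)."""
        return np.column_stack([self.r1, self.r2])


def heaviside(x):
    """Unit step: 1 for x ≥ 0, 0 for x < 0 (elementwise on arrays)."""
    return np.where(np.asarray(x, dtype=float) >= 0, 1, 0)[()]


def rr_features(beat_times: np.ndarray) -> RRFeatures:
    """R1, α and R2 for a strictly increasing beat-time series.

    Interior beats (the third through the second-to-last) have fully
    defined α.  Boundaries: the first beat has no preceding interval, so
    R1 copies the second beat's value; α (hence R2) is zero at the first
    two and the last beats.
    """
    R = np.asarray(beat_times, dtype=float)
    n = len(R)
    if n < 4:
        raise ValueError("need at least 4 beats for RR features")
    if np.any(np.diff(R) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    r1 = np.empty(n)
    r1[1:] = np.diff(R)
    r1[0] = r1[1]
    alpha = np.zeros(n)
    i = np.arange(2, n - 1)
    alpha[i] = (r1[i + 1] - r1[i]) - (r1[i] - r1[i - 1])
    r2 = heaviside(alpha) * alpha
    return RRFeatures(r1=r1, alpha=alpha, r2=r2)


@dataclass(frozen=True)
class _Blocks:
    leads: list[tuple[int, ...]]
    rr: tuple[int, ...]


@dataclass
class BeatRepresentation:
    """All per-beat feature views of one recording.

    ``lead_features[r]`` is the (n, N+1) block (c_0..c_{N-1}, σ) for lead
    r; ``rr`` is the (n, 2) block (R1, R2).  ``joint`` concatenates them
    in lead order followed by the rhythm pair.
    """

    lead_features: list[np.ndarray]
    rr: np.ndarray
    symbols: list[str] | None = None

    def __post_init__(self):
        self.lead_features = [np.asarray(F, dtype=float) for F in self.lead_features]
        self.rr = np.asarray(self.rr, dtype=float)
        n = self.rr.shape[0]
        if self.rr.ndim != 2 or self.rr.shape[1] != 2:
            raise ValueError("rr block must be (n, 2)")
        for F in self.lead_features:
            if F.shape[0] != n:
                raise ValueError("lead blocks and rr block disagree on beat count")

    @property
    def n_beats(self) -> int:
        return self.rr.shape[0]

    @property
    def n_leads(self) -> int:
        return len(self.lead_features)

    @property
    def joint(self) -> np.ndarray:
        """u_i = (C_1, σ_1, …, C_d, σ_d, R1, R2) stacked over beats."""
        return np.hstack([*self.lead_features, self.rr])

    def blocks(self) -> _Blocks:
        """Column index groups of ``joint`` per source."""
        leads, offset = [], 0
        for F in self.lead_features:
            leads.append(tuple(range(offset, offset + F.shape[1])))
            offset += F.shape[1]
        return _Blocks(leads=leads, rr=tuple(range(offset, offset + 2)))


def assemble_representations(
    lead_fits: list[list[HermiteFit]],
    rr: RRFeatures,
    symbols: list[str] | None = None,
) -> BeatRepresentation:
    """Bundle per-lead Hermite fits (d lists of n fits) and RR features."""
    if not lead_fits:
        raise ValueError("need at least one lead")
    n = len(lead_fits[0])
    if any(len(fits) != n for fits in lead_fits):
        raise ValueError("all leads must be fitted for all beats")
    if n != len(rr.r1):
        raise ValueError("Hermite fits and RR features disagree on beat count")
    blocks = [np.array([fit.vector for fit in fits]) for fits in lead_fits]
    return BeatRepresentation(lead_features=blocks, rr=rr.matrix, symbols=symbols)


def featurize_record(
    beats: BeatSeries,
    N: int = DEFAULT_N,
    sigma_grid: np.ndarray | None = None,
    width: float = DEFAULT_WINDOW,
) -> BeatRepresentation:
    """Full extraction pipeline for one recording.

    For every annotated beat and every lead: extract the baseline-
    corrected window, fit the Hermite representation; then compute the
    RR features from the annotation times.
    """
    lead_fits: list[list[HermiteFit]] = []
    for r in range(beats.n_leads):
        signal = beats.signals[:, r]
        fits = [
            fit_hermite(extract_beat_window(signal, beats.fs, t, width), beats.fs,
                        N=N, sigma_grid=sigma_grid)
            for t in beats.beat_times
        ]
        lead_fits.append(fits)
    rr = rr_features(beats.beat_times)
    return assemble_representations(lead_fits, rr, symbols=beats.beat_symbols)
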