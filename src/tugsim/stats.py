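"""Track classification and weighted trajectory statistics.

Implements the quantification layer applied to segmented tracks:

* classification of tracks into minus / plus / reversal / stationary from
  the signs of their runs, plus a taxonomy of pauses (reversal pause when
  the flanking runs have opposite signs, non-reversal otherwise) and of
  instantaneous reversals (adjacent opposite-sign runs with no pause
  between);
* velocities (frame-to-frame instantaneous velocities; run velocities as
  their arithmetic mean within a run);
* the distance-weighted spatial pause frequency with its weighted SD / SEM;
* a weighted two-sample Kolmogorov--Smirnov test built on the weighted
  ECDF, with Bonferroni correction for multiple comparisons;
* resampling of long simulated tracks into pieces matching an experimental
  track-duration distribution, with per-piece weights;
* the vesicle elongation index (long - short)/(long + short).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import distributions

from .segmentation import PAUSE, RUN_NEG, RUN_POS, Segment
from .simulate import Track

__all__ = [
    "WeightedSample",
    "TrackClassification",
    "PauseFrequencyResult",
    "instantaneous_velocities",
    "run_mean_velocity",
    "classify_track",
    "spatial_pause_frequency",
    "weighted_mean_sd_sem",
    "weighted_ecdf",
    "weighted_ks_2samp",
    "bonferroni",
    "resample_to_durations",
    "elongation_index",
]


@dataclass
class WeightedSample:
    """Values with normalized non-negative weights (sum to 1)."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.weights = np.asarray(self.weights, float)
        if self.values.shape != self.weights.shape or self.values.ndim != 1:
            raise ValueError("values and weights must be equal-length 1-d arrays")
        if len(self.values) == 0:
            raise ValueError("sample must be non-empty")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 (got %r)" % total)

    @classmethod
    def uniform(cls, values) -> "WeightedSample":
        values = np.asarray(values, float)
        n = len(values)
        return cls(values, np.full(n, 1.0 / n))

    @classmethod
    def from_weights(cls, values, weights) -> "WeightedSample":
        """Normalize raw non-negative weights to sum to 1."""
        weights = np.asarray(weights, float)
        return cls(np.asarray(values, float), weights / weights.sum())

    @property
    def n_effective(self) -> float:
        """Kish effective sample size (sum w)^2 / sum w^2 = 1 / sum w^2."""
        return 1.0 / float(np.sum(self.weights**2))


# ---------------------------------------------------------------------------
# velocities


def instantaneous_velocities(track: Track) -> np.ndarray:
    """Frame-to-frame velocities (nm/s), length N-1."""
    if len(track) < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(track.x) / np.diff(track.t)


def run_mean_velocity(track: Track, segment: Segment) -> float:
    """Arithmetic mean of the instantaneous velocities inside a run
    segment (nm/s)."""
    if not segment.is_run:
        raise ValueError("segment is not a run")
    v = np.diff(track.x[segment.i_start : segment.i_end + 1]) / np.diff(
        track.t[segment.i_start : segment.i_end + 1]
    )
    return float(np.mean(v))


# ---------------------------------------------------------------------------
# classification


MINUS = "minus"
PLUS = "plus"
REVERSAL = "reversal"
STATIONARY = "stationary"


@dataclass
class TrackClassification:
    """Directional class of one track plus its pause/reversal taxonomy.

    ``pause_kinds`` has one entry per pause segment: 'reversal' when the
    nearest runs before and after the pause have opposite signs,
    'non_reversal' when they share a sign, 'edge' when a flanking run is
    missing (pause at a track end).  ``n_instant_reversals`` counts
    opposite-sign run pairs with no pause between them.
    """

    label: str
    n_runs_pos: int
    n_runs_neg: int
    n_pauses: int
    pause_kinds: list = field(default_factory=list)
    n_instant_reversals: int = 0

    @property
    def n_reversal_events(self) -> int:
        """Number of run-sign changes along the track."""
        return self.n_instant_reversals + sum(
            1 for k in self.pause_kinds if k == "reversal"
        )


def classify_track(segments: list[Segment]) -> TrackClassification:
    """Classify a segmented track from the signs of its runs.

    minus = only negative runs, plus = only positive runs, reversal = at
    least one of each, stationary = no runs at all.
    """
    if not segments:
        raise ValueError("empty segment list")
    n_pos = sum(1 for s in segments if s.kind == RUN_POS)
    n_neg = sum(1 for s in segments if s.kind == RUN_NEG)
    n_pause = sum(1 for s in segments if s.kind == PAUSE)
    if n_pos and n_neg:
        label = REVERSAL
    elif n_pos:
        label = PLUS
    elif n_neg:
        label = MINUS
    else:
        label = STATIONARY

    # pause taxonomy: compare the nearest run on each side of every pause
    kinds = [s.kind for s in segments]
    pause_kinds = []
    for i, k in enumerate(kinds):
        if k != PAUSE:
            continue
        before = next((kinds[j] for j in range(i - 1, -1, -1) if kinds[j] != PAUSE), None)
        after = next((kinds[j] for j in range(i + 1, len(kinds)) if kinds[j] != PAUSE), None)
        if before is None or after is None:
            pause_kinds.append("edge")
        elif before == after:
            pause_kinds.append("non_reversal")
        else:
            pause_kinds.append("reversal")

    n_instant = sum(
        1
        for a, b in zip(kinds[:-1], kinds[1:])
        if {a, b} == {RUN_POS, RUN_NEG}
    )
    return TrackClassification(label, n_pos, n_neg, n_pause, pause_kinds, n_instant)


# ---------------------------------------------------------------------------
# weighted estimators


def weighted_mean_sd_sem(values, weights) -> tuple[float, float, float]:
    """Distance-weighted mean, SD and SEM.

    mean = sum w_i v_i with normalized weights;
    SD   = sqrt( sum w_i (v_i - mean)^2 / ((N-1)/N) );
    SEM  = SD / sqrt(N-1).
    At N = 1 the SD/SEM are undefined and returned as 0 with a warning.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    w = weights / weights.sum()
    n = len(values)
    mean = float(np.sum(w * values))
    if n < 2:
        warnings.warn("SD/SEM undefined for a single value; returning 0")
        return mean, 0.0, 0.0
    var = float(np.sum(w * (values - mean) ** 2) / ((n - 1) / n))
    sd = float(np.sqrt(var))
    return mean, sd, sd / np.sqrt(n - 1)


@dataclass
class PauseFrequencyResult:
    """Weighted spatial pause frequency (1/um) across a set of tracks."""

    weighted_mean: float
    weighted_sd: float
    weighted_sem: float
    n_tracks: int
    sample: WeightedSample | None = None


def spatial_pause_frequency(per_track) -> PauseFrequencyResult:
    """Distance-weighted spatial pause frequency of a set of tracks.

    ``per_track`` is an iterable of (n_pauses, distance_travelled_um) pairs;
    distances enter as absolute values, and each track's pause frequency
    x_f = n_pauses / |distance| is weighted by its share of the total
    distance.  Zero-distance tracks are excluded with a warning.
    """
    pairs = [(int(p), abs(float(d))) for p, d in per_track]
    kept = [(p, d) for p, d in pairs if d > 0]
    if len(kept) < len(pairs):
        warnings.warn(
            f"excluded {len(pairs) - len(kept)} track(s) with zero distance"
        )
    if not kept:
        raise ValueError("no tracks with positive distance")
    pauses = np.array([p for p, _ in kept], float)
    dist = np.array([d for _, d in kept], float)
    xf = pauses / dist
    mean, sd, sem = weighted_mean_sd_sem(xf, dist)
    return PauseFrequencyResult(
        mean, sd, sem, len(kept), WeightedSample.from_weights(xf, dist)
    )


# ---------------------------------------------------------------------------
# weighted ECDF / KS


def weighted_ecdf(sample: WeightedSample):
    """(sorted values, cumulative weights): F^w(x_i) = sum_{j<=i} w_j."""
    order = np.argsort(sample.values, kind="mergesort")
    return sample.values[order], np.cumsum(sample.weights[order])


def _ecdf_at(values_sorted, cumw, q):
    idx = np.searchsorted(values_sorted, q, side="right")
    return np.where(idx > 0, np.concatenate(([0.0], cumw))[idx], 0.0)


def weighted_ks_2samp(a: WeightedSample, b: WeightedSample):
    """Two-sample, two-tailed Kolmogorov--Smirnov test on weighted ECDFs.

    The statistic is the supremum over the pooled values of the difference
    between the two weighted ECDFs.  The p-value uses the standard
    asymptotic two-sample distribution with each sample entering through
    its effective size n_eff = (sum w)^2 / sum w^2, so that with uniform
    weights the test reduces exactly to the classical asymptotic KS test.
    Returns (statistic, p_value).
    """
    va, ca = weighted_ecdf(a)
    vb, cb = weighted_ecdf(b)
    pooled = np.concatenate([va, vb])
    fa = _ecdf_at(va, ca, pooled)
    fb = _ecdf_at(vb, cb, pooled)
    d = float(np.max(np.abs(fa - fb)))
    na, nb = a.n_effective, b.n_effective
    en = na * nb / (na + nb)
    p = float(np.clip(distributions.kstwo.sf(d, int(round(en))), 0.0, 1.0))
    return d, p


def bonferroni(p: float, m_comparisons: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    return min(1.0, p * m_comparisons)


# ---------------------------------------------------------------------------
# resampling of simulated tracks to experimental durations


def resample_to_durations(
    sim_tracks: list[Track],
    target_durations,
    rng: np.random.Generator | None = None,
) -> list[tuple[Track, float]]:
    """Cut simulated tracks into pieces with experiment-like durations.

    Each track is chopped sequentially: a duration is drawn (with
    replacement) from ``target_durations``, the corresponding leading piece
    is split off, and the process repeats; a trailing remainder shorter
    than its drawn duration is discarded.  Every piece carries the weight
    1 / (total number of pieces), so the pieces of one condition together
    weigh like one experimental data set.  Returns (piece, weight) pairs.
    """
    target = np.asarray(list(target_durations), float)
    if len(target) == 0 or np.any(target <= 0):
        raise ValueError("target durations must be positive and non-empty")
    rng = np.random.default_rng() if rng is None else rng
    pieces: list[Track] = []
    for track in sim_tracks:
        if len(track) < 2:
            continue
        dt = track.sample_interval
        i0 = 0
        n = len(track)
        k = 0
        while True:
            dur = float(rng.choice(target))
            n_pts = max(2, int(round(dur / dt)) + 1)
            if i0 + n_pts > n:
                break  # remainder shorter than the drawn duration: discarded
            pieces.append(
                track.slice(i0, i0 + n_pts, track_id=f"{track.track_id}/p{k}")
            )
            i0 += n_pts - 1  # pieces share their boundary sample
            k += 1
    if not pieces:
        return []
    w = 1.0 / len(pieces)
    return [(p, w) for p in pieces]


# ---------------------------------------------------------------------------
# shape


def elongation_index(long_axis: float, short_axis: float) -> float:
    """(long - short) / (long + short); 0 for a sphere, -> 1 when highly
    elongated."""
    if not (long_axis >= short_axis > 0):
        raise ValueError("need long >= short > 0")
    return (long_axis - short_axis) / (long_axis + short_axis)
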