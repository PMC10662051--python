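"""Synthetic ground-truth tracks for validating segmentation and statistics.

Real tracks are piecewise phases of roughly constant velocity corrupted by
Gaussian localization noise (sub-pixel tracking of ~87 nm pixels resolves
positions to a few tens of nm).  :func:`make_track` generates exactly that
structure from an explicit blueprint, together with the ground-truth
run/pause segments obtained by applying the 100 nm/s slope and 500 nm
distance rules to the noiseless signal, so recovery can be scored without
circular use of the segmentation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motors import lognormal_from_median_iqr
from .segmentation import (
    MIN_RUN_DISTANCE_NM,
    PAUSE,
    PAUSE_SLOPE_NM_S,
    RUN_NEG,
    RUN_POS,
    Segment,
)
from .simulate import Track

__all__ = ["TrackBlueprint", "make_track", "make_duration_sample"]


@dataclass(frozen=True)
class TrackBlueprint:
    """Ground-truth description of one piecewise-linear track.

    ``change_times`` are the segment boundaries in s, starting at 0 and
    ending at the track duration; ``segment_velocities`` (nm/s, one per
    interval, sign = direction) define the noiseless signal.  Velocities of
    magnitude below 100 nm/s encode intended pauses.
    """

    change_times: tuple = (0.0, 10.0)
    segment_velocities: tuple = (800.0,)
    noise_sd: float = 20.0  # nm localization noise
    sample_interval: float = 0.1  # s
    x0: float = 0.0

    def __post_init__(self) -> None:
        ct = np.asarray(self.change_times, float)
        if len(ct) != len(self.segment_velocities) + 1:
            raise ValueError("need len(change_times) == len(velocities) + 1")
        if ct[0] != 0.0:
            raise ValueError("first change time must be 0")
        if np.any(np.diff(ct) <= 0):
            raise ValueError("change times must be strictly increasing")
        if self.noise_sd < 0 or self.sample_interval <= 0:
            raise ValueError("invalid noise_sd or sample_interval")


def _noiseless(bp: TrackBlueprint, t: np.ndarray) -> np.ndarray:
    ct = np.asarray(bp.change_times, float)
    v = np.asarray(bp.segment_velocities, float)
    knots_x = bp.x0 + np.concatenate(([0.0], np.cumsum(v * np.diff(ct))))
    return np.interp(t, ct, knots_x)


def make_track(
    bp: TrackBlueprint,
    rng: np.random.Generator | None = None,
    track_id: str = "synth-0",
) -> tuple[Track, list[Segment]]:
    """Sampled noisy track plus its ground-truth segments.

    The signal is the piecewise-linear integral of the blueprint
    velocities; iid Gaussian noise of SD ``noise_sd`` is added per sample.
    Ground-truth segment kinds come from the noiseless signal: |v| < 100
    nm/s or |net distance| < 500 nm -> pause, else run in the sign of v.
    """
    rng = np.random.default_rng() if rng is None else rng
    ct = np.asarray(bp.change_times, float)
    duration = ct[-1]
    n = int(round(duration / bp.sample_interval)) + 1
    t = bp.sample_interval * np.arange(n)
    clean = _noiseless(bp, t)
    x = clean + rng.normal(0.0, bp.noise_sd, size=n)
    track = Track(track_id, t, x, meta=dict(noise_sd=bp.noise_sd))

    truth: list[Segment] = []
    for k, v in enumerate(bp.segment_velocities):
        i0 = int(round(ct[k] / bp.sample_interval))
        i1 = min(int(round(ct[k + 1] / bp.sample_interval)), n - 1)
        dist = v * (ct[k + 1] - ct[k])
        if abs(v) < PAUSE_SLOPE_NM_S or abs(dist) < MIN_RUN_DISTANCE_NM:
            kind = PAUSE
        else:
            kind = RUN_POS if v > 0 else RUN_NEG
        truth.append(
            Segment(
                kind,
                i0,
                i1,
                float(t[i0]),
                float(t[i1]),
                float(clean[i0]),
                float(clean[i1]),
            )
        )
    return track, truth


def make_duration_sample(
    median: float,
    iqr: float,
    n: int,
    rng: np.random.Generator | None = None,
    sample_interval: float = 0.1,
) -> np.ndarray:
    """Log-normal track durations (s) with the given median and IQR.

    Matched through the exact quantile relations of the log-normal; values
    are floored at two sampling intervals so every duration can hold a
    minimal track piece.
    """
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng() if rng is None else rng
    mu, sigma = lognormal_from_median_iqr(median, iqr)
    draws = rng.lognormal(mu, sigma, size=n)
    return np.maximum(draws, 2.0 * sample_interval)
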