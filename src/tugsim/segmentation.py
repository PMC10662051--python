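"""Change-point segmentation of position--time tracks.

A track is approximated by a continuous piecewise-linear function whose
knots ("change points") are optimized by simulated annealing against the
cost

    H = sum_i (x_i - f(t_i))^2  +  mu * N_cp         [nm^2]

where ``N_cp`` counts interior change points (the two endpoint knots are
pinned to the track ends).  Proposals shift a knot in (t, x), add a knot at
a random data point, or delete a knot; acceptance is Metropolis with
inverse temperature beta, equilibrated at beta = 0.005 for 4000 updates and
then cooled by one decade per 1000 updates up to beta = 50.

The optimized knots are then post-processed into run/pause segments by three
rules, applied in order: a segment with |slope| < 100 nm/s is a pause;
one-point segments are merged into the following segment; a run whose net
|distance| < 500 nm becomes a pause.

The module exposes a statsmodels-flavoured front end
(:class:`ChangePointModel` / :class:`SegmentationResult`) on top of the
functional pieces (:func:`anneal`, :func:`postprocess`, :func:`cost`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .simulate import MAX_SEED, Track

__all__ = [
    "AnnealConfig",
    "Segment",
    "eval_piecewise",
    "cost",
    "propose",
    "anneal",
    "postprocess",
    "segment_track",
    "ChangePointModel",
    "SegmentationResult",
    "PAUSE_SLOPE_NM_S",
    "MIN_RUN_DISTANCE_NM",
]

PAUSE_SLOPE_NM_S = 100.0
MIN_RUN_DISTANCE_NM = 500.0

RUN_POS = "run_pos"
RUN_NEG = "run_neg"
PAUSE = "pause"


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule and move set.

    ``mu_cost`` is the per-change-point penalty in nm^2.  The beta schedule
    starts at ``beta_init`` for ``equil_updates`` updates and is then
    multiplied by 10 every ``cooling_updates_per_decade`` updates until it
    reaches ``beta_final``.  ``eps_x`` (nm) and ``eps_t`` (s; None = two
    sampling intervals) set the shift-move amplitudes; ``n_cp_init`` (None =
    one knot per 5 s of track) sets the initial interior knot count.
    """

    mu_cost: float = 10_000.0
    beta_init: float = 0.005
    beta_final: float = 50.0
    equil_updates: int = 4000
    cooling_updates_per_decade: int = 1000
    eps_x: float = 200.0
    eps_t: float | None = None
    p_shift: float = 0.8
    p_add: float = 0.1
    p_remove: float = 0.1
    n_cp_init: int | None = None
    max_cp: int = 512
    merge_same_kind: bool = False

    def __post_init__(self) -> None:
        if abs(self.p_shift + self.p_add + self.p_remove - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if self.beta_final < self.beta_init:
            raise ValueError("beta_final must be >= beta_init")
        if self.mu_cost < 0:
            raise ValueError("mu_cost must be non-negative")

    def replace(self, **overrides) -> "AnnealConfig":
        return replace(self, **overrides)

    def betas(self) -> tuple[np.ndarray, np.ndarray]:
        """(beta values, updates per stage) of the full schedule."""
        stages = [self.beta_init]
        while stages[-1] * 10 <= self.beta_final * 1.0000001:
            stages.append(stages[-1] * 10)
        updates = [self.equil_updates] + [self.cooling_updates_per_decade] * (
            len(stages) - 1
        )
        return np.asarray(stages), np.asarray(updates, np.int64)

    def eps_t_for(self, sample_interval: float) -> float:
        return 2.0 * sample_interval if self.eps_t is None else self.eps_t

    def n_init_for(self, duration: float) -> int:
        if self.n_cp_init is not None:
            return self.n_cp_init
        return max(1, int(duration / 5.0))


@dataclass
class Segment:
    """One run/pause segment.

    ``i_start``/``i_end`` index the track samples; adjacent segments share
    their boundary sample, so the time intervals tile the track.  ``slope``
    is the end-to-end slope (x_end - x_start)/(t_end - t_start), which for
    uniformly sampled data equals the arithmetic mean of the instantaneous
    velocities inside the segment.
    """

    kind: str
    i_start: int
    i_end: int
    t_start: float
    t_end: float
    x_start: float
    x_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def distance(self) -> float:
        return self.x_end - self.x_start

    @property
    def slope(self) -> float:
        return self.distance / self.duration if self.duration > 0 else 0.0

    @property
    def mean_velocity(self) -> float:
        return self.slope

    @property
    def is_run(self) -> bool:
        return self.kind in (RUN_POS, RUN_NEG)


# ---------------------------------------------------------------------------
# cost machinery


def eval_piecewise(cp_t, cp_x, t):
    """Piecewise-linear interpolation through the change points at times
    ``t`` (scalar or array)."""
    cp_t = np.asarray(cp_t, float)
    cp_x = np.asarray(cp_x, float)
    if len(cp_t) < 2:
        raise ValueError("need at least the two endpoint change points")
    if np.any(np.diff(cp_t) <= 0):
        raise ValueError("change-point times must be strictly increasing")
    return np.interp(t, cp_t, cp_x)


def cost(track: Track, cp_t, cp_x, mu_cost: float = 10_000.0) -> float:
    """Total cost H = E_err + mu * N_cp (nm^2), N_cp = interior knots."""
    f = eval_piecewise(cp_t, cp_x, track.t)
    e_err = float(np.sum((track.x - f) ** 2))
    return e_err + mu_cost * (len(np.asarray(cp_t)) - 2)


# -- compiled residual helpers ----------------------------------------------


@njit(cache=True)
def _resid_line(t, x, i0, i1, ta, xa, tb, xb):
    # residual sum over data indices [i0, i1) against the line (ta,xa)-(tb,xb)
    s = 0.0
    slope = (xb - xa) / (tb - ta)
    for i in range(i0, i1):
        r = x[i] - (xa + slope * (t[i] - ta))
        s += r * r
    return s


@njit(cache=True)
def _one_seg_resid(t, x, ta, xa, tb, xb, include_end):
    i0 = np.searchsorted(t, ta)
    i1 = len(t) if include_end else np.searchsorted(t, tb)
    return _resid_line(t, x, i0, i1, ta, xa, tb, xb)


@njit(cache=True)
def _two_seg_resid(t, x, ta, xa, tm, xm, tb, xb, include_end):
    i0 = np.searchsorted(t, ta)
    im = np.searchsorted(t, tm)
    i1 = len(t) if include_end else np.searchsorted(t, tb)
    return _resid_line(t, x, i0, im, ta, xa, tm, xm) + _resid_line(
        t, x, im, i1, tm, xm, tb, xb
    )


@njit(cache=True)
def _anneal_core(
    t,
    x,
    n_init,
    mu,
    betas,
    n_updates,
    eps_x,
    eps_t,
    p_shift,
    p_add,
    seed,
    max_cp,
):
    """Simulated annealing over change-point configurations.

    Maintains H incrementally: every accepted move adjusts H by a locally
    recomputed residual difference.  Returns (cp_t, cp_x, H_final,
    H_initial).
    """
    np.random.seed(seed)
    n_data = len(t)
    cp_t = np.empty(max_cp + 2)
    cp_x = np.empty(max_cp + 2)
    m = n_init + 2
    cp_t[0] = t[0]
    cp_x[0] = x[0]
    cp_t[m - 1] = t[-1]
    cp_x[m - 1] = x[-1]
    span = t[-1] - t[0]
    for k in range(1, n_init + 1):
        tk = t[0] + span * k / (n_init + 1)
        j = np.searchsorted(t, tk)
        if j <= 0:
            xk = x[0]
        elif j >= n_data:
            xk = x[-1]
        else:
            w = (tk - t[j - 1]) / (t[j] - t[j - 1])
            xk = x[j - 1] + w * (x[j] - x[j - 1])
        cp_t[k] = tk
        cp_x[k] = xk

    h = mu * (m - 2)
    for k in range(m - 1):
        h += _one_seg_resid(
            t, x, cp_t[k], cp_x[k], cp_t[k + 1], cp_x[k + 1], k + 1 == m - 1
        )
    h_init = h

    for stage in range(len(betas)):
        beta = betas[stage]
        for _ in range(n_updates[stage]):
            u = np.random.random()
            if u < p_shift:
                if m <= 2:
                    continue
                k = 1 + int(np.random.random() * (m - 2))
                tn = cp_t[k] + eps_t * (np.random.random() - 0.5)
                xn = cp_x[k] + eps_x * (np.random.random() - 0.5)
                if tn <= cp_t[k - 1] or tn >= cp_t[k + 1]:
                    continue  # breaks ordering: rejected outright
                last = k + 1 == m - 1
                old = _two_seg_resid(
                    t, x, cp_t[k - 1], cp_x[k - 1], cp_t[k], cp_x[k],
                    cp_t[k + 1], cp_x[k + 1], last,
                )
                new = _two_seg_resid(
                    t, x, cp_t[k - 1], cp_x[k - 1], tn, xn,
                    cp_t[k + 1], cp_x[k + 1], last,
                )
                dh = new - old
                if dh <= 0.0 or np.random.random() < math.exp(-beta * dh):
                    cp_t[k] = tn
                    cp_x[k] = xn
                    h += dh
            elif u < p_shift + p_add:
                if m - 2 >= max_cp:
                    continue
                i = int(np.random.random() * n_data)
                ti = t[i]
                xi = x[i]
                if ti <= cp_t[0] or ti >= cp_t[m - 1]:
                    continue
                j = np.searchsorted(cp_t[:m], ti) - 1
                if ti == cp_t[j] or ti == cp_t[j + 1]:
                    continue  # collides with an existing knot
                last = j + 1 == m - 1
                old = _one_seg_resid(
                    t, x, cp_t[j], cp_x[j], cp_t[j + 1], cp_x[j + 1], last
                )
                new = _two_seg_resid(
                    t, x, cp_t[j], cp_x[j], ti, xi, cp_t[j + 1], cp_x[j + 1], last
                )
                dh = new - old + mu
                if dh <= 0.0 or np.random.random() < math.exp(-beta * dh):
                    for q in range(m, j + 1, -1):
                        cp_t[q] = cp_t[q - 1]
                        cp_x[q] = cp_x[q - 1]
                    cp_t[j + 1] = ti
                    cp_x[j + 1] = xi
                    m += 1
                    h += dh
            else:
                if m <= 2:
                    continue  # nothing removable: counts as an update
                k = 1 + int(np.random.random() * (m - 2))
                last = k + 1 == m - 1
                old = _two_seg_resid(
                    t, x, cp_t[k - 1], cp_x[k - 1], cp_t[k], cp_x[k],
                    cp_t[k + 1], cp_x[k + 1], last,
                )
                new = _one_seg_resid(
                    t, x, cp_t[k - 1], cp_x[k - 1], cp_t[k + 1], cp_x[k + 1], last
                )
                dh = new - old - mu
                if dh <= 0.0 or np.random.random() < math.exp(-beta * dh):
                    for q in range(k, m - 1):
                        cp_t[q] = cp_t[q + 1]
                        cp_x[q] = cp_x[q + 1]
                    m -= 1
                    h += dh
    return cp_t[:m].copy(), cp_x[:m].copy(), h, h_init


# ---------------------------------------------------------------------------
# reference move generator (mirrors the compiled move set; used for testing
# and as the documented definition of the proposal distribution)


def propose(
    cp_t,
    cp_x,
    track: Track,
    config: AnnealConfig,
    rng: np.random.Generator,
):
    """One proposal from the annealer's move set.

    Returns ``(move, new_cp_t, new_cp_x)`` where move is one of
    'shift'/'add'/'remove'; proposals that would break time ordering or
    leave the track interval return the unchanged configuration (they still
    count as updates).
    """
    cp_t = np.asarray(cp_t, float).copy()
    cp_x = np.asarray(cp_x, float).copy()
    m = len(cp_t)
    eps_t = config.eps_t_for(track.sample_interval)
    u = rng.random()
    if u < config.p_shift:
        if m <= 2:
            return "shift", cp_t, cp_x
        k = 1 + int(rng.random() * (m - 2))
        tn = cp_t[k] + eps_t * (rng.random() - 0.5)
        xn = cp_x[k] + config.eps_x * (rng.random() - 0.5)
        if tn <= cp_t[k - 1] or tn >= cp_t[k + 1]:
            return "shift", cp_t, cp_x
        cp_t[k] = tn
        cp_x[k] = xn
        return "shift", cp_t, cp_x
    if u < config.p_shift + config.p_add:
        i = int(rng.random() * len(track))
        ti, xi = track.t[i], track.x[i]
        if ti <= cp_t[0] or ti >= cp_t[-1] or np.any(cp_t == ti):
            return "add", cp_t, cp_x
        j = int(np.searchsorted(cp_t, ti))
        return "add", np.insert(cp_t, j, ti), np.insert(cp_x, j, xi)
    if m <= 2:
        return "remove", cp_t, cp_x
    k = 1 + int(rng.random() * (m - 2))
    return "remove", np.delete(cp_t, k), np.delete(cp_x, k)


def anneal(
    track: Track,
    config: AnnealConfig | None = None,
    seed: int = 0,
):
    """Optimize the change points of ``track``; returns (cp_t, cp_x, H)."""
    config = AnnealConfig() if config is None else config
    if len(track) < 2:
        raise ValueError("track must have at least 2 samples")
    betas, n_updates = config.betas()
    cp_t, cp_x, h, _ = _anneal_core(
        np.ascontiguousarray(track.t),
        np.ascontiguousarray(track.x),
        config.n_init_for(track.duration),
        config.mu_cost,
        betas,
        n_updates,
        config.eps_x,
        config.eps_t_for(track.sample_interval),
        config.p_shift,
        config.p_add,
        seed % MAX_SEED,
        config.max_cp,
    )
    return cp_t, cp_x, float(h)


# ---------------------------------------------------------------------------
# post-processing into labeled segments


def _label(slope: float) -> str:
    if abs(slope) < PAUSE_SLOPE_NM_S:
        return PAUSE
    return RUN_POS if slope > 0 else RUN_NEG


def postprocess(
    track: Track,
    cp_t,
    cp_x=None,
    merge_same_kind: bool = False,
) -> list[Segment]:
    """Label the inter-change-point segments as runs and pauses.

    Rules, in order: |end-to-end slope| < 100 nm/s -> pause; segments one
    data point long are merged into the following segment; a run with net
    |distance| < 500 nm becomes a pause.  Segment boundaries are the data
    samples nearest after each change-point time; adjacent segments share
    their boundary sample.  ``merge_same_kind`` optionally fuses adjacent
    segments of identical kind afterwards (off by default).
    """
    cp_t = np.asarray(cp_t, float)
    n = len(track)
    if n < 2:
        raise ValueError("track must have at least 2 samples")
    bounds = np.searchsorted(track.t, cp_t[1:-1])
    idx = [0] + [int(b) for b in bounds] + [n - 1]
    # one-point (or empty) segments collapse into the following segment
    keep = [0]
    for b in idx[1:-1]:
        if b > keep[-1]:
            keep.append(b)
    if keep[-1] >= n - 1:
        keep.pop()
    keep.append(n - 1)
    if len(keep) >= 3 and keep[-1] == keep[-2]:
        keep.pop(-2)

    segments: list[Segment] = []
    for a, b in zip(keep[:-1], keep[1:]):
        t0, t1 = float(track.t[a]), float(track.t[b])
        x0, x1 = float(track.x[a]), float(track.x[b])
        slope = (x1 - x0) / (t1 - t0)
        kind = _label(slope)
        if kind != PAUSE and abs(x1 - x0) < MIN_RUN_DISTANCE_NM:
            kind = PAUSE
        segments.append(Segment(kind, a, b, t0, t1, x0, x1))

    if merge_same_kind:
        merged: list[Segment] = []
        for seg in segments:
            if merged and merged[-1].kind == seg.kind:
                prev = merged[-1]
                merged[-1] = Segment(
                    prev.kind,
                    prev.i_start,
                    seg.i_end,
                    prev.t_start,
                    seg.t_end,
                    prev.x_start,
                    seg.x_end,
                )
            else:
                merged.append(seg)
        segments = merged
    return segments


def segment_track(
    track: Track,
    config: AnnealConfig | None = None,
    seed: int = 0,
) -> "SegmentationResult":
    """Anneal + post-process in one call."""
    return ChangePointModel(track, config).fit(seed=seed)


# ---------------------------------------------------------------------------
# model / results front end


class ChangePointModel:
    """Piecewise-linear change-point model of a single track.

    Parameters
    ----------
    track : Track
        Uniformly sampled position--time series.
    config : AnnealConfig, optional
        Cost and annealing-schedule settings.
    """

    def __init__(self, track: Track, config: AnnealConfig | None = None):
        self.track = track
        self.config = AnnealConfig() if config is None else config

    @classmethod
    def from_arrays(cls, t, x, track_id="track", config=None):
        return cls(Track(track_id, np.asarray(t), np.asarray(x)), config)

    def cost(self, cp_t, cp_x) -> float:
        return cost(self.track, cp_t, cp_x, self.config.mu_cost)

    def fit(self, seed: int = 0) -> "SegmentationResult":
        """Anneal the change points and label run/pause segments."""
        cp_t, cp_x, h = anneal(self.track, self.config, seed=seed)
        segments = postprocess(
            self.track, cp_t, cp_x, merge_same_kind=self.config.merge_same_kind
        )
        return SegmentationResult(self, cp_t, cp_x, h, segments, seed)


class SegmentationResult:
    """Fitted segmentation: change points, cost, and labeled segments."""

    def __init__(self, model, cp_t, cp_x, cost_value, segments, seed):
        self.model = model
        self.track = model.track
        self.cp_t = cp_t
        self.cp_x = cp_x
        self.cost = cost_value
        self.segments = segments
        self.seed = seed

    @property
    def n_changepoints(self) -> int:
        return len(self.cp_t) - 2

    def predict(self, t=None):
        """Fitted piecewise-linear position at times ``t`` (default: the
        track's own sample times)."""
        t = self.track.t if t is None else t
        return eval_piecewise(self.cp_t, self.cp_x, t)

    def summary(self) -> pd.DataFrame:
        rows = [
            dict(
                seg_index=i,
                kind=s.kind,
                t_start=s.t_start,
                t_end=s.t_end,
                x_start=s.x_start,
                x_end=s.x_end,
                duration_s=s.duration,
                distance_nm=s.distance,
                mean_velocity_nm_s=s.mean_velocity,
            )
            for i, s in enumerate(self.segments)
        ]
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Track, fitted piecewise-linear approximation and segment kinds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.track.t, self.track.x, ".", ms=2, color="0.6", label="data")
        ax.plot(self.cp_t, self.cp_x, "o-", color="C3", label="fit")
        colors = {RUN_POS: "C2", RUN_NEG: "C0", PAUSE: "C4"}
        for s in self.segments:
            ax.axvspan(s.t_start, s.t_end, alpha=0.12, color=colors[s.kind])
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position (nm)")
        ax.legend(frameon=False)
        return ax
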