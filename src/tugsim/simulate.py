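"""Cargo-level simulation: configuration, team sampling, and the public
wrapper around the compiled Gillespie engine.

A cargo carries a fixed team of DDB and KIF16B motors.  The team size is
drawn from a Gaussian whose width grows as ``sigma_coeff * sqrt(mu)`` with
the mean team size (mimicking the cargo-to-cargo fluctuation of motor
numbers at fixed incubation conditions), and is split between the species
binomially according to the mean numbers.  Motors attach to a 7-lane
lattice, step, diffuse and detach with the force-dependent rates of
:mod:`tugsim.kinetics`; after every state change the cargo relaxes by
Metropolis diffusion in the potential of the attached springs.  Positions
are sampled on a fixed grid after a relaxation window, emulating imaging at
10 frames/s.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _engine
from .motors import MotorParams, ddb_params, kif16b_params

__all__ = [
    "SimConfig",
    "Track",
    "sample_motor_count",
    "split_species",
    "assign_activity",
    "sample_lane",
    "cargo_force",
    "relax_cargo",
    "simulate_cargo",
    "simulate_cargoes",
    "single_motor_runs",
    "single_motor_tracks",
]

MAX_SEED = 2**31 - 1


def _subseed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, np.uint32)[0] % MAX_SEED) + 1


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one experiment.

    ``mean_n_ddb`` / ``mean_n_kif`` are the mean motor numbers in the
    attachment area; ``fixed_counts`` bypasses the random team draw with an
    exact (n_ddb, n_kif) pair.  ``atp=None`` means saturating ATP.  Times in
    s, lengths in nm, energies in pN nm.
    """

    mean_n_ddb: float = 8.0
    mean_n_kif: float = 14.0
    sigma_coeff: float = 1.0683
    atp: float | None = 2.5  # mM; None = saturating
    kbt: float = 4.11  # pN nm
    lane_cut: int = 3  # lanes -3..+3 (7 protofilaments)
    relax_time: float = 4.0  # s, pre-measurement window
    max_time: float = 80.0  # s, hard termination
    sample_interval: float = 0.1  # s (10 frames/s imaging)
    metropolis_proposals: int = 100
    metropolis_step: float = 8.0  # nm
    stall_rate: float = 0.1  # 1/s, stepping rate pinned at stall
    detachment_load_sign: int = 1  # +1 Bell (slip), -1 literal catch variant
    fixed_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.max_time <= self.relax_time:
            raise ValueError("max_time must exceed relax_time")
        if self.mean_n_ddb < 0 or self.mean_n_kif < 0:
            raise ValueError("mean motor numbers must be non-negative")
        if self.detachment_load_sign not in (-1, 1):
            raise ValueError("detachment_load_sign must be +1 or -1")

    def replace(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Track:
    """A sampled position--time series for one cargo.

    ``t`` (s) is uniformly spaced; ``x`` (nm) is the cargo position with the
    microtubule plus-end along +x.  ``extras`` may carry per-sample attached
    motor counts, the summed motor force magnitude and similar channels;
    ``meta`` carries provenance (seed, config hash, motor counts).
    """

    track_id: str
    t: np.ndarray
    x: np.ndarray
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        if self.t.shape != self.x.shape:
            raise ValueError("t and x must have the same length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError(f"track {self.track_id}: t must be increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"track {self.track_id}: sampling must be uniform"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sample_interval(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else math.nan

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def slice(self, i0: int, i1: int, track_id: str | None = None) -> "Track":
        extras = {k: np.asarray(v)[i0:i1] for k, v in self.extras.items()}
        return Track(
            track_id or f"{self.track_id}:{i0}-{i1}",
            self.t[i0:i1],
            self.x[i0:i1],
            extras,
            dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"track_id": self.track_id, "t_s": self.t, "x_nm": self.x}
        for k, v in self.extras.items():
            data[k] = np.asarray(v)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# team sampling


def sample_motor_count(
    mu: float,
    sigma_coeff: float = 1.0683,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Total motor number(s): round(Normal(mu, sigma_coeff*sqrt(mu))),
    clipped at zero."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    draw = rng.normal(mu, sigma_coeff * math.sqrt(mu), size=size)
    out = np.maximum(np.rint(draw), 0.0)
    return int(out) if size is None else out.astype(np.int64)


def split_species(
    total,
    mean_d: float,
    mean_k: float,
    rng: np.random.Generator | None = None,
):
    """Binomial split of ``total`` motors into (n_ddb, n_kif) with
    probability mean_d / (mean_d + mean_k) for DDB."""
    if mean_d < 0 or mean_k < 0:
        raise ValueError("mean motor numbers must be non-negative")
    total_arr = np.asarray(total)
    if mean_d + mean_k <= 0:
        if np.any(total_arr > 0):
            raise ValueError("cannot split motors when both means are zero")
        return total_arr * 0, total_arr * 0
    rng = np.random.default_rng() if rng is None else rng
    n_d = rng.binomial(total, mean_d / (mean_d + mean_k))
    return n_d, total - n_d


ACTIVITY_LABELS = ("active", "inactive", "diffusive")


def assign_activity(
    params: MotorParams,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Activity class draw(s): 'inactive' w.p. frac_inactive, 'diffusive'
    w.p. frac_diffusive, else 'active'.  Re-drawn at every attachment."""
    rng = np.random.default_rng() if rng is None else rng
    u = rng.random(size=size)
    codes = np.where(
        u < params.frac_inactive,
        _engine.ACT_INACTIVE,
        np.where(
            u < params.frac_inactive + params.frac_diffusive,
            _engine.ACT_DIFFUSIVE,
            _engine.ACT_ACTIVE,
        ),
    )
    if size is None:
        return ACTIVITY_LABELS[int(codes)]
    return codes


def sample_lane(
    rng: np.random.Generator | None = None,
    size: int | None = None,
    cut: int = 3,
):
    """Lane indices in [-cut, cut], P(l) proportional to exp(-l^2/2)."""
    rng = np.random.default_rng() if rng is None else rng
    lanes = np.arange(-cut, cut + 1)
    p = np.exp(-0.5 * lanes**2)
    p /= p.sum()
    out = rng.choice(lanes, size=size, p=p)
    return int(out) if size is None else out


# ---------------------------------------------------------------------------
# small python-facing physics helpers


def cargo_force(forces: Sequence[float]) -> float:
    """Cargo force readout: sum of the absolute motor forces (pN)."""
    return float(np.sum(np.abs(np.asarray(forces, float))))


def relax_cargo(
    x_v: float,
    head_positions: Sequence[float],
    params_list: Sequence[MotorParams],
    kbt: float = 4.11,
    n_proposals: int = 100,
    step: float = 8.0,
    seed: int = 0,
) -> float:
    """Metropolis relaxation of the cargo among explicit attached motors.

    Convenience wrapper over the compiled kernel for testing and
    prototyping; heads are given directly in nm (they are snapped to each
    species' lattice internally).
    """
    n = len(head_positions)
    if n == 0:
        return float(x_v)
    if len(params_list) != n:
        raise ValueError("one MotorParams per head position required")
    P = np.zeros((n, _engine.NPAR))
    sites = np.zeros(n, np.int64)
    for i, (h, p) in enumerate(zip(head_positions, params_list)):
        P[i] = p.as_array()
        sites[i] = int(round(h / p.step_size))
    sp = np.arange(n, dtype=np.int64)
    attached = np.ones(n, np.int64)
    np.random.seed(seed % MAX_SEED)
    return float(
        _engine.metropolis_relax(
            float(x_v), n, attached, sites, sp, P, kbt, n_proposals, step
        )
    )


# ---------------------------------------------------------------------------
# engine wrapper


def _run_engine(
    config: SimConfig,
    ddb: MotorParams,
    kif: MotorParams,
    n_d: int,
    n_k: int,
    seed: int,
    max_runs: int = 200_000,
):
    P = np.vstack([ddb.as_array(), kif.as_array()])
    n_samp = int(round((config.max_time - config.relax_time) / config.sample_interval)) + 2
    samp_x = np.empty(n_samp)
    samp_nd = np.empty(n_samp, np.int64)
    samp_nk = np.empty(n_samp, np.int64)
    samp_f = np.empty(n_samp)
    samp_h0 = np.empty(n_samp)
    run_sp = np.empty(max_runs, np.int64)
    run_act = np.empty(max_runs, np.int64)
    run_len = np.empty(max_runs)
    run_dur = np.empty(max_runs)
    run_t0 = np.empty(max_runs)
    atp = _engine_atp(config.atp)
    ns, nr, t_end = _engine.run_cargo(
        P,
        n_d,
        n_k,
        atp,
        config.kbt,
        config.relax_time,
        config.max_time,
        config.sample_interval,
        config.metropolis_proposals,
        config.metropolis_step,
        config.lane_cut,
        config.stall_rate,
        config.detachment_load_sign,
        seed,
        samp_x,
        samp_nd,
        samp_nk,
        samp_f,
        samp_h0,
        run_sp,
        run_act,
        run_len,
        run_dur,
        run_t0,
    )
    samples = dict(
        x=samp_x[:ns].copy(),
        n_att_ddb=samp_nd[:ns].copy(),
        n_att_kif=samp_nk[:ns].copy(),
        f_cargo_pN=samp_f[:ns].copy(),
        head0_nm=samp_h0[:ns].copy(),
    )
    runs = pd.DataFrame(
        dict(
            species=np.where(run_sp[:nr] == 0, "DDB", "KIF16B"),
            activity=[ACTIVITY_LABELS[a] for a in run_act[:nr]],
            length_nm=run_len[:nr].copy(),
            duration_s=run_dur[:nr].copy(),
            t_attach_s=run_t0[:nr].copy(),
        )
    )
    return samples, runs, t_end


def _engine_atp(atp: float | None) -> float:
    return -1.0 if atp is None else float(atp)


def simulate_cargo(
    config: SimConfig,
    ddb: MotorParams | None = None,
    kif: MotorParams | None = None,
    seed: int = 0,
    track_id: str = "sim-0",
    return_runs: bool = False,
):
    """Simulate one cargo and return its sampled :class:`Track`.

    The motor team is drawn from the config (or taken from
    ``config.fixed_counts``); a fixed ``seed`` makes the track bit-identical
    across calls.  With ``return_runs=True`` a per-detachment run table
    (species, head displacement, duration) is returned alongside.
    """
    ddb = ddb_params() if ddb is None else ddb
    kif = kif16b_params() if kif is None else kif
    seq = np.random.SeedSequence(seed)
    team_seq, engine_seq = seq.spawn(2)
    if config.fixed_counts is not None:
        n_d, n_k = config.fixed_counts
    else:
        rng = np.random.default_rng(team_seq)
        total = sample_motor_count(
            config.mean_n_ddb + config.mean_n_kif, config.sigma_coeff, rng
        )
        n_d, n_k = split_species(total, config.mean_n_ddb, config.mean_n_kif, rng)
    samples, runs, t_end = _run_engine(
        config, ddb, kif, int(n_d), int(n_k), _subseed(engine_seq)
    )
    n_samp = len(samples["x"])
    t = config.relax_time + config.sample_interval * np.arange(n_samp)
    track = Track(
        track_id,
        t,
        samples["x"],
        extras={k: v for k, v in samples.items() if k != "x"},
        meta=dict(
            seed=seed,
            config_hash=config.hash(),
            n_ddb=int(n_d),
            n_kif=int(n_k),
            end_time=t_end,
        ),
    )
    return (track, runs) if return_runs else track


def simulate_cargoes(
    config: SimConfig,
    n_cargoes: int,
    seed: int = 0,
    ddb: MotorParams | None = None,
    kif: MotorParams | None = None,
    min_samples: int = 2,
) -> list[Track]:
    """Simulate ``n_cargoes`` independent cargoes.

    Per-cargo seeds derive deterministically from ``seed``.  Tracks with
    fewer than ``min_samples`` samples (cargoes that never attached in the
    measurement window) are dropped.
    """
    tracks = []
    for i in range(n_cargoes):
        tr = simulate_cargo(
            config,
            ddb,
            kif,
            seed=seed + i,
            track_id=f"sim-{seed}-{i}",
        )
        if len(tr) >= min_samples:
            tracks.append(tr)
    return tracks


# ---------------------------------------------------------------------------
# single-motor reference simulations


def _single_motor_config(params: MotorParams, **overrides) -> tuple[SimConfig, MotorParams]:
    """Zero-load single-motor setup: one motor, no spring coupling
    (kappa = 0), all motors active, no relaxation window."""
    solo = params.replace(kappa=0.0, frac_inactive=0.0, frac_diffusive=0.0)
    is_ddb = params.polarity < 0
    cfg = SimConfig(
        mean_n_ddb=0.0,
        mean_n_kif=0.0,
        fixed_counts=(1, 0) if is_ddb else (0, 1),
        relax_time=0.0,
        max_time=600.0,
        sample_interval=0.1,
        metropolis_proposals=0,
        atp=None,
        **overrides,
    )
    return cfg, solo


def single_motor_runs(
    params: MotorParams,
    n_runs: int,
    seed: int = 0,
    fixed_velocity: float | None = None,
) -> pd.DataFrame:
    """Run-length/duration table of ``n_runs`` single active motors at zero
    load and saturating ATP.

    Each simulation attaches one motor, lets it step at its maximal rate and
    ends at the first detachment; the recorded run is the signed head
    displacement between attachment and detachment.  ``fixed_velocity``
    (nm/s) pins the individual maximal velocity instead of drawing it from
    the species' log-normal.
    """
    if fixed_velocity is not None:
        params = params.replace(v_median=fixed_velocity, v_iqr=0.0)
    cfg, solo = _single_motor_config(params)
    ddb = solo if params.polarity < 0 else ddb_params()
    kif = solo if params.polarity > 0 else kif16b_params()
    seq = np.random.SeedSequence(seed)
    frames = []
    for i, child in enumerate(seq.spawn(n_runs)):
        _, runs, _ = _run_engine(
            cfg, ddb, kif, *cfg.fixed_counts, _subseed(child), max_runs=4
        )
        if len(runs):
            frames.append(runs.iloc[[0]])
    out = pd.concat(frames, ignore_index=True)
    return out


def single_motor_tracks(
    params: MotorParams,
    n_tracks: int,
    seed: int = 0,
    fixed_velocity: float | None = None,
    sample_interval: float = 0.1,
    loc_noise_sd: float = 20.0,
) -> list[np.ndarray]:
    """Head-position trajectories of single motors sampled at
    ``sample_interval``, one array of positions (nm) per motor, spanning
    attachment to detachment.

    ``loc_noise_sd`` adds iid Gaussian localization noise per sample,
    emulating sub-pixel tracking of the fluorescence signal; set it to 0
    for the bare lattice positions.
    """
    if fixed_velocity is not None:
        params = params.replace(v_median=fixed_velocity, v_iqr=0.0)
    cfg, solo = _single_motor_config(params)
    cfg = cfg.replace(sample_interval=sample_interval)
    ddb = solo if params.polarity < 0 else ddb_params()
    kif = solo if params.polarity > 0 else kif16b_params()
    seq = np.random.SeedSequence(seed)
    noise_rng = np.random.default_rng(seq.spawn(1)[0])
    out = []
    for child in seq.spawn(n_tracks):
        samples, _, _ = _run_engine(
            cfg, ddb, kif, *cfg.fixed_counts, _subseed(child), max_runs=4
        )
        head = samples["head0_nm"]
        head = head[~np.isnan(head)]
        if len(head) >= 2:
            if loc_noise_sd > 0:
                head = head + noise_rng.normal(0.0, loc_noise_sd, len(head))
            out.append(head)
    return out
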