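"""Numba event loop of the cargo simulation.

One call to :func:`run_cargo` advances a single cargo with a fixed motor
complement through attachment, force-dependent stepping/diffusion,
detachment and Metropolis cargo relaxation, using the Gillespie algorithm
for event scheduling.  State is kept in flat arrays so the whole loop
compiles to machine code; :mod:`tugsim.simulate` provides the ergonomic
wrapper.

Conventions
-----------
* species index 0 = DDB (minus-directed), 1 = KIF16B (plus-directed); the
  parameter matrix ``P`` has one row per species with the column layout
  given by the module constants below.
* motor heads live on integer lattice sites of spacing ``d`` (column
  ``STEP``); lanes are integers in [-lane_cut, +lane_cut] and at most one
  attached motor may occupy a (lane, site) pair.
* the cargo coordinate is continuous; forces on the cargo are signed with
  the microtubule plus-end along +x.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .kinetics import (
    calibrate_delta,
    detachment_rate,
    diffusive_rates,
    motor_force,
    spring_energy,
    stepping_rate,
)

# parameter matrix columns
KAPPA = 0
LREST = 1
FS = 2
FD = 3
KA = 4
KD0 = 5
KD0IN = 6
VB = 7
STEP = 8
FIN = 9
FDIFF = 10
S0 = 11
KB0 = 12
PB = 13
QB = 14
PCAT = 15
QCAT = 16
POL = 17
VMU = 18
VSIG = 19
NPAR = 20

# activity classes
ACT_ACTIVE = 0
ACT_INACTIVE = 1
ACT_DIFFUSIVE = 2

# event kinds
EV_ATTACH = 0
EV_DETACH = 1
EV_STEP = 2


@njit(cache=True)
def draw_lane(cut):
    """Lane index sampled from a discretized standard normal truncated at
    +-cut: P(lane = l) proportional to exp(-l^2/2)."""
    total = 0.0
    for l in range(-cut, cut + 1):
        total += math.exp(-0.5 * l * l)
    u = np.random.random() * total
    acc = 0.0
    for l in range(-cut, cut + 1):
        acc += math.exp(-0.5 * l * l)
        if u <= acc:
            return l
    return cut


@njit(cache=True)
def _occupied(lane, site, i_self, n, attached, lanes, sites):
    for j in range(n):
        if (
            j != i_self
            and attached[j] == 1
            and lanes[j] == lane
            and sites[j] == site
        ):
            return True
    return False


@njit(cache=True)
def cargo_energy(x_v, n, attached, sites, sp, P):
    """Total elastic energy of the attached motor springs at cargo
    position ``x_v``."""
    e = 0.0
    for j in range(n):
        if attached[j] == 1:
            s = sp[j]
            dx = sites[j] * P[s, STEP] - x_v
            e += spring_energy(dx, P[s, KAPPA], P[s, LREST])
    return e


@njit(cache=True)
def metropolis_relax(x_v, n, attached, sites, sp, P, kbt, n_prop, step):
    """Metropolis random walk of the cargo in the attached-spring potential.

    Proposals are uniform in [-step, +step]; acceptance min(1, exp(-dE/kBT)).
    Returns the final cargo position.
    """
    e = cargo_energy(x_v, n, attached, sites, sp, P)
    for _ in range(n_prop):
        xp = x_v + (2.0 * np.random.random() - 1.0) * step
        ep = cargo_energy(xp, n, attached, sites, sp, P)
        de = ep - e
        if de <= 0.0 or np.random.random() < math.exp(-de / kbt):
            x_v = xp
            e = ep
    return x_v


@njit(cache=True)
def run_cargo(
    P,
    n_d,
    n_k,
    atp,
    kbt,
    relax_time,
    max_time,
    dt_s,
    n_prop,
    m_step,
    lane_cut,
    stall_rate,
    det_sign,
    seed,
    samp_x,
    samp_nd,
    samp_nk,
    samp_f,
    samp_head0,
    run_sp,
    run_act,
    run_len,
    run_dur,
    run_t0,
):
    """Simulate one cargo; fills the preallocated sample/run buffers.

    Returns ``(n_samples, n_runs, end_time)``.  Samples are taken on the
    grid ``relax_time + k * dt_s``; the track ends when no motor is attached
    after the relaxation window, or at ``max_time``.  Each detachment event
    appends one run record (species, activity class, signed head
    displacement since attachment, duration, attachment time).
    """
    np.random.seed(seed)
    n = n_d + n_k
    ns = 0
    nr = 0
    if n == 0:
        return ns, nr, 0.0
    ns_max = samp_x.shape[0]
    nr_max = run_sp.shape[0]

    sp = np.empty(n, np.int64)
    for i in range(n):
        sp[i] = 0 if i < n_d else 1
    attached = np.zeros(n, np.int64)
    act = np.zeros(n, np.int64)
    lanes = np.zeros(n, np.int64)
    sites = np.zeros(n, np.int64)
    vf = np.zeros(n)
    delta = np.zeros(n)
    att_x = np.zeros(n)
    att_t = np.zeros(n)

    x_v = 0.0
    t = 0.0
    next_s = relax_time
    n_att = 0

    max_ev = 3 * n
    rate = np.empty(max_ev)
    ev_kind = np.empty(max_ev, np.int64)
    ev_motor = np.empty(max_ev, np.int64)
    ev_dir = np.empty(max_ev, np.int64)
    n_ev = 0
    total = 0.0
    need_rates = True

    while True:
        if need_rates:
            n_ev = 0
            total = 0.0
            for i in range(n):
                s = sp[i]
                if attached[i] == 0:
                    r = P[s, KA]
                    if r > 0.0:
                        rate[n_ev] = r
                        ev_kind[n_ev] = EV_ATTACH
                        ev_motor[n_ev] = i
                        ev_dir[n_ev] = 0
                        n_ev += 1
                        total += r
                    continue
                d = P[s, STEP]
                dx = sites[i] * d - x_v
                f = motor_force(dx, P[s, KAPPA], P[s, LREST])
                f_abs = abs(f)
                kd0 = P[s, KD0] if act[i] != ACT_INACTIVE else P[s, KD0IN]
                r = detachment_rate(f_abs, kd0, P[s, FD], det_sign)
                if r > 0.0:
                    rate[n_ev] = r
                    ev_kind[n_ev] = EV_DETACH
                    ev_motor[n_ev] = i
                    ev_dir[n_ev] = 0
                    n_ev += 1
                    total += r
                if act[i] == ACT_ACTIVE:
                    pol = int(P[s, POL])
                    f_res = f * pol
                    if P[s, FS] > 0.0 and f_res > P[s, FS]:
                        r = P[s, VB] / d
                        direction = -pol
                    else:
                        fr = f_res if f_res > 0.0 else 0.0
                        r = stepping_rate(
                            fr,
                            atp,
                            vf[i] / d,
                            P[s, KB0],
                            P[s, PCAT],
                            P[s, QCAT],
                            P[s, PB],
                            P[s, QB],
                            delta[i],
                            kbt,
                        )
                        direction = pol
                    if r > 0.0 and not _occupied(
                        lanes[i], sites[i] + direction, i, n, attached, lanes, sites
                    ):
                        rate[n_ev] = r
                        ev_kind[n_ev] = EV_STEP
                        ev_motor[n_ev] = i
                        ev_dir[n_ev] = direction
                        n_ev += 1
                        total += r
                elif act[i] == ACT_DIFFUSIVE:
                    if dx > P[s, LREST]:
                        toward = -1
                    elif dx < -P[s, LREST]:
                        toward = 1
                    else:
                        toward = 1  # unloaded: both directions at s0
                    r_to, r_away = diffusive_rates(f_abs, P[s, S0], d, kbt)
                    if r_to > 0.0 and not _occupied(
                        lanes[i], sites[i] + toward, i, n, attached, lanes, sites
                    ):
                        rate[n_ev] = r_to
                        ev_kind[n_ev] = EV_STEP
                        ev_motor[n_ev] = i
                        ev_dir[n_ev] = toward
                        n_ev += 1
                        total += r_to
                    if r_away > 0.0 and not _occupied(
                        lanes[i], sites[i] - toward, i, n, attached, lanes, sites
                    ):
                        rate[n_ev] = r_away
                        ev_kind[n_ev] = EV_STEP
                        ev_motor[n_ev] = i
                        ev_dir[n_ev] = -toward
                        n_ev += 1
                        total += r_away
            need_rates = False

        if total <= 0.0:
            break

        u = np.random.random()
        dt = 1.0e30 if u <= 0.0 else -math.log(u) / total
        tn = t + dt
        t_lim = tn if tn < max_time else max_time

        # record samples falling inside [t, min(tn, max_time)]
        while next_s <= t_lim + 1e-12 and ns < ns_max:
            samp_x[ns] = x_v
            nd = 0
            nk = 0
            fc = 0.0
            for j in range(n):
                if attached[j] == 1:
                    if sp[j] == 0:
                        nd += 1
                    else:
                        nk += 1
                    sj = sp[j]
                    dxj = sites[j] * P[sj, STEP] - x_v
                    fc += abs(motor_force(dxj, P[sj, KAPPA], P[sj, LREST]))
            samp_nd[ns] = nd
            samp_nk[ns] = nk
            samp_f[ns] = fc
            samp_head0[ns] = sites[0] * P[sp[0], STEP] if attached[0] == 1 else np.nan
            ns += 1
            next_s += dt_s

        if tn >= max_time:
            t = max_time
            break
        t = tn

        # select the event
        r_pick = np.random.random() * total
        acc = 0.0
        k = n_ev - 1
        for j in range(n_ev):
            acc += rate[j]
            if r_pick <= acc:
                k = j
                break
        kind = ev_kind[k]
        i = ev_motor[k]
        changed = True

        if kind == EV_ATTACH:
            s = sp[i]
            d = P[s, STEP]
            lane = draw_lane(lane_cut)
            site = int(math.floor(x_v / d + 0.5))  # lattice site nearest cargo
            if _occupied(lane, site, i, n, attached, lanes, sites):
                changed = False  # aborted attachment: legal no-op
            else:
                attached[i] = 1
                lanes[i] = lane
                sites[i] = site
                ua = np.random.random()
                if ua < P[s, FIN]:
                    act[i] = ACT_INACTIVE
                elif ua < P[s, FIN] + P[s, FDIFF]:
                    act[i] = ACT_DIFFUSIVE
                else:
                    act[i] = ACT_ACTIVE
                if P[s, VSIG] > 0.0:
                    vf[i] = math.exp(
                        P[s, VMU] + P[s, VSIG] * np.random.standard_normal()
                    )
                else:
                    vf[i] = math.exp(P[s, VMU])
                if act[i] == ACT_ACTIVE and P[s, FS] > 0.0:
                    dlt = calibrate_delta(
                        P[s, FS],
                        atp,
                        vf[i] / d,
                        P[s, KB0],
                        P[s, PCAT],
                        P[s, QCAT],
                        P[s, PB],
                        P[s, QB],
                        kbt,
                        stall_rate,
                    )
                    delta[i] = dlt if dlt > 0.0 else 0.0
                else:
                    delta[i] = 0.0
                att_x[i] = site * d
                att_t[i] = t
                n_att += 1
        elif kind == EV_DETACH:
            if nr < nr_max:
                run_sp[nr] = sp[i]
                run_act[nr] = act[i]
                run_len[nr] = sites[i] * P[sp[i], STEP] - att_x[i]
                run_dur[nr] = t - att_t[i]
                run_t0[nr] = att_t[i]
                nr += 1
            attached[i] = 0
            n_att -= 1
        else:  # EV_STEP
            sites[i] += ev_dir[k]

        if changed:
            if n_prop > 0 and n_att > 0:
                x_v = metropolis_relax(
                    x_v, n, attached, sites, sp, P, kbt, n_prop, m_step
                )
            need_rates = True

        if n_att == 0 and t > relax_time:
            break

    return ns, nr, t
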