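"""Force-dependent single-motor kinetics.

Scalar rate laws shared by the stochastic engine and the public API:

* piecewise-Hookean motor springs with a dead zone of width ``2 L`` around
  zero deflection,
* Michaelis--Menten stepping with Boltzmann-distributed catalytic and
  ATP-binding rates (composite load dependence with a single load distance
  ``delta``),
* Bell-type (exponential) load dependence of detachment,
* biased hopping of diffusive motors in their spring potential.

All functions are Numba-compiled scalars so the event loop in
:mod:`tugsim._engine` can call them without Python overhead; they are equally
usable from plain Python.

Units: nm, s, pN, mM, and pN nm for energies (kBT ~ 4.11 pN nm at room
temperature).
"""

from __future__ import annotations

import math

from numba import njit

__all__ = [
    "motor_force",
    "spring_energy",
    "stepping_rate",
    "calibrate_delta",
    "detachment_rate",
    "diffusive_rates",
]

#: a non-positive ATP concentration is interpreted as "saturating", i.e. the
#: Michaelis--Menten factor is dropped and the stepping rate equals k_cat(F).
ATP_SATURATING = -1.0


@njit(cache=True)
def motor_force(dx, kappa, L):
    """Signed force (pN) of a Hookean spring with rest length ``L``.

    ``dx`` is the motor-head deflection relative to the cargo (nm).  The
    spring is slack for ``|dx| <= L`` (dead zone) and engages linearly
    beyond it.
    """
    if dx > L:
        return kappa * (dx - L)
    if dx < -L:
        return kappa * (dx + L)
    return 0.0


@njit(cache=True)
def spring_energy(dx, kappa, L):
    """Elastic energy (pN nm) of the piecewise-Hookean motor spring."""
    if dx > L:
        u = dx - L
        return 0.5 * kappa * u * u
    if dx < -L:
        u = dx + L
        return 0.5 * kappa * u * u
    return 0.0


@njit(cache=True)
def _boltzmann_rate(k0, p, q, f_resist, delta, kbt):
    # k(F) = k0 / (p + q exp(F delta / kBT)); F is the resisting magnitude.
    return k0 / (p + q * math.exp(f_resist * delta / kbt))


@njit(cache=True)
def stepping_rate(
    f_resist, atp, kcat0, kb0, p_cat, q_cat, p_b, q_b, delta, kbt
):
    """Forward stepping rate (1/s) under a resisting load ``f_resist`` >= 0.

    Michaelis--Menten in ATP with V_max = k_cat(F) and K_M = k_cat(F)/k_b(F),
    both rates sharing the load distance ``delta``.  Callers handle the
    assisting regime by passing ``f_resist = 0`` and the super-stall regime
    separately (constant backstepping).  ``atp <= 0`` means saturating ATP.
    """
    kcat = _boltzmann_rate(kcat0, p_cat, q_cat, f_resist, delta, kbt)
    if atp <= 0.0:
        return kcat
    kb = _boltzmann_rate(kb0, p_b, q_b, f_resist, delta, kbt)
    return kcat * atp / (atp + kcat / kb)


@njit(cache=True)
def calibrate_delta(
    f_stall, atp, kcat0, kb0, p_cat, q_cat, p_b, q_b, kbt, stall_rate
):
    """Load distance ``delta`` (nm) such that the stepping rate at the stall
    force equals ``stall_rate``.

    Solved by bisection; the stepping rate is strictly decreasing in delta
    at fixed resisting force, so the root is unique.  Returns -1.0 when the
    constraint is unsatisfiable (zero-load rate already at or below
    ``stall_rate``, or no bracket below 1e6 nm).
    """
    r0 = stepping_rate(f_stall, atp, kcat0, kb0, p_cat, q_cat, p_b, q_b, 0.0, kbt)
    if r0 <= stall_rate or f_stall <= 0.0:
        return -1.0
    hi = 1.0
    while (
        stepping_rate(f_stall, atp, kcat0, kb0, p_cat, q_cat, p_b, q_b, hi, kbt)
        > stall_rate
    ):
        hi *= 2.0
        if hi > 1.0e6:
            return -1.0
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = stepping_rate(
            f_stall, atp, kcat0, kb0, p_cat, q_cat, p_b, q_b, mid, kbt
        )
        if r > stall_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def detachment_rate(f_abs, kd0, fd, load_sign):
    """Load-dependent detachment rate (1/s).

    ``load_sign = +1`` gives the Bell law k_d0 exp(+|F|/F_d) (detachment
    accelerated by load, the default); ``load_sign = -1`` gives the
    catch-bond-like variant k_d0 exp(-|F|/F_d).
    """
    return kd0 * math.exp(load_sign * f_abs / fd)


@njit(cache=True)
def diffusive_rates(f_abs, s0, d, kbt):
    """(toward-equilibrium, away-from-equilibrium) hopping rates (1/s).

    A diffusive motor hops by one lattice site ``d`` with rates
    s0 exp(+-|F| d / 2 kBT); the faster direction relaxes the spring, so the
    pair satisfies detailed balance in the spring potential.
    """
    arg = f_abs * d / (2.0 * kbt)
    return s0 * math.exp(arg), s0 * math.exp(-arg)
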