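"""Motor species parameters.

Ships documented default parameter sets for the two motor species of the
vesicle tug-of-war model:

* **KIF16B** -- a kinesin-3 family, plus-end directed motor (polarity +1),
* **DDB** -- the dynein-dynactin-BICD2N complex, minus-end directed
  (polarity -1).

Zero-load kinetics are anchored to the single-molecule medians measured for
these motors (KIF16B: 0.80 um/s velocity, 0.63 um run length; DDB: 1.46 um/s,
3.29 um); mechanical constants (stiffness, rest length, stall and detachment
forces) are literature-plausible values for kinesin-3 and activated dynein
and can all be overridden per instance or from a YAML config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetics

__all__ = [
    "SchnitzerParams",
    "MotorParams",
    "kif16b_params",
    "ddb_params",
    "lognormal_from_median_iqr",
]

_LN2 = math.log(2.0)

#: standard normal quartile, used to match a log-normal to a median and IQR
_Z75 = 0.6744897501960817


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and interquartile
    range.

    The quartiles of LogNormal(mu, sigma) are ``median * exp(+-z75 sigma)``,
    so ``iqr = 2 median sinh(z75 sigma)`` which inverts in closed form.
    ``iqr = 0`` yields a point mass at the median (sigma = 0).
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if iqr < 0:
        raise ValueError("iqr must be non-negative")
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / _Z75
    return mu, sigma


@dataclass(frozen=True)
class SchnitzerParams:
    """Load-sharing constants of the composite stepping model.

    ``k_cat`` and ``k_b`` are Boltzmann-distributed between a
    load-insensitive fraction ``p`` and a load-bearing fraction ``q``
    (``p + q = 1`` for each), sharing a single load distance delta.
    ``k_b0`` is the second-order ATP binding rate in 1/(s mM).
    """

    k_b0: float = 1350.0
    p_b: float = 0.05
    q_b: float = 0.95
    p_cat: float = 0.5
    q_cat: float = 0.5

    def __post_init__(self) -> None:
        if abs(self.p_b + self.q_b - 1.0) > 1e-9:
            raise ValueError("p_b + q_b must equal 1")
        if abs(self.p_cat + self.q_cat - 1.0) > 1e-9:
            raise ValueError("p_cat + q_cat must equal 1")
        if min(self.k_b0, self.p_b, self.q_b, self.p_cat, self.q_cat) < 0:
            raise ValueError("Schnitzer constants must be non-negative")


@dataclass(frozen=True)
class MotorParams:
    """Kinetic and mechanical constants of one motor species.

    Units: nm, s, pN, mM.  ``polarity`` is +1 for plus-end directed motors
    (KIF16B) and -1 for minus-end directed motors (DDB).  ``v_median`` and
    ``v_iqr`` (nm/s) parametrize the log-normal from which each motor's
    individual maximal velocity is drawn on attachment; an IQR of zero fixes
    the velocity at the median.
    """

    species_name: str
    kappa: float  # spring stiffness, pN/nm
    rest_length: float  # dead-zone half width L, nm
    stall_force: float  # F_s, pN (magnitude)
    detach_force: float  # F_d, pN
    attach_rate: float  # k_a, 1/s
    detach_rate_active: float  # k_d0 of stepping motors, 1/s
    detach_rate_inactive: float  # k_d0 of rigor-like motors, 1/s
    back_velocity: float  # v_b beyond stall, nm/s
    step_size: float  # d, nm
    frac_inactive: float
    frac_diffusive: float
    diffusive_rate: float  # s_0, 1/s
    v_median: float  # nm/s
    v_iqr: float  # nm/s
    polarity: int
    schnitzer: SchnitzerParams = field(default_factory=SchnitzerParams)

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.frac_inactive < 0 or self.frac_diffusive < 0:
            raise ValueError("class fractions must be non-negative")
        if self.frac_inactive + self.frac_diffusive > 1.0 + 1e-12:
            raise ValueError("frac_inactive + frac_diffusive must be <= 1")
        nonneg = (
            self.kappa,
            self.rest_length,
            self.stall_force,
            self.detach_force,
            self.attach_rate,
            self.detach_rate_active,
            self.detach_rate_inactive,
            self.back_velocity,
            self.step_size,
            self.diffusive_rate,
            self.v_median,
            self.v_iqr,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("rates, forces and lengths must be non-negative")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def v_lognormal(self) -> tuple[float, float]:
        """(mu, sigma) of the individual maximal-velocity distribution."""
        return lognormal_from_median_iqr(self.v_median, self.v_iqr)

    def kcat0(self, v: float | None = None) -> float:
        """Zero-load catalytic rate v/d for velocity ``v`` (default median)."""
        return (self.v_median if v is None else v) / self.step_size

    def stepping_rate(
        self,
        force: float,
        atp: float | None,
        *,
        v: float | None = None,
        delta: float | None = None,
        kbt: float = 4.11,
        stall_rate: float = 0.1,
    ) -> float:
        """Stepping rate under the signed force ``force`` exerted on the cargo.

        The force is resisting when it points along the species' direction of
        motion (it then pulls the motor head backwards).  Resisting loads
        below stall follow the composite Michaelis--Menten law, assisting
        loads step at the zero-load rate, and super-stall loads backstep at
        ``back_velocity / step_size``.  ``atp=None`` means saturating ATP.
        ``delta`` defaults to the calibrated value for this (v, atp, kbt).
        """
        f_res = force * self.polarity
        if self.stall_force > 0 and f_res > self.stall_force:
            return self.back_velocity / self.step_size
        if delta is None:
            delta = self.calibrate_delta(atp, v=v, kbt=kbt, stall_rate=stall_rate)
        sch = self.schnitzer
        return kinetics.stepping_rate(
            max(f_res, 0.0),
            kinetics.ATP_SATURATING if atp is None else atp,
            self.kcat0(v),
            sch.k_b0,
            sch.p_cat,
            sch.q_cat,
            sch.p_b,
            sch.q_b,
            delta,
            kbt,
        )

    def calibrate_delta(
        self,
        atp: float | None,
        *,
        v: float | None = None,
        kbt: float = 4.11,
        stall_rate: float = 0.1,
    ) -> float:
        """Load distance delta (nm) pinning the stepping rate at stall to
        ``stall_rate`` (0.1 1/s by default)."""
        sch = self.schnitzer
        delta = kinetics.calibrate_delta(
            self.stall_force,
            kinetics.ATP_SATURATING if atp is None else atp,
            self.kcat0(v),
            sch.k_b0,
            sch.p_cat,
            sch.q_cat,
            sch.p_b,
            sch.q_b,
            kbt,
            stall_rate,
        )
        if delta < 0:
            raise ValueError(
                f"stall calibration failed for {self.species_name}: the "
                f"zero-load stepping rate must exceed {stall_rate} 1/s"
            )
        return delta

    def detachment_rate(
        self, force: float, *, active: bool = True, load_sign: int = 1
    ) -> float:
        kd0 = self.detach_rate_active if active else self.detach_rate_inactive
        return kinetics.detachment_rate(abs(force), kd0, self.detach_force, load_sign)

    def replace(self, **overrides) -> "MotorParams":
        return replace(self, **overrides)

    def as_array(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Flat float64 row consumed by the compiled engine."""
        from . import _engine as eg

        mu, sigma = self.v_lognormal
        row = np.zeros(eg.NPAR)
        row[eg.KAPPA] = self.kappa
        row[eg.LREST] = self.rest_length
        row[eg.FS] = self.stall_force
        row[eg.FD] = self.detach_force
        row[eg.KA] = self.attach_rate
        row[eg.KD0] = self.detach_rate_active
        row[eg.KD0IN] = self.detach_rate_inactive
        row[eg.VB] = self.back_velocity
        row[eg.STEP] = self.step_size
        row[eg.FIN] = self.frac_inactive
        row[eg.FDIFF] = self.frac_diffusive
        row[eg.S0] = self.diffusive_rate
        row[eg.KB0] = self.schnitzer.k_b0
        row[eg.PB] = self.schnitzer.p_b
        row[eg.QB] = self.schnitzer.q_b
        row[eg.PCAT] = self.schnitzer.p_cat
        row[eg.QCAT] = self.schnitzer.q_cat
        row[eg.POL] = float(self.polarity)
        row[eg.VMU] = mu
        row[eg.VSIG] = sigma
        return row


def _kd0_from_medians(v_median_nm_s: float, run_length_median_nm: float) -> float:
    # exponential run lengths: median = ln2 * v / k_d0
    return v_median_nm_s * _LN2 / run_length_median_nm


def kif16b_params(**overrides) -> MotorParams:
    """Default KIF16B parameter set (plus-end directed kinesin-3)."""
    base = MotorParams(
        species_name="KIF16B",
        kappa=0.3,
        rest_length=80.0,
        stall_force=6.0,
        detach_force=3.0,
        attach_rate=0.5,
        detach_rate_active=_kd0_from_medians(800.0, 630.0),
        detach_rate_inactive=0.25,
        back_velocity=4.0,
        step_size=8.0,
        frac_inactive=0.2,
        frac_diffusive=0.0,
        diffusive_rate=0.0,
        v_median=800.0,
        v_iqr=630.0,
        polarity=+1,
    )
    return base.replace(**overrides) if overrides else base


def ddb_params(**overrides) -> MotorParams:
    """Default DDB parameter set (minus-end directed dynein-dynactin-BICD2N)."""
    base = MotorParams(
        species_name="DDB",
        kappa=0.2,
        rest_length=50.0,
        stall_force=4.0,
        detach_force=2.0,
        attach_rate=0.5,
        detach_rate_active=_kd0_from_medians(1460.0, 3290.0),
        detach_rate_inactive=0.25,
        back_velocity=4.0,
        step_size=8.0,
        frac_inactive=0.1,
        frac_diffusive=0.1,
        diffusive_rate=156.0,
        v_median=1460.0,
        v_iqr=1630.0,
        polarity=-1,
    )
    return base.replace(**overrides) if overrides else base
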