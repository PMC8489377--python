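"""One-compartment intravenous-infusion kinetics.

Closed-form concentration prediction for a drug given by repeated
zero-order (constant-rate) infusions into a single well-stirred
compartment with first-order elimination.  The model has two individual
parameters, clearance ``CL`` (L/h) and apparent volume of distribution
``V`` (L); the elimination rate constant is ``k = CL/V``.

For a single infusion of ``amount`` mg over ``duration`` h starting at
``start_time``, with zero-order rate R0 = amount/duration:

    C(t) = 0                                          t <= start
    C(t) = (R0/CL) * (1 - exp(-k (t - start)))        start < t <= end
    C(t) = C(end) * exp(-k (t - end))                 t > end

Multiple infusions superpose linearly (the system is linear and
time-invariant), so the multi-dose profile is the sum of single-infusion
profiles; overlapping infusions simply add their rates.

Units are fixed throughout the package: time in hours, amounts in mg,
volumes in L, concentrations in mg/L (numerically identical to ug/mL).

`ode_oracle_concentration` integrates the mass-balance ODE numerically
and serves as an independent cross-check of the closed form in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DosingEvent",
    "IndividualParameters",
    "InvalidParameterError",
    "single_infusion_concentration",
    "concentration_at",
    "ode_oracle_concentration",
    "accumulation_factor",
]


class InvalidParameterError(ValueError):
    """Raised for non-positive CL, V, dose amount or infusion duration."""


@dataclass(frozen=True)
class DosingEvent:
    """One intravenous infusion.

    Parameters
    ----------
    start_time : float
        Hours since the first dose of the regimen (>= 0).
    amount : float
        Dose in mg (> 0).
    duration : float, default 1.0
        Infusion length in hours (> 0).  The study protocol requires
        infusions of at least 60 min, hence the default.
    """

    start_time: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not (self.amount > 0):
            raise InvalidParameterError(f"dose amount must be > 0, got {self.amount}")
        if not (self.duration > 0):
            raise InvalidParameterError(
                f"infusion duration must be > 0, got {self.duration}"
            )
        if self.start_time < 0:
            raise InvalidParameterError(
                f"start_time must be >= 0, got {self.start_time}"
            )

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def rate(self) -> float:
        """Zero-order infusion rate R0 in mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class IndividualParameters:
    """Individual clearance (L/h) and apparent volume of distribution (L)."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not (self.cl > 0) or not np.isfinite(self.cl):
            raise InvalidParameterError(f"CL must be positive and finite, got {self.cl}")
        if not (self.v > 0) or not np.isfinite(self.v):
            raise InvalidParameterError(f"V must be positive and finite, got {self.v}")

    @property
    def k(self) -> float:
        """First-order elimination rate constant (1/h)."""
        return self.cl / self.v


def single_infusion_concentration(
    t: float | np.ndarray, event: DosingEvent, ip: IndividualParameters
) -> float | np.ndarray:
    """Concentration (mg/L) at time ``t`` from one infusion.

    ``t`` may be a scalar or an array of times (hours since first dose).
    Times before the infusion starts yield exactly 0.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    k = ip.k
    dt = t_arr - event.start_time
    # rise during infusion, frozen at the end-of-infusion value afterwards
    rise = (event.rate / ip.cl) * -np.expm1(-k * np.clip(dt, 0.0, event.duration))
    decay = np.exp(-k * np.clip(dt - event.duration, 0.0, None))
    c = np.where(dt <= 0.0, 0.0, rise * decay)
    return float(c[0]) if scalar else c


def concentration_at(
    t: float | np.ndarray,
    events: Iterable[DosingEvent],
    ip: IndividualParameters,
) -> float | np.ndarray:
    """Concentration (mg/L) at time ``t`` under a multi-infusion regimen.

    Linear superposition of `single_infusion_concentration` over all
    events; an empty event list gives 0 everywhere.  Overlapping
    infusions are permitted (their rates add).
    """
    events = list(events)
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    total = np.zeros_like(np.atleast_1d(t_arr))
    for ev in events:
        total = total + single_infusion_concentration(np.atleast_1d(t_arr), ev, ip)
    return float(total[0]) if scalar else total


class OdeIntegrationError(RuntimeError):
    """Raised when the numerical oracle integrator fails."""


def ode_oracle_concentration(
    t: float | Sequence[float] | np.ndarray,
    events: Iterable[DosingEvent],
    ip: IndividualParameters,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float | np.ndarray:
    """Numerically integrate dA/dt = rate_in(t) - k*A and return A(t)/V.

    Independent oracle for `concentration_at`: the infusion schedule is
    handled by integrating segment-by-segment between rate
    discontinuities with an adaptive Runge-Kutta method, so the
    piecewise-constant input introduces no stiffness artefacts.
    """
    events = list(events)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = np.asarray(t, dtype=float).ndim == 0
    if len(events) == 0:
        out = np.zeros_like(t_arr)
        return float(out[0]) if scalar else out

    k = ip.k

    breaks = sorted(
        {0.0}
        | {ev.start_time for ev in events}
        | {ev.end_time for ev in events}
        | set(t_arr.tolist())
    )

    def rate_in(time: float) -> float:
        return sum(ev.rate for ev in events if ev.start_time <= time < ev.end_time)

    amounts = {}
    a = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        amounts[lo] = a
        if hi > lo:
            r = rate_in(0.5 * (lo + hi))  # constant on the open segment

            def rhs(_t, y, r=r):
                return [r - k * y[0]]

            sol = solve_ivp(
                rhs, (lo, hi), [a], method="RK45", rtol=rtol, atol=atol,
                dense_output=False,
            )
            if not sol.success:
                raise OdeIntegrationError(sol.message)
            a = float(sol.y[0, -1])
    amounts[breaks[-1]] = a

    conc = np.array([amounts[tt] / ip.v if tt >= 0 else 0.0 for tt in t_arr])
    return float(conc[0]) if scalar else conc


def accumulation_factor(k: float, tau: float) -> float:
    """Steady-state accumulation ratio 1/(1 - exp(-k*tau)) for interval tau."""
    return 1.0 / -np.expm1(-k * tau)
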