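"""Two-variable linear excitation-adaptation model.

The model tracks a fast excitation variable ``u1`` (the response) and a slow
adaptation variable ``u2``::

    du1/dt = (f(S(t)) - u1 - u2) / tau_e
    du2/dt = (f(S(t)) - u2) / tau_a

with ``tau_e << tau_a`` in the biologically relevant regime.  For any constant
stimulus the steady state is ``(u1, u2) = (0, f(S))``: the response adapts
perfectly while the adaptation variable absorbs the background.  For a step of
amplitude ``S0`` applied at t = 0 from rest the solution is

    u1(t) = f(S0) * tau_a/(tau_a - tau_e) * (exp(-t/tau_a) - exp(-t/tau_e))
    u2(t) = f(S0) * (1 - exp(-t/tau_a))

Because the system is linear with piecewise-constant drive, trajectories are
integrated exactly (matrix-exponential update per segment); ramp segments fall
back to classic fixed-step RK4.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "CartoonParams",
    "CartoonState",
    "StimulusProtocol",
    "Segment",
    "cartoon_rhs",
    "integrate_cartoon",
    "analytic_step_response",
    "pulse_response_peak",
]


def _identity(s: float) -> float:
    return s


@dataclass(frozen=True)
class CartoonParams:
    """Time constants and transduction function of the adaptation model.

    Parameters
    ----------
    tau_e : float
        Excitation time constant in seconds (> 0).
    tau_a : float
        Adaptation time constant in seconds (> 0).
    f : callable
        Transduction function mapping stimulus level to drive; must satisfy
        ``f(0) == 0``.  Defaults to the identity.
    """

    tau_e: float
    tau_a: float
    f: Callable[[float], float] = _identity

    def __post_init__(self) -> None:
        if not (self.tau_e > 0 and self.tau_a > 0):
            raise ValueError("time constants must be positive")
        if abs(self.f(0.0)) > 1e-12:
            raise ValueError("transduction function must satisfy f(0) = 0")


@dataclass
class CartoonState:
    """Instantaneous state: excitation u1, adaptation u2, and time t (s)."""

    u1: float = 0.0
    u2: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u1) and math.isfinite(self.u2)):
            raise ValueError("state variables must be finite")


@dataclass(frozen=True)
class Segment:
    """One stimulus segment: constant ``level``, or a ramp if slope != 0."""

    t_start: float
    t_end: float
    level: float
    slope: float = 0.0

    def value(self, t: float) -> float:
        if self.slope == 0.0:
            return self.level
        return self.level + self.slope * (t - self.t_start)


@dataclass
class StimulusProtocol:
    """Piecewise-defined stimulus S(t); zero outside all segments."""

    segments: Sequence[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.t_start)
        prev_end = -math.inf
        for s in segs:
            if s.t_end < s.t_start:
                raise ValueError("segment with t_end < t_start")
            if s.t_start < prev_end - 1e-15:
                raise ValueError("overlapping stimulus segments")
            if s.level < 0:
                raise ValueError("stimulus levels must be >= 0")
            prev_end = s.t_end
        self.segments = segs

    @classmethod
    def step(cls, s0: float, t_on: float = 0.0, t_off: float = math.inf) -> "StimulusProtocol":
        return cls([Segment(t_on, t_off, s0)])

    @classmethod
    def constant(cls, s0: float) -> "StimulusProtocol":
        return cls.step(s0, 0.0, math.inf)

    def value(self, t: float) -> float:
        for s in self.segments:
            if s.t_start <= t < s.t_end:
                return s.value(t)
        return 0.0

    def has_ramps(self) -> bool:
        return any(s.slope != 0.0 for s in self.segments)

    def breakpoints(self, t_end: float) -> np.ndarray:
        pts = {0.0, t_end}
        for s in self.segments:
            if 0.0 < s.t_start < t_end:
                pts.add(s.t_start)
            if 0.0 < s.t_end < t_end:
                pts.add(s.t_end)
        return np.array(sorted(pts))


def cartoon_rhs(
    state: CartoonState, s_level: float, params: CartoonParams
) -> tuple[float, float]:
    """Right-hand side of the excitation-adaptation ODE at one instant."""
    if not math.isfinite(s_level):
        raise ValueError("stimulus level must be finite")
    if not (math.isfinite(state.u1) and math.isfinite(state.u2)):
        raise ValueError("state variables must be finite")
    drive = params.f(s_level)
    du1 = (drive - state.u1 - state.u2) / params.tau_e
    du2 = (drive - state.u2) / params.tau_a
    return du1, du2


def _propagator(params: CartoonParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact update over dt for constant drive c: u' = A u + b c.

    Returns (E, g) with u(t+dt) = E @ u + g * c, via the augmented matrix
    exponential, so the update is exact for any tau_e, tau_a.
    """
    te, ta = params.tau_e, params.tau_a
    M = np.array(
        [
            [-1.0 / te, -1.0 / te, 1.0 / te],
            [0.0, -1.0 / ta, 1.0 / ta],
            [0.0, 0.0, 0.0],
        ]
    )
    P = expm(M * dt)
    return P[:2, :2], P[:2, 2]


def integrate_cartoon(
    params: CartoonParams,
    protocol: StimulusProtocol,
    dt: float,
    t_end: float,
    state0: CartoonState | None = None,
) -> pd.DataFrame:
    """Integrate the model on a uniform grid; exact per-segment updates.

    For piecewise-constant stimuli the matrix-exponential update introduces no
    truncation error; segment boundaries falling inside a step are split so the
    only error is round-off.  Ramp segments use fixed-step RK4 at the same dt.

    Returns a DataFrame with columns ``t, u1, u2, S``.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if dt >= t_end:
        raise ValueError("dt must be smaller than t_end")

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    u = np.zeros(2) if state0 is None else np.array([state0.u1, state0.u2], float)
    breaks = protocol.breakpoints(t_end)

    out = np.empty((n_steps + 1, 2))
    out[0] = u
    # cache propagators keyed by interval length
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def advance_const(u: np.ndarray, c: float, h: float) -> np.ndarray:
        key = round(h, 15)
        if key not in cache:
            cache[key] = _propagator(params, h)
        E, g = cache[key]
        return E @ u + g * c

    def advance_rk4(u: np.ndarray, t0: float, h: float, seg: Segment) -> np.ndarray:
        # evaluate the stimulus through the active segment so RK4 stages at
        # the right edge of a half-open segment see its own extension
        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            d = params.f(seg.value(t))
            return np.array(
                [(d - y[0] - y[1]) / params.tau_e, (d - y[1]) / params.tau_a]
            )

        k1 = rhs(t0, u)
        k2 = rhs(t0 + h / 2, u + h / 2 * k1)
        k3 = rhs(t0 + h / 2, u + h / 2 * k2)
        k4 = rhs(t0 + h, u + h * k3)
        return u + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    for i in range(n_steps):
        t0, t1 = times[i], times[i + 1]
        # split the step at protocol breakpoints to keep segment updates exact
        inner = breaks[(breaks > t0 + 1e-15) & (breaks < t1 - 1e-15)]
        edges = np.concatenate(([t0], inner, [t1]))
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            seg = next(
                (s for s in protocol.segments if s.t_start <= mid < s.t_end), None
            )
            if seg is not None and seg.slope != 0.0:
                u = advance_rk4(u, a, b - a, seg)
            else:
                level = 0.0 if seg is None else seg.level
                u = advance_const(u, params.f(level), b - a)
        out[i + 1] = u

    S = np.array([protocol.value(t) for t in times])
    return pd.DataFrame({"t": times, "u1": out[:, 0], "u2": out[:, 1], "S": S})


def analytic_step_response(
    params: CartoonParams, s0: float, t: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form response to a step of amplitude s0 from rest at t = 0.

    Valid for ``tau_a != tau_e`` (the confluent case is rejected).  Note the
    prefactor ``tau_a/(tau_a - tau_e)``: this is the solution of the model ODE
    and agrees with the exact integrator to round-off.
    """
    te, ta = params.tau_e, params.tau_a
    if te == ta:
        raise ValueError("degenerate case tau_a == tau_e not supported")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    c = params.f(s0)
    u1 = c * ta / (ta - te) * (np.exp(-t / ta) - np.exp(-t / te))
    u2 = c * (1.0 - np.exp(-t / ta))
    return u1, u2


def pulse_response_peak(params: CartoonParams, s1: float) -> float:
    """Peak of u1 for a pulse S = s1 on (0, tau_e), zero after.

    In the ``tau_e << tau_a`` limit the peak is ``(1 - 1/e) * s1`` (about
    2/3 of the pulse amplitude).  Requires a linear transduction function;
    warns when ``tau_a/tau_e < 100`` since the limit is then inaccurate.
    """
    if params.tau_a / params.tau_e < 100:
        warnings.warn(
            "tau_a/tau_e < 100: the short-pulse limit 2*S1/3 is not accurate",
            stacklevel=2,
        )
    if s1 == 0:
        return 0.0
    te = params.tau_e
    protocol = StimulusProtocol([Segment(0.0, te, s1)])
    traj = integrate_cartoon(params, protocol, dt=te / 200.0, t_end=5.0 * te)
    return float(traj["u1"].max())
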