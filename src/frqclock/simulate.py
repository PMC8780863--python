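"""Method-of-steps integration of the delayed clock model.

The system carries a single retarded variable (*frq* mRNA at t - tau),
so the integrator keeps the full solution grid in memory and resolves
the delayed value by cubic Lagrange interpolation on already-computed
points.  The scheme is a fixed-step classical Runge-Kutta (RK4); with
dt <= tau/20 every delayed lookup lies at least 19 steps in the past,
so interpolation never reaches unknown values.

Light forcing is discontinuous, which would ruin a smooth stepper at
the transitions.  The step size is therefore snapped down so that every
phase duration is an integer number of steps: each step then sees a
constant light level (evaluated at the step midpoint) and every light
transition coincides with a grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .model import STATE_NAMES, ModelParameters, ModelState
from .protocols import LDProtocol, light_at

__all__ = ["Trajectory", "simulate", "aligned_dt"]

DEFAULT_DT = 0.01  # h
DEFAULT_HISTORY = ModelState.uniform(0.1)


@dataclass(frozen=True)
class Trajectory:
    """Dense solution of one simulation run.

    ``states`` has one row per time point, columns ordered as
    :data:`frqclock.model.STATE_NAMES`.  The protocol, parameters,
    step size and initial history are carried along so the run can be
    reproduced exactly.
    """

    times: np.ndarray
    states: np.ndarray
    protocol: LDProtocol
    params: ModelParameters
    dt: float
    history: ModelState

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def series(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) pair for one state component."""
        return self.times, self.component(name)

    @property
    def light(self) -> np.ndarray:
        return np.array([light_at(self.protocol, t) for t in self.times])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df["light"] = self.light
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def aligned_dt(protocol: LDProtocol, dt: float) -> float:
    """Largest step <= ``dt`` for which every light transition of
    ``protocol`` falls on a grid point.

    Durations are treated as rationals (denominator <= 1e6), their GCD
    taken, and that GCD subdivided into equal steps no larger than the
    requested dt.  Constant protocols need no alignment.
    """
    durations = [Fraction(d).limit_denominator(10**6) for d, _ in protocol.phases]
    if protocol.t0 != 0.0:
        durations.append(Fraction(protocol.t0).limit_denominator(10**6))
    if not protocol.periodic and len(protocol.phases) == 1:
        return dt
    g = durations[0]
    for d in durations[1:]:
        g = Fraction(math.gcd(g.numerator * d.denominator, d.numerator * g.denominator),
                     g.denominator * d.denominator)
    n = max(1, math.ceil(g / Fraction(dt).limit_denominator(10**6)))
    return float(g / n)


def simulate(
    params: ModelParameters,
    protocol: LDProtocol,
    t_end: float,
    dt: float = DEFAULT_DT,
    history: ModelState = DEFAULT_HISTORY,
) -> Trajectory:
    """Integrate the model from constant pre-zero history to ``t_end``.

    Parameters
    ----------
    params, protocol
        Model parameter set and light schedule.
    t_end : float
        Final time (h), > 0.
    dt : float
        Requested step (h); snapped down so light transitions align with
        the grid.  Must satisfy dt <= tau/20.
    history : ModelState
        State held constant for all t <= 0 (the method-of-steps initial
        history).  Componentwise >= 0.

    Returns
    -------
    Trajectory
        Uniform-grid solution, deterministic for identical inputs.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if dt > params.tau / 20.0:
        raise ValueError(
            f"dt={dt} too large for tau={params.tau}: need dt <= tau/20 = "
            f"{params.tau / 20.0:g} so delayed lookups stay behind the "
            "integration front; reduce dt"
        )
    if any(x < 0 for x in history):
        raise ValueError("history must be componentwise >= 0")

    dt = aligned_dt(protocol, dt)
    n_steps = math.ceil(round(t_end / dt, 9))
    times = np.arange(n_steps + 1) * dt

    # unpack parameters to locals: the inner loop is pure scalar math
    p = params
    v_dark, v_light, K_I, h = p.v_dark, p.v_light, p.K_I, p.h
    d_M, k_s, tau, d_F = p.d_M, p.k_s_eff, p.tau, p.d_F
    v_w, k_fw, d_Mw, k_w = p.v_w, p.k_fw, p.d_Mw, p.k_w_eff
    d_Wd, d_Wl, k_act, k_rel = p.d_Wd, p.d_Wl, p.k_act, p.k_rel
    K_V, k_v, d_V = p.K_V, p.k_v_eff, p.d_V
    KIh = K_I ** h

    out = np.empty((n_steps + 1, 6))
    out[0] = history
    M_hist = out[:, 0]  # view: delayed lookups read column 0
    M0 = float(history.M_frq)

    def m_delayed(s: float) -> float:
        # M_frq at absolute time s (s <= current front - 19*dt)
        if s <= 0.0:
            return M0
        u = s / dt
        i0 = int(u)
        if i0 + 2 >= n_steps + 1:
            i0 = n_steps - 2
        lo = max(0, i0 - 1)
        if lo + 3 > n_steps:
            lo = n_steps - 3
        x = u - lo
        y0, y1, y2, y3 = M_hist[lo], M_hist[lo + 1], M_hist[lo + 2], M_hist[lo + 3]
        # cubic Lagrange on the 4 unit-spaced points lo..lo+3
        return (
            -y0 * (x - 1) * (x - 2) * (x - 3) / 6.0
            + y1 * x * (x - 2) * (x - 3) / 2.0
            - y2 * x * (x - 1) * (x - 3) / 2.0
            + y3 * x * (x - 1) * (x - 2) / 6.0
        )

    def rhs(M, F, Mw, Wd, Wl, V, M_tau, L):
        repress = KIh / (KIh + (F if F > 0.0 else 0.0) ** h)
        act = k_act * L * Wd / (1.0 + V / K_V)
        return (
            v_dark * Wd * repress + v_light * Wl - d_M * M,
            k_s * M_tau - d_F * F,
            v_w + k_fw * F - d_Mw * Mw,
            k_w * Mw - act + k_rel * Wl - d_Wd * Wd,
            act - k_rel * Wl - d_Wl * Wl,
            k_v * Wl - d_V * V,
        )

    half = dt / 2.0
    sixth = dt / 6.0
    y = [float(x) for x in history]
    for i in range(n_steps):
        t = i * dt
        L = light_at(protocol, t + half)  # constant within the step
        Md0 = m_delayed(t - tau)
        Mdh = m_delayed(t + half - tau)
        Md1 = m_delayed(t + dt - tau)

        k1 = rhs(*y, Md0, L)
        y2 = [y[j] + half * k1[j] for j in range(6)]
        k2 = rhs(*y2, Mdh, L)
        y3 = [y[j] + half * k2[j] for j in range(6)]
        k3 = rhs(*y3, Mdh, L)
        y4 = [y[j] + dt * k3[j] for j in range(6)]
        k4 = rhs(*y4, Md1, L)

        y = [
            y[j] + sixth * (k1[j] + 2.0 * (k2[j] + k3[j]) + k4[j])
            for j in range(6)
        ]
        # trajectories are nonnegative up to integration error; clip
        y = [x if x > 0.0 else 0.0 for x in y]
        s = y[0] + y[1] + y[2] + y[3] + y[4] + y[5]
        if not math.isfinite(s):
            raise FloatingPointError(
                f"non-finite state at t={t + dt:.3f} h (integration blow-up); "
                "check parameters or reduce dt"
            )
        out[i + 1] = y

    return Trajectory(times=times, states=out, protocol=protocol,
                      params=params, dt=dt, history=history)
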