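"""Time integration of the replicator system and convergence measurement.

The vector field is tangent to the unit cube (each component's rate carries
an ``s(s-1)`` prefactor), so trajectories analytically never leave
``[0,1]^3``; clamping after integration only corrects solver round-off.
Time units are abstract — the model defines no calendar — so convergence
times are meaningful only ordinally, for comparing runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import replicator_rates
from .params import GameParameters, StrategyState

__all__ = [
    "SolverSettings",
    "Trajectory",
    "SimulationError",
    "simulate",
    "convergence_time",
    "component_convergence_time",
    "ensemble",
]


class SimulationError(RuntimeError):
    """ODE integration failed; carries the last valid state reached."""

    def __init__(self, message: str, last_state: StrategyState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings.

    horizon
        Length of the integration window in abstract evolutionary time
        (default 50).
    rtol, atol
        Adaptive Runge-Kutta tolerances.
    max_step
        Cap on the solver step (``inf`` leaves the solver free).
    clamp
        Clamp stored states to [0,1] (round-off correction only).
    n_samples
        Number of equally spaced output times (the dense interpolant is kept
        alongside for sub-grid queries).
    """

    horizon: float = 50.0
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = float("inf")
    clamp: bool = True
    n_samples: int = 2001

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("tolerances must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")


@dataclass(frozen=True)
class Trajectory:
    """A solved path: times (strictly increasing, starting at 0) and states
    (n, 3). ``interpolant`` is the solver's dense output, used to refine
    crossing times below the sampling grid."""

    times: np.ndarray
    states: np.ndarray
    interpolant: Callable[[float], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def final_state(self) -> StrategyState:
        return StrategyState.from_array(np.clip(self.states[-1], 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "x": self.states[:, 0],
            "y": self.states[:, 1],
            "z": self.states[:, 2],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def state_at(self, t: float) -> np.ndarray:
        if self.interpolant is not None:
            return np.clip(self.interpolant(t), 0.0, 1.0)
        out = np.empty(3)
        for i in range(3):
            out[i] = np.interp(t, self.times, self.states[:, i])
        return out


def simulate(
    params: GameParameters,
    init: StrategyState,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the replicator ODE from ``init`` over the horizon.

    Corners are exact fixed points (the rates vanish identically there), so
    corner initial conditions yield constant trajectories.
    """
    settings = settings or SolverSettings()

    def rhs(t: float, s: np.ndarray) -> list[float]:
        sc = np.clip(s, 0.0, 1.0)
        return list(replicator_rates(params, StrategyState(*sc)))

    t_eval = np.linspace(0.0, settings.horizon, settings.n_samples)
    sol = solve_ivp(
        rhs, (0.0, settings.horizon), init.as_array(), method="RK45",
        t_eval=t_eval, dense_output=True, rtol=settings.rtol,
        atol=settings.atol, max_step=settings.max_step,
    )
    if not sol.success:
        last = (StrategyState.from_array(np.clip(sol.y[:, -1], 0, 1))
                if sol.y.size else init)
        raise SimulationError(f"solver failed: {sol.message}", last_state=last)
    states = sol.y.T
    if settings.clamp:
        states = np.clip(states, 0.0, 1.0)
    return Trajectory(sol.t, states, interpolant=sol.sol)


def _entry_time(
    traj: Trajectory, inside: Callable[[np.ndarray], float]
) -> float | None:
    """Earliest time after which ``inside(state) <= 0`` holds to the end.

    ``inside`` is a signed margin: non-positive means the state satisfies
    the convergence condition.  The crossing is refined on the dense
    interpolant when available.
    """
    margins = np.array([inside(s) for s in traj.states])
    ok = margins <= 0.0
    if not ok[-1]:
        return None
    # last index where the condition fails; entry is in the following interval
    bad = np.nonzero(~ok)[0]
    if len(bad) == 0:
        return float(traj.times[0])
    i = bad[-1]
    t_lo, t_hi = float(traj.times[i]), float(traj.times[i + 1])
    if traj.interpolant is None:
        return t_hi
    f = lambda t: inside(np.clip(traj.interpolant(t), 0.0, 1.0))
    try:
        if f(t_lo) > 0 and f(t_hi) <= 0:
            return float(brentq(f, t_lo, t_hi, xtol=1e-12))
    except ValueError:
        pass
    return t_hi


def convergence_time(
    traj: Trajectory, target: StrategyState, eps: float
) -> float | None:
    """Earliest time the trajectory enters (and stays in) the max-norm
    ``eps``-ball around ``target``; ``None`` if it never settles there."""
    if not eps > 0:
        raise ValueError("eps must be positive")
    tgt = target.as_array()
    return _entry_time(traj, lambda s: float(np.max(np.abs(s - tgt))) - eps)


def component_convergence_time(
    traj: Trajectory, component: str, eps: float, target: float = 1.0
) -> float | None:
    """Earliest time one component enters (and stays within) ``eps`` of
    ``target``; the standard sweep metric is time to reach ``1 - eps``."""
    if not eps > 0:
        raise ValueError("eps must be positive")
    idx = {"x": 0, "y": 1, "z": 2}[component]
    return _entry_time(traj, lambda s: abs(float(s[idx]) - target) - eps)


def ensemble(
    params: GameParameters,
    inits: Sequence[StrategyState],
    settings: SolverSettings | None = None,
) -> list[Trajectory]:
    """Integrate one trajectory per initial condition, order preserved."""
    return [simulate(params, init, settings) for init in inits]
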