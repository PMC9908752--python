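"""Parameter-sensitivity sweeps over the replicator dynamics.

A sweep varies exactly one of the 17 parameters over an ordered grid,
integrates the system from a common initial state, and measures the time
for a tracked strategy share to settle within ``eps`` of full adoption
(share = 1).  Six built-in scenarios cover the standard policy questions:
the operating subsidy ``We`` and fine ``Ws`` (private-sector adoption of
high quality), the regulation cost ``Cg`` and reward ``Rg`` (government
adoption of active regulation), and the monitoring cost ``Cp`` and reward
``Rp`` (public adoption of monitoring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .dynamics import (SimulationError, SolverSettings, Trajectory,
                       component_convergence_time, simulate)
from .params import PARAM_NAMES, GameParameters, ParameterError, StrategyState

__all__ = [
    "SweepSpec",
    "SweepRun",
    "SweepResult",
    "sweep_parameter",
    "figure_scenarios",
    "SCENARIO_NAMES",
    "monotonicity_report",
]

DEFAULT_INIT = StrategyState(0.2, 0.2, 0.2)
#: Convergence band for timing: tracked share within 0.01 of 1.
DEFAULT_EPS = 0.01
#: Relative convergence-time spread below which a sweep is reported as
#: "indistinguishable".
INDISTINGUISHABLE_REL_SPREAD = 0.05


@dataclass(frozen=True)
class SweepSpec:
    parameter: str
    values: tuple[float, ...]
    track: str  # one of 'x', 'y', 'z'
    init: StrategyState = DEFAULT_INIT
    settings: SolverSettings = field(default_factory=SolverSettings)
    eps: float = DEFAULT_EPS
    label: str | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.track not in ("x", "y", "z"):
            raise ValueError("track must be 'x', 'y' or 'z'")
        vals = tuple(float(v) for v in self.values)
        if len(vals) != len(set(vals)) or not all(math.isfinite(v) for v in vals):
            raise ValueError("swept values must be finite and distinct")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SweepRun:
    """One grid point of a sweep; ``error`` is set (and the rest None) when
    the swept value broke a parameter invariant or the solver failed."""

    value: float
    params: GameParameters | None
    trajectory: Trajectory | None
    convergence_time: float | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    runs: tuple[SweepRun, ...]

    @property
    def times(self) -> list[float | None]:
        return [r.convergence_time for r in self.runs]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: (parameter, value, time, x, y, z) per sample."""
        frames = []
        for run in self.runs:
            if not run.ok:
                continue
            df = run.trajectory.to_frame()
            df.insert(0, "value", run.value)
            df.insert(0, "parameter", self.spec.parameter)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["parameter", "value", "time", "x", "y", "z"])
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for run in self.runs:
            final = run.trajectory.final_state if run.ok else None
            rows.append({
                "parameter": self.spec.parameter,
                "value": run.value,
                "tracked": self.spec.track,
                "convergence_time": run.convergence_time,
                "final_x": final.x if final else None,
                "final_y": final.y if final else None,
                "final_z": final.z if final else None,
                "error": run.error,
            })
        return pd.DataFrame(rows)


def sweep_parameter(base: GameParameters, spec: SweepSpec) -> SweepResult:
    """Run the sweep: all runs share ``spec.init`` and ``spec.settings``;
    only ``spec.parameter`` varies across ``spec.values``."""
    runs: list[SweepRun] = []
    for value in spec.values:
        try:
            params = base.replace(**{spec.parameter: value})
        except ParameterError as exc:
            runs.append(SweepRun(value, None, None, None, error=str(exc)))
            continue
        try:
            traj = simulate(params, spec.init, spec.settings)
        except SimulationError as exc:
            runs.append(SweepRun(value, params, None, None, error=str(exc)))
            continue
        t = component_convergence_time(traj, spec.track, spec.eps)
        runs.append(SweepRun(value, params, traj, t))
    return SweepResult(spec, tuple(runs))


#: Built-in scenario grids.  The We/Ws/Cg/Rg grids follow the standard
#: calibration; the Cp/Rp grids are symmetric around the baseline values
#: (Cp=10, Rp=15) since no canonical grid exists for them.
_SCENARIOS: tuple[tuple[str, str, tuple[float, ...], str], ...] = (
    ("fig4", "We", (30.0, 50.0, 70.0), "x"),
    ("fig5", "Ws", (40.0, 80.0, 120.0), "x"),
    ("fig6", "Cg", (30.0, 45.0, 60.0), "y"),
    ("fig7", "Rg", (20.0, 40.0, 60.0), "y"),
    ("fig8", "Cp", (5.0, 10.0, 15.0), "z"),
    ("fig9", "Rp", (10.0, 15.0, 20.0), "z"),
)

SCENARIO_NAMES: tuple[str, ...] = tuple(s[0] for s in _SCENARIOS)


def figure_scenarios(
    base: GameParameters,
    init: StrategyState = DEFAULT_INIT,
    settings: SolverSettings | None = None,
) -> list[SweepSpec]:
    """The six built-in sweep specifications (``fig4`` .. ``fig9``)."""
    settings = settings or SolverSettings()
    return [
        SweepSpec(parameter=param, values=values, track=track,
                  init=init, settings=settings, label=label)
        for label, param, values, track in _SCENARIOS
    ]


def scenario_by_name(
    base: GameParameters, name: str, **kwargs
) -> SweepSpec:
    for spec in figure_scenarios(base, **kwargs):
        if spec.label == name:
            return spec
    raise KeyError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
    )


def monotonicity_report(
    result: SweepResult,
    rel_tol: float = INDISTINGUISHABLE_REL_SPREAD,
) -> str:
    """Classify how convergence time orders across the sweep grid.

    Returns one of ``"increasing"``, ``"decreasing"``, ``"non-monotone"`` or
    ``"indistinguishable"``.  A run whose tracked share never settles gets
    time ``+inf``.  "Indistinguishable" means all times are finite and no
    time deviates from the median by more than ``rel_tol`` of the median —
    the grid has no practically visible effect.  Raises ``ValueError`` with
    fewer than two successful runs.
    """
    times = [
        (math.inf if r.convergence_time is None else r.convergence_time)
        for r in result.runs if r.ok
    ]
    if len(times) < 2:
        raise ValueError("monotonicity needs at least 2 successful runs")
    if all(math.isfinite(t) for t in times):
        med = sorted(times)[len(times) // 2]
        deviation = max(abs(t - med) for t in times)
        if med > 0 and deviation / med < rel_tol:
            return "indistinguishable"
    if all(a < b for a, b in zip(times, times[1:])):
        return "increasing"
    if all(a > b for a, b in zip(times, times[1:])):
        return "decreasing"
    return "non-monotone"
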