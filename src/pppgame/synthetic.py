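"""Synthetic inputs: the baseline calibration, random parameter regimes,
and random initial states.

``baseline_parameters`` returns the reference calibration under which the
all-cooperate corner (1,1,1) is the unique ESS.  ``sample_parameters`` draws
random parameter sets by rejection against a chosen stability regime, so
tests can probe both sides of each ESS inequality without hand-picked
numbers.  All sampling is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .params import GameParameters, StrategyState
from .stability import ess_margins

__all__ = [
    "UNASSIGNED_IN_BASELINE",
    "baseline_parameters",
    "RegimeSpec",
    "sample_parameters",
    "sample_initial_states",
]

#: Parameters with no calibrated value: they cancel from every payoff
#: difference, so the dynamics are invariant to them.  The defaults below
#: are arbitrary positives used only for payoff-table display.
UNASSIGNED_IN_BASELINE: tuple[str, ...] = ("Mi", "Fi", "R1")

_BASELINE = dict(
    Cp=10.0, Rp=15.0, beta1=30.0, beta2=5.0, Cg=30.0, Rg=20.0,
    alpha1=20.0, alpha2=10.0, CH=70.0, CL=30.0, We=30.0, Ws=80.0,
    Fg=100.0, P=300.0,
)

#: Names of the three ESS inequalities at (1,1,1), i.e. which eigenvalue a
#: targeted violation should flip positive.
ESS_CONSTRAINTS = ("public", "government", "private")


def baseline_parameters(
    Mi: float = 100.0, Fi: float = 100.0, R1: float = 50.0
) -> GameParameters:
    """The reference calibration.

    ``Mi``, ``Fi`` and ``R1`` are not pinned down by the calibration (they
    do not affect the dynamics); their defaults are arbitrary positives —
    see :data:`UNASSIGNED_IN_BASELINE`.
    """
    return GameParameters(Mi=Mi, Fi=Fi, R1=R1, **_BASELINE)


def _default_ranges() -> dict[str, tuple[float, float]]:
    base = baseline_parameters().as_dict()
    return {name: (0.5 * v, 2.0 * v) for name, v in base.items()}


@dataclass(frozen=True)
class RegimeSpec:
    """What constraint set a random parameter draw must satisfy.

    regime
        ``"baseline"`` (no randomness), ``"ess_stable"`` (all three ESS
        inequalities at (1,1,1) hold), ``"ess_violated"`` (the inequality
        named by ``violated`` is reversed, the other two hold), or
        ``"unconstrained"`` (only the structural invariants CH>CL,
        alpha1>alpha2, beta1>beta2).
    ranges
        Per-parameter uniform sampling ranges; defaults to [0.5x, 2x] the
        baseline value.
    seed
        Fixes all randomness.
    """

    regime: str = "unconstrained"
    violated: str | None = None
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=_default_ranges)
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.regime not in ("baseline", "ess_stable", "ess_violated",
                               "unconstrained"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "ess_violated" and self.violated not in ESS_CONSTRAINTS:
            raise ValueError(
                f"violated must be one of {ESS_CONSTRAINTS}, got {self.violated!r}"
            )


def _satisfies(params: GameParameters, spec: RegimeSpec) -> bool:
    if spec.regime == "unconstrained":
        return True
    margins = ess_margins(params)
    if spec.regime == "ess_stable":
        return all(v < 0 for v in margins.values())
    # ess_violated: exactly the targeted inequality reversed
    return all(
        (margins[name] > 0) if name == spec.violated else (margins[name] < 0)
        for name in ESS_CONSTRAINTS
    )


def sample_parameters(spec: RegimeSpec) -> GameParameters:
    """Draw one parameter set satisfying the regime, by rejection sampling.

    Raises ``RuntimeError`` naming the regime when the rejection budget is
    exhausted (infeasible ranges).
    """
    if spec.regime == "baseline":
        return baseline_parameters()
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.ranges)
    for _ in range(spec.max_attempts):
        draw = {n: float(rng.uniform(*spec.ranges[n])) for n in names}
        try:
            params = GameParameters.from_dict(draw)
        except ValueError:
            continue  # structural invariant broken; redraw
        if _satisfies(params, spec):
            return params
    constraint = (f"ess_violated({spec.violated})"
                  if spec.regime == "ess_violated" else spec.regime)
    raise RuntimeError(
        f"rejection budget ({spec.max_attempts}) exhausted for constraint "
        f"{constraint}; ranges may make it infeasible"
    )


def sample_initial_states(
    n: int, seed: int, margin: float = 0.1
) -> list[StrategyState]:
    """``n`` interior states uniform on ``[margin, 1-margin]^3``."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 < margin < 0.5:
        raise ValueError("margin must lie strictly between 0 and 0.5")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(margin, 1.0 - margin, size=(n, 3))
    return [StrategyState(*map(float, row)) for row in pts]
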