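"""Parameter and state containers for the tripartite PPP regulation game.

The game has three bounded-rational populations: a private operator that
either provides high-quality service ("no violation", share ``x``) or cuts
quality ("violation", share ``1-x``); a government that either actively
regulates (share ``y``) or does not; and a public that either participates in
monitoring (share ``z``) or does not.  All payoffs, costs, fines, rewards and
reputation levels are measured in one common dimensionless utility unit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "PARAM_NAMES",
    "ParameterError",
    "GameParameters",
    "StrategyState",
]

#: Canonical parameter names, in the order they are conventionally tabulated.
PARAM_NAMES: tuple[str, ...] = (
    "Mi", "CH", "CL", "We", "Ws", "alpha1", "alpha2", "Fi", "Rg", "Cg",
    "beta1", "beta2", "Rp", "Fg", "Cp", "R1", "P",
)


class ParameterError(ValueError):
    """A parameter set violates one of the model's structural inequalities."""


@dataclass(frozen=True)
class GameParameters:
    """The 17 scalar payoff/cost/reputation parameters of the game.

    Parameters
    ----------
    Mi : float
        Private sector's minimum benefit from user fees.
    CH, CL : float
        Private cost of high- / low-quality service; ``CH > CL`` is required
        (quality costs more).
    We : float
        Operating subsidy paid to a compliant private operator after
        government assessment.
    Ws : float
        Fine the private sector pays when a violation is caught by
        government supervision.
    alpha1, alpha2 : float
        Reputation granted to the private sector by a monitoring public
        under high / low quality; ``alpha1 > alpha2``.
    Fi : float
        Government fixed income.
    Rg : float
        Extra benefit (higher-authority reward, recognition) of active
        regulation.
    Cg : float
        Cost of active regulation.
    beta1, beta2 : float
        Government reputation under public scrutiny when regulating / not;
        ``beta1 > beta2``.
    Rp : float
        Reward the government pays to a monitoring public.
    Fg : float
        Penalty to a non-regulating government when an undetected violation
        is exposed by the public.
    Cp : float
        Public's monitoring cost.
    R1 : float
        Damage the public suffers from low-quality service.
    P : float
        Compensation the public receives for reporting that damage.

    Notes
    -----
    ``Mi``, ``Fi`` and ``R1`` shift every cell of the respective player's
    payoff row equally, so they cancel from all payoff differences and have
    no effect on the replicator dynamics.
    """

    Mi: float
    CH: float
    CL: float
    We: float
    Ws: float
    alpha1: float
    alpha2: float
    Fi: float
    Rg: float
    Cg: float
    beta1: float
    beta2: float
    Rp: float
    Fg: float
    Cp: float
    R1: float
    P: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the first violated constraint."""
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise ParameterError(f"parameter {name} must be >= 0, got {value!r}")
        if not self.CH > self.CL:
            raise ParameterError(
                f"CH > CL is required (high quality costs more); got CH={self.CH}, CL={self.CL}"
            )
        if not self.alpha1 > self.alpha2:
            raise ParameterError(
                f"alpha1 > alpha2 is required; got alpha1={self.alpha1}, alpha2={self.alpha2}"
            )
        if not self.beta1 > self.beta2:
            raise ParameterError(
                f"beta1 > beta2 is required; got beta1={self.beta1}, beta2={self.beta2}"
            )

    # -- conversion ---------------------------------------------------------

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "GameParameters":
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(data)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def replace(self, **changes: float) -> "GameParameters":
        """Return a copy with the given parameters changed (revalidated)."""
        return dataclasses.replace(self, **changes)

    # -- file I/O (flat key-value YAML or JSON) -----------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "GameParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:  # YAML is a superset of JSON, so this also covers odd suffixes
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))


@dataclass(frozen=True)
class StrategyState:
    """A population mixed-strategy point ``(x, y, z)`` in the unit cube.

    ``x`` — share of private operators providing high-quality service;
    ``y`` — share of government agents actively regulating;
    ``z`` — share of the public participating in monitoring.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"strategy share {name} must lie in [0, 1], got {v!r}")

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y
        yield self.z

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StrategyState":
        x, y, z = (float(v) for v in arr)
        return cls(x, y, z)

    def is_corner(self, tol: float = 0.0) -> bool:
        return all(min(v, 1.0 - v) <= tol for v in self)
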