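"""Model core: payoff table, expected payoffs, replicator dynamics.

The 2x2x2 stage game assigns each of the eight pure-strategy outcomes a
payoff triple (private, government, public).  Replicator dynamics then let
each population's strategy share grow in proportion to the payoff advantage
of that strategy over the population mean:

    dx/dt = x (x - 1) G(y, z),   G = CH - CL - We - z (a1 - a2) - y Ws
    dy/dt = y (y - 1) J(x, z),   J = Cg - Rg - z (b1 - b2) - (1-x) z Fg - (1-x) Ws
    dz/dt = z (z - 1) D(x),      D = Cp - Rp - P + P x

where ``G``, ``J``, ``D`` are the switching functions: when negative, the
corresponding strategy share drifts upward on the open interval (0, 1).

Two independent routes to the same rates are provided: the closed forms
above, and :func:`replicator_rates_oracle`, which rebuilds the expected
payoffs by summing payoff-table cells weighted by the other two populations'
mixed strategies.  Their agreement is the core internal-consistency check
between the payoff table and the closed-form algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .params import GameParameters, StrategyState

__all__ = [
    "PureOutcome",
    "PayoffTriple",
    "PayoffTable",
    "RateVector",
    "Threshold",
    "Thresholds",
    "build_payoff_table",
    "expected_private_payoffs",
    "expected_government_payoffs",
    "expected_public_payoffs",
    "replicator_rates",
    "replicator_rates_oracle",
    "switching_functions",
    "switching_values",
    "critical_thresholds",
]


@dataclass(frozen=True)
class PureOutcome:
    """One of the 8 pure-strategy outcomes of the stage game."""

    private_no_violation: bool
    government_supervises: bool
    public_participates: bool

    @classmethod
    def all(cls) -> tuple["PureOutcome", ...]:
        return tuple(
            cls(bool(h), bool(s), bool(p))
            for h in (1, 0) for s in (1, 0) for p in (1, 0)
        )


@dataclass(frozen=True)
class PayoffTriple:
    private: float
    government: float
    public: float

    def __iter__(self) -> Iterator[float]:
        yield self.private
        yield self.government
        yield self.public


PayoffTable = dict[PureOutcome, PayoffTriple]


@dataclass(frozen=True)
class RateVector:
    """Replicator rates (dx/dt, dy/dt, dz/dt); all zero at cube corners."""

    dx_dt: float
    dy_dt: float
    dz_dt: float

    def __iter__(self) -> Iterator[float]:
        yield self.dx_dt
        yield self.dy_dt
        yield self.dz_dt


def build_payoff_table(params: GameParameters) -> PayoffTable:
    """Build the payoff triple for every pure outcome.

    Conventions of the stage game: the operating subsidy ``We`` is paid only
    for compliant operation; the fine ``Ws`` moves from private sector to
    government only when a violation occurs under supervision; the exposure
    penalty ``Fg`` hits the government only for an unsupervised violation
    caught by a participating public; reputation terms (``alpha*``,
    ``beta*``) accrue only when the public participates; a participating
    public is paid ``Rp`` and damaged members receive compensation ``P``.
    """
    params.validate()
    p = params
    table: PayoffTable = {}
    for outcome in PureOutcome.all():
        h, s, m = (outcome.private_no_violation, outcome.government_supervises,
                   outcome.public_participates)
        if h:
            private = p.Mi + p.We - p.CH + (p.alpha1 if m else 0.0)
            public = (p.Rp - p.Cp) if m else 0.0
            if s:
                government = (p.Fi + p.Rg - p.Cg - (p.Rp if m else 0.0)
                              + (p.beta1 if m else 0.0))
            else:
                government = p.Fi + ((p.beta2 - p.Rp) if m else 0.0)
        else:
            fined = s  # the fine is collected only under supervision
            private = p.Mi - p.CL + (p.alpha2 if m else 0.0) - (p.Ws if fined else 0.0)
            public = (p.Rp - p.Cp - p.R1 + p.P) if m else -p.R1
            if s:
                government = (p.Fi + p.Rg + p.Ws - p.Cg - (p.Rp if m else 0.0)
                              + (p.beta1 if m else 0.0))
            else:
                government = p.Fi + ((p.beta2 - p.Rp - p.Fg) if m else 0.0)
        table[outcome] = PayoffTriple(private, government, public)
    return table


# ---------------------------------------------------------------------------
# expected payoffs (closed forms)
# ---------------------------------------------------------------------------

def expected_private_payoffs(
    params: GameParameters, state: StrategyState
) -> tuple[float, float, float]:
    """Expected payoff of high quality (Y11), low quality (Y12), and the
    population mean ``x*Y11 + (1-x)*Y12``."""
    p, (x, y, z) = params, state
    y11 = (y * z * (p.Mi + p.We + p.alpha1 - p.CH)
           + (1 - y) * z * (p.Mi + p.We + p.alpha1 - p.CH)
           + y * (1 - z) * (p.Mi + p.We - p.CH)
           + (1 - y) * (1 - z) * (p.Mi + p.We - p.CH))
    y12 = (y * z * (p.Mi + p.alpha2 - p.CL - p.Ws)
           + (1 - y) * z * (p.Mi + p.alpha2 - p.CL)
           + y * (1 - z) * (p.Mi - p.CL - p.Ws)
           + (1 - y) * (1 - z) * (p.Mi - p.CL))
    return y11, y12, x * y11 + (1 - x) * y12


def expected_government_payoffs(
    params: GameParameters, state: StrategyState
) -> tuple[float, float, float]:
    """Expected payoff of regulating (Y21), not regulating (Y22), and mean."""
    p, (x, y, z) = params, state
    y21 = (x * z * (p.Fi + p.Rg + p.beta1 - p.Cg - p.Rp)
           + x * (1 - z) * (p.Fi + p.Rg - p.Cg)
           + (1 - x) * z * (p.Fi + p.Rg + p.Ws + p.beta1 - p.Cg - p.Rp)
           + (1 - x) * (1 - z) * (p.Fi + p.Rg + p.Ws - p.Cg))
    y22 = (x * z * (p.Fi + p.beta2 - p.Rp)
           + x * (1 - z) * p.Fi
           + (1 - x) * z * (p.Fi + p.beta2 - p.Rp - p.Fg)
           + (1 - x) * (1 - z) * p.Fi)
    return y21, y22, y * y21 + (1 - y) * y22


def expected_public_payoffs(
    params: GameParameters, state: StrategyState
) -> tuple[float, float, float]:
    """Expected payoff of monitoring (Y31), not monitoring (Y32), and mean."""
    p, (x, y, z) = params, state
    y31 = (x * y * (p.Rp - p.Cp)
           + x * (1 - y) * (p.Rp - p.Cp)
           + (1 - x) * y * (p.Rp - p.Cp - p.R1 + p.P)
           + (1 - x) * (1 - y) * (p.Rp - p.Cp - p.R1 + p.P))
    y32 = (1 - x) * y * (-p.R1) + (1 - x) * (1 - y) * (-p.R1)
    return y31, y32, z * y31 + (1 - z) * y32


# ---------------------------------------------------------------------------
# replicator dynamics
# ---------------------------------------------------------------------------

def switching_values(
    params: GameParameters, x: float, y: float, z: float
) -> tuple[float, float, float]:
    """(G, J, D) evaluated at raw coordinates, without the [0,1] check.

    The switching functions are affine in each share, so evaluating them
    outside the cube is meaningful — e.g. to verify that an out-of-range
    critical threshold is still an exact root.
    """
    p = params
    g = p.CH - p.CL - p.We - z * (p.alpha1 - p.alpha2) - y * p.Ws
    j = (p.Cg - p.Rg - z * (p.beta1 - p.beta2)
         - (1 - x) * z * p.Fg - (1 - x) * p.Ws)
    d = p.Cp - p.Rp - p.P + p.P * x
    return g, j, d


def switching_functions(
    params: GameParameters, state: StrategyState
) -> tuple[float, float, float]:
    """Return (G, J, D): the payoff-difference brackets of the replicator
    equations.  ``G < 0`` drives x upward on (0,1); similarly J for y and
    D for z."""
    return switching_values(params, state.x, state.y, state.z)


def replicator_rates(params: GameParameters, state: StrategyState) -> RateVector:
    """Closed-form replicator rates for the three populations."""
    x, y, z = state
    g, j, d = switching_functions(params, state)
    return RateVector(x * (x - 1) * g, y * (y - 1) * j, z * (z - 1) * d)


def replicator_rates_oracle(
    params: GameParameters, state: StrategyState
) -> RateVector:
    """Replicator rates rebuilt from the payoff table (independent route).

    Each strategy's expected payoff is the sum of payoff-table cells
    weighted by the other two populations' mixed strategies; the rate is
    ``share * (own-strategy payoff - population mean)``.
    """
    table = build_payoff_table(params)
    x, y, z = state

    def cell(h: bool, s: bool, m: bool) -> PayoffTriple:
        return table[PureOutcome(h, s, m)]

    def w(prob: float, on: bool) -> float:
        return prob if on else 1.0 - prob

    y11 = sum(w(y, s) * w(z, m) * cell(True, s, m).private
              for s in (True, False) for m in (True, False))
    y12 = sum(w(y, s) * w(z, m) * cell(False, s, m).private
              for s in (True, False) for m in (True, False))
    y21 = sum(w(x, h) * w(z, m) * cell(h, True, m).government
              for h in (True, False) for m in (True, False))
    y22 = sum(w(x, h) * w(z, m) * cell(h, False, m).government
              for h in (True, False) for m in (True, False))
    y31 = sum(w(x, h) * w(y, s) * cell(h, s, True).public
              for h in (True, False) for s in (True, False))
    y32 = sum(w(x, h) * w(y, s) * cell(h, s, False).public
              for h in (True, False) for s in (True, False))

    return RateVector(
        x * (y11 - (x * y11 + (1 - x) * y12)),
        y * (y21 - (y * y21 + (1 - y) * y22)),
        z * (y31 - (z * y31 + (1 - z) * y32)),
    )


# ---------------------------------------------------------------------------
# critical thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Threshold:
    """A critical opposing-population mixture at which a switching function
    vanishes.  ``value`` is returned unclipped (out-of-range thresholds mean
    the drift direction is fixed over the whole feasible interval)."""

    value: float
    finite: bool
    in_range: bool

    @classmethod
    def of(cls, value: float) -> "Threshold":
        finite = math.isfinite(value)
        return cls(value, finite, finite and 0.0 <= value <= 1.0)

    @classmethod
    def none(cls) -> "Threshold":
        return cls(math.nan, False, False)


@dataclass(frozen=True)
class Thresholds:
    y_star: Threshold  # government share at which G(y) = 0, given z
    z_star: Threshold  # public share at which J(z) = 0, given x
    x_star: Threshold  # private share at which D(x) = 0


def critical_thresholds(params: GameParameters, state: StrategyState) -> Thresholds:
    """Thresholds y*(z), z*(x), x* where G, J, D change sign.

    y* = [CH - CL - We - z (a1 - a2)] / Ws
    z* = [Rg - Cg + (1-x) Ws] / [(x-1) Fg - (b1 - b2)]
    x* = (P + Rp - Cp) / P
    """
    p, (x, _, z) = params, state
    y_star = (Threshold.of((p.CH - p.CL - p.We - z * (p.alpha1 - p.alpha2)) / p.Ws)
              if p.Ws != 0 else Threshold.none())
    denom = (x - 1) * p.Fg - (p.beta1 - p.beta2)
    z_star = (Threshold.of((p.Rg - p.Cg + (1 - x) * p.Ws) / denom)
              if denom != 0 else Threshold.none())
    x_star = (Threshold.of((p.P + p.Rp - p.Cp) / p.P)
              if p.P != 0 else Threshold.none())
    return Thresholds(y_star, z_star, x_star)
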