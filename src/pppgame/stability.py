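"""Equilibrium stability: Jacobian, pure equilibria, eigenvalue classification.

The replicator system has eight pure (corner) fixed points.  At every
corner the prefactors ``x(x-1)``, ``y(y-1)``, ``z(z-1)`` kill all
off-diagonal Jacobian entries, so the corner eigenvalues are exactly the
three diagonal terms ``(2x-1)G``, ``(2y-1)J``, ``(2z-1)D``.  A corner is an
evolutionary stable strategy (ESS) of the dynamics iff all three are
negative; a zero eigenvalue makes the linearization inconclusive
(non-hyperbolic).

The reference classification table prints each corner's eigenvalues in a
row-specific order; :func:`table3_eigen_expressions` reproduces both the
printed symbolic expressions and the permutation back to (x, y, z)
component order, so the symbolic and numeric routes can be compared
entry-for-entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp

from .model import replicator_rates, switching_functions
from .params import PARAM_NAMES, GameParameters, StrategyState

__all__ = [
    "EquilibriumReport",
    "ClassificationResult",
    "jacobian",
    "pure_equilibria",
    "table3_eigen_expressions",
    "corner_eigenvalues",
    "classify_equilibrium",
    "classify_all",
    "ess_margins",
]

#: Default tolerance below which an eigenvalue counts as zero.
DEFAULT_TOL = 1e-9

_SYMS = {name: sp.Symbol(name, real=True) for name in PARAM_NAMES}


def jacobian(params: GameParameters, state: StrategyState) -> np.ndarray:
    """Evaluate the 3x3 Jacobian of the replicator vector field at ``state``.

    Rows differentiate (dx/dt, dy/dt, dz/dt) with respect to (x, y, z).
    Note the (z, y) entry is identically zero: the public's switching
    function D depends only on x.
    """
    p, (x, y, z) = params, state
    g, j, d = switching_functions(params, state)
    return np.array([
        [(2 * x - 1) * g, -x * (x - 1) * p.Ws, -x * (x - 1) * (p.alpha1 - p.alpha2)],
        [y * (y - 1) * (z * p.Fg + p.Ws), (2 * y - 1) * j,
         y * (y - 1) * (-(p.beta1 - p.beta2) - (1 - x) * p.Fg)],
        [z * (z - 1) * p.P, 0.0, (2 * z - 1) * d],
    ])


def pure_equilibria() -> list[StrategyState]:
    """The 8 corner fixed points E1..E8, in conventional order."""
    corners = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
               (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    return [StrategyState(*c) for c in corners]


def _t3(expr_str: str) -> sp.Expr:
    return sp.sympify(expr_str, locals=_SYMS)


# Printed eigenvalue expressions per corner, with the permutation mapping
# printed position -> state component whose diagonal Jacobian entry it is.
_TABLE3: dict[tuple[int, int, int], tuple[tuple[str, str, str], tuple[str, str, str]]] = {
    (0, 0, 0): (("CL - CH + We", "P - Cp + Rp", "Rg - Cg + Ws"), ("x", "z", "y")),
    (1, 0, 0): (("Rg - Cg", "Rp - Cp", "CH - CL - We"), ("y", "z", "x")),
    (0, 1, 0): (("Cg - Rg - Ws", "P - Cp + Rp", "CL - CH + We + Ws"), ("y", "z", "x")),
    (0, 0, 1): (("Cp - P - Rp", "alpha1 - alpha2 - CH + CL + We",
                 "beta1 - beta2 - Cg + Fg + Rg + Ws"), ("z", "x", "y")),
    (1, 1, 0): (("Cg - Rg", "Rp - Cp", "CH - CL - We - Ws"), ("y", "z", "x")),
    (1, 0, 1): (("Cp - Rp", "beta1 - beta2 - Cg + Rg",
                 "alpha2 - alpha1 + CH - CL - We"), ("z", "y", "x")),
    (0, 1, 1): (("Cp - P - Rp", "beta2 - beta1 + Cg - Fg - Rg - Ws",
                 "alpha1 - alpha2 - CH + CL + We + Ws"), ("z", "y", "x")),
    (1, 1, 1): (("Cp - Rp", "beta2 - beta1 + Cg - Rg",
                 "alpha2 - alpha1 + CH - CL - We - Ws"), ("z", "y", "x")),
}


def _corner_key(corner: StrategyState) -> tuple[int, int, int]:
    key = (round(corner.x), round(corner.y), round(corner.z))
    if key not in _TABLE3 or not corner.is_corner():
        raise ValueError(f"not a pure-strategy corner: {tuple(corner)}")
    return key


def table3_eigen_expressions(
    corner: StrategyState,
) -> tuple[tuple[sp.Expr, sp.Expr, sp.Expr], tuple[str, str, str]]:
    """Symbolic eigenvalue expressions for a corner, in printed order.

    Returns ``(expressions, components)`` where ``components[i]`` names the
    state component (``'x'``, ``'y'`` or ``'z'``) whose Jacobian diagonal
    entry ``expressions[i]`` is.
    """
    exprs, order = _TABLE3[_corner_key(corner)]
    return tuple(_t3(e) for e in exprs), order


@lru_cache(maxsize=None)
def _table3_lambdified(key: tuple[int, int, int]):
    exprs, order = _TABLE3[key]
    args = [_SYMS[name] for name in PARAM_NAMES]
    return [sp.lambdify(args, _t3(e), "math") for e in exprs], order


def table3_eigenvalues(params: GameParameters, corner: StrategyState) -> dict[str, float]:
    """Numeric values of the printed symbolic expressions, keyed by component."""
    funcs, order = _table3_lambdified(_corner_key(corner))
    vals = [f(*(getattr(params, n) for n in PARAM_NAMES)) for f in funcs]
    return {comp: float(v) for comp, v in zip(order, vals)}


def corner_eigenvalues(
    params: GameParameters, corner: StrategyState
) -> tuple[float, float, float]:
    """Eigenvalues at a corner in (x, y, z) component order.

    At corners the Jacobian is diagonal, so these are just the diagonal
    entries ``(2x-1)G``, ``(2y-1)J``, ``(2z-1)D``.
    """
    _corner_key(corner)
    x, y, z = corner
    g, j, d = switching_functions(params, corner)
    return ((2 * x - 1) * g, (2 * y - 1) * j, (2 * z - 1) * d)


@dataclass(frozen=True)
class EquilibriumReport:
    """Stability verdict for one corner fixed point.

    ``eigenvalues`` are in (x, y, z) component order; ``eigenvalues_sorted``
    is the ascending view.  ``verdict`` is ``"ESS"`` when all eigenvalues are
    below ``-tol``, ``"unstable"`` when some eigenvalue exceeds ``+tol``, and
    ``"non-hyperbolic"`` otherwise; ``non_hyperbolic`` additionally flags any
    eigenvalue within ``tol`` of zero (linearization inconclusive in that
    direction, even if a positive eigenvalue already settles instability).
    """

    point: StrategyState
    eigenvalues: tuple[float, float, float]
    sign_pattern: tuple[str, str, str]
    verdict: str
    non_hyperbolic: bool
    tol: float

    @property
    def eigenvalues_sorted(self) -> tuple[float, float, float]:
        return tuple(sorted(self.eigenvalues))

    @property
    def is_ess(self) -> bool:
        return self.verdict == "ESS"


def classify_equilibrium(
    params: GameParameters, corner: StrategyState, tol: float = DEFAULT_TOL
) -> EquilibriumReport:
    """Classify one corner by the signs of its three eigenvalues."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    eig = corner_eigenvalues(params, corner)
    signs = tuple("0" if abs(v) <= tol else ("-" if v < 0 else "+") for v in eig)
    non_hyp = "0" in signs
    if all(s == "-" for s in signs):
        verdict = "ESS"
    elif any(s == "+" for s in signs):
        verdict = "unstable"
    else:
        verdict = "non-hyperbolic"
    return EquilibriumReport(corner, eig, signs, verdict, non_hyp, tol)


@dataclass(frozen=True)
class ClassificationResult:
    reports: tuple[EquilibriumReport, ...]

    @property
    def ess(self) -> tuple[StrategyState, ...]:
        return tuple(r.point for r in self.reports if r.is_ess)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.reports, start=1):
            rows.append({
                "corner": f"E{i}",
                "x": r.point.x, "y": r.point.y, "z": r.point.z,
                "eig_x": r.eigenvalues[0], "eig_y": r.eigenvalues[1],
                "eig_z": r.eigenvalues[2],
                "signs": "".join(r.sign_pattern),
                "verdict": r.verdict,
                "non_hyperbolic": r.non_hyperbolic,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(self.to_frame().to_dict(orient="records"), indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def classify_all(
    params: GameParameters, tol: float = DEFAULT_TOL
) -> ClassificationResult:
    """Classify all 8 corners; the ESS set is exposed on the result."""
    return ClassificationResult(
        tuple(classify_equilibrium(params, c, tol) for c in pure_equilibria())
    )


def ess_margins(params: GameParameters) -> dict[str, float]:
    """Advisory: the three eigenvalues of the all-cooperate corner (1,1,1).

    The corner is an ESS iff all three margins are negative:
    ``Cp - Rp < 0``, ``beta2 - beta1 + Cg - Rg < 0`` and
    ``alpha2 - alpha1 + CH - CL - We - Ws < 0``.  Not enforced as a
    parameter invariant — sweeps may legitimately cross them.
    """
    p = params
    return {
        "public": p.Cp - p.Rp,
        "government": p.beta2 - p.beta1 + p.Cg - p.Rg,
        "private": p.alpha2 - p.alpha1 + p.CH - p.CL - p.We - p.Ws,
    }


def numeric_eigenvalues(params: GameParameters, state: StrategyState) -> np.ndarray:
    """Eigenvalues of the full Jacobian via a general eigensolver (any state)."""
    return np.linalg.eigvals(jacobian(params, state))


def interior_equilibrium(
    params: GameParameters, guess: StrategyState | None = None
) -> StrategyState | None:
    """Optional numeric search for an interior rest point (untested against
    any reference; corner analysis is the supported surface)."""
    from scipy.optimize import fsolve

    x0 = guess.as_array() if guess is not None else np.array([0.5, 0.5, 0.5])
    sol, info, ier, _ = fsolve(
        lambda s: list(replicator_rates(params, StrategyState(*np.clip(s, 0, 1)))),
        x0, full_output=True,
    )
    if ier != 1 or np.any(sol < -1e-9) or np.any(sol > 1 + 1e-9):
        return None
    return StrategyState(*np.clip(sol, 0.0, 1.0))
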