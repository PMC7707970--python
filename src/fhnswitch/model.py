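"""Deterministic analysis of the bistable FitzHugh-Nagumo (FN) system.

The model is the two-variable neuron reduction

    du/dt = c (e u - u^3/3 - v)        (membrane potential)
    dv/dt = c (a u - b v)              (linear recovery variable)

with positive kinetic constants ``a, b, c`` and excitability parameter ``e``.
The cubic equation for equilibria factorises exactly: ``u0 = 0`` always, and a
symmetric pair ``u0 = ±sqrt(3 (e - a/b))`` branches off in a supercritical
pitchfork at ``e = a/b``.  For ``e > a/b`` the system is bistable -- the outer
equilibria (the "resting" and "firing" branches) are linearly stable and the
origin is a saddle-like unstable point separating the two basins.

Stability is classified through the Routh-Hurwitz conditions on the 2x2
Jacobian: with characteristic polynomial ``lambda^2 + c1 lambda + c0`` the
equilibrium is asymptotically stable iff ``c1 > 0`` and ``c0 > 0``, which
reduces to ``u0^2 > max(e - b, (b e - a)/b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FNParams",
    "StatePoint",
    "EquilibriumSet",
    "StabilityReport",
    "vector_field",
    "find_equilibria",
    "jacobian",
    "characteristic_coeffs",
    "hurwitz_stable",
    "bifurcation_diagram",
    "write_bifurcation_csv",
]

#: |e - a/b| below which the parameter set is reported as critical (at the
#: pitchfork point itself).
CRITICAL_TOL = 1e-12

#: sup-norm tolerance for "point is an equilibrium" checks.
EQUILIBRIUM_TOL = 1e-8


class StatePoint(NamedTuple):
    """A point (u, v) in the phase plane."""

    u: float
    v: float


@dataclass(frozen=True)
class FNParams:
    """Kinetic constants of the FN system (all dimensionless, all > 0)."""

    a: float
    b: float
    c: float
    e: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "e"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"FNParams.{name} must be finite and > 0, got {val!r}")

    @property
    def e_critical(self) -> float:
        """Pitchfork location e* = a/b."""
        return self.a / self.b


@dataclass(frozen=True)
class EquilibriumSet:
    """Equilibria of the FN system, sorted by u, with stability flags.

    ``regime`` is ``"monostable"`` (one equilibrium, e < a/b), ``"critical"``
    (at the pitchfork) or ``"bistable"`` (three equilibria, e > a/b).
    """

    points: tuple[StatePoint, ...]
    stability_flags: tuple[bool, ...]
    regime: str

    def __post_init__(self) -> None:
        if len(self.points) not in (1, 3):
            raise ValueError("EquilibriumSet must hold 1 or 3 points")
        if len(self.points) != len(self.stability_flags):
            raise ValueError("points and stability_flags length mismatch")

    @property
    def stable_points(self) -> tuple[StatePoint, ...]:
        return tuple(p for p, s in zip(self.points, self.stability_flags) if s)


@dataclass(frozen=True)
class StabilityReport:
    """Routh-Hurwitz report at a single equilibrium.

    ``trace_condition`` is c1 = -tr(J) = c b - c e + c u0^2 and
    ``det_condition`` is c0 = det(J) = c b (c u0^2 - c e) + a c^2;
    the point is Hurwitz-stable iff both are positive.  ``marginal`` flags
    the untreated boundary case where a condition is exactly zero (reported
    as unstable).
    """

    trace_condition: float
    det_condition: float
    hurwitz_stable: bool
    eigenvalues: tuple[complex, complex]
    marginal: bool = False


def _check_state(state: Sequence[float]) -> StatePoint:
    u, v = float(state[0]), float(state[1])
    if not (np.isfinite(u) and np.isfinite(v)):
        raise ValueError(f"state must be finite, got ({u!r}, {v!r})")
    return StatePoint(u, v)


def vector_field(params: FNParams, state: Sequence[float]) -> tuple[float, float]:
    """Evaluate (du/dt, dv/dt) at a phase-plane point."""
    u, v = _check_state(state)
    du = params.c * (params.e * u - u**3 / 3.0 - v)
    dv = params.c * (params.a * u - params.b * v)
    return du, dv


def find_equilibria(params: FNParams) -> EquilibriumSet:
    """All equilibria in closed form, sorted by u, with stability flags.

    The nullcline intersection reduces to ``u0 (u0^2 - 3 (e - a/b)) = 0`` and
    ``v0 = a u0 / b``, so the equilibria are exact up to float rounding.
    """
    gap = params.e - params.e_critical
    if abs(gap) < CRITICAL_TOL:
        regime = "critical"
        u_roots = [0.0]
    elif gap < 0:
        regime = "monostable"
        u_roots = [0.0]
    else:
        regime = "bistable"
        r = float(np.sqrt(3.0 * gap))
        u_roots = [-r, 0.0, r]
    points = tuple(StatePoint(u0, params.a * u0 / params.b) for u0 in u_roots)
    flags = tuple(hurwitz_stable(params, p, _warn=False).hurwitz_stable for p in points)
    return EquilibriumSet(points=points, stability_flags=flags, regime=regime)


def jacobian(params: FNParams, point: Sequence[float]) -> np.ndarray:
    """Jacobian matrix [[c e - c u0^2, -c], [c a, -c b]] at a point."""
    u0, _ = _check_state(point)
    a, b, c, e = params.a, params.b, params.c, params.e
    return np.array([[c * e - c * u0**2, -c], [c * a, -c * b]], dtype=float)


def characteristic_coeffs(params: FNParams, point: Sequence[float]) -> tuple[float, float]:
    """Coefficients (c1, c0) of the characteristic polynomial l^2 + c1 l + c0.

    Identically c1 = -trace(J) and c0 = det(J).
    """
    u0, _ = _check_state(point)
    a, b, c, e = params.a, params.b, params.c, params.e
    c1 = c * b - c * e + c * u0**2
    c0 = c * b * (c * u0**2 - c * e) + a * c**2
    return c1, c0


def hurwitz_stable(params: FNParams, point: Sequence[float], *, _warn: bool = True) -> StabilityReport:
    """Routh-Hurwitz stability classification at an equilibrium.

    Warns if the supplied point is not an equilibrium (the classification is
    then formal).  A condition that is exactly zero is marginal: reported as
    unstable with ``marginal=True``.
    """
    pt = _check_state(point)
    if _warn:
        f = vector_field(params, pt)
        if max(abs(f[0]), abs(f[1])) > EQUILIBRIUM_TOL:
            warnings.warn(
                f"hurwitz_stable called at non-equilibrium point {tuple(pt)}; "
                "classification is formal",
                stacklevel=2,
            )
    c1, c0 = characteristic_coeffs(params, pt)
    disc = c1 * c1 - 4.0 * c0
    sq = np.sqrt(complex(disc))
    eigs = ((-c1 + sq) / 2.0, (-c1 - sq) / 2.0)
    marginal = c1 == 0.0 or c0 == 0.0
    stable = (c1 > 0.0) and (c0 > 0.0)
    return StabilityReport(
        trace_condition=c1,
        det_condition=c0,
        hurwitz_stable=stable,
        eigenvalues=eigs,
        marginal=marginal,
    )


def bifurcation_diagram(params: FNParams, e_grid: Iterable[float]) -> pd.DataFrame:
    """Equilibrium branches over a grid of excitability values.

    Returns a tidy frame with columns ``e, u0, v0, stable``: one row per
    (e, branch).  One branch for e <= a/b, three for e > a/b, the outer
    branches following ±sqrt(3 (e - a/b)).
    """
    rows = []
    for e_val in e_grid:
        e_val = float(e_val)
        if e_val <= 0:
            raise ValueError("e_grid values must be positive")
        p = FNParams(params.a, params.b, params.c, e_val)
        eq = find_equilibria(p)
        for pt, stab in zip(eq.points, eq.stability_flags):
            rows.append({"e": e_val, "u0": pt.u, "v0": pt.v, "stable": bool(stab)})
    return pd.DataFrame(rows, columns=["e", "u0", "v0", "stable"])


def write_bifurcation_csv(df: pd.DataFrame, path) -> None:
    """Write a bifurcation table as columnar text (CSV)."""
    df.to_csv(path, index=False)
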