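"""Two-strain Lotka-Volterra competition from carrying-capacity measurements.

A pair of competing strains with monoculture carrying capacities K1, K2 and
competition coefficients a12, a21 follows

    dN1/dt = r1 N1 (1 - (N1 + a12 N2)/K1)
    dN2/dt = r2 N2 (1 - (N2 + a21 N1)/K2).

When a co-culture settles at total biomass K_co with strain-1 fraction p1,
the observed point (N1*, N2*) = (p1 K_co, (1-p1) K_co) must lie on both zero
isoclines, which pins down the coefficients:

    a12 = (K1 - N1*) / N2*,      a21 = (K2 - N2*) / N1*.

Mutual invasibility (a12 < K1/K2 and a21 < K2/K1) then classifies the
equilibrium: stable coexistence, competitive exclusion, or founder control.
Carrying capacities are kept in whatever consistent biomass unit the
measurements use (here, dry weight in g per 30 ml).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LVSystem",
    "competition_coefficients",
    "classify_equilibrium",
    "equilibrium_point",
    "expected_mixture_capacity",
    "simulate_lv",
    "DegenerateEquilibriumError",
]


class DegenerateEquilibriumError(ValueError):
    """Raised for boundary or parallel-isocline degeneracies."""


@dataclass(frozen=True)
class LVSystem:
    """Two-strain Lotka-Volterra competition parameters.

    ``r1``/``r2`` (1/h) only matter for time-domain simulation; the
    equilibrium and its classification are independent of them.
    """

    K1: float
    K2: float
    alpha12: float
    alpha21: float
    r1: float = 1.0
    r2: float = 1.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("carrying capacities must be positive")
        if self.alpha12 < 0 or self.alpha21 < 0:
            raise ValueError("competition coefficients must be non-negative "
                             "(negative values indicate facilitation; see "
                             "competition_coefficients warnings)")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("intrinsic rates must be positive")


def competition_coefficients(
    K1: float, K2: float, K_co: float, p1: float
) -> tuple[float, float, list[str]]:
    """Solve the isocline equations for (a12, a21) from capacity measurements.

    The co-culture equilibrium is taken as N1* = p1*K_co, N2* = (1-p1)*K_co;
    substituting into N1* + a12*N2* = K1 and N2* + a21*N1* = K2 gives the
    coefficients directly.  A solved coefficient coming out negative is
    biologically facilitation; it is returned as-is with a warning flag
    rather than clipped.

    Returns ``(alpha12, alpha21, warnings)``.
    """
    if K1 <= 0 or K2 <= 0 or K_co <= 0:
        raise ValueError("carrying capacities must be positive")
    if not 0.0 < p1 < 1.0:
        raise DegenerateEquilibriumError(
            "p1 must lie strictly in (0,1); a boundary proportion admits no "
            "interior equilibrium"
        )
    n1 = p1 * K_co
    n2 = (1.0 - p1) * K_co
    alpha12 = (K1 - n1) / n2
    alpha21 = (K2 - n2) / n1
    warnings = [
        f"alpha{tag} negative ({val:.4g}): implies facilitation"
        for tag, val in (("12", alpha12), ("21", alpha21))
        if val < 0
    ]
    return float(alpha12), float(alpha21), warnings


EquilibriumClass = Literal[
    "stable_coexistence", "exclusion_of_1", "exclusion_of_2", "founder_control"
]


def classify_equilibrium(sys: LVSystem, tol: float = 0.0) -> EquilibriumClass:
    """Classify the competitive outcome by the mutual-invasibility rule.

    Strain 1 can invade a strain-2 monoculture iff a12 < K1/K2, and vice
    versa.  Both invade -> stable coexistence; exactly one fails -> exclusion
    of the non-invader; both fail -> founder control (the initial majority
    wins).  Equality within ``tol`` raises: the outcome is structurally
    degenerate.
    """
    c1 = sys.K1 / sys.K2  # threshold for alpha12
    c2 = sys.K2 / sys.K1
    if abs(sys.alpha12 - c1) <= tol or abs(sys.alpha21 - c2) <= tol:
        raise DegenerateEquilibriumError(
            "competition coefficient equals the invasion threshold; "
            "classification is degenerate"
        )
    inv1 = sys.alpha12 < c1  # strain 1 invades strain 2's monoculture
    inv2 = sys.alpha21 < c2
    if inv1 and inv2:
        return "stable_coexistence"
    if inv1 and not inv2:
        return "exclusion_of_2"
    if inv2 and not inv1:
        return "exclusion_of_1"
    return "founder_control"


def equilibrium_point(sys: LVSystem) -> tuple[float, float]:
    """Interior equilibrium (N1*, N2*) solving both isocline equations.

    Raises :class:`DegenerateEquilibriumError` when a12*a21 = 1 (parallel
    isoclines) or when the interior solution is not strictly positive (the
    relevant equilibria are then on the boundary: (K1, 0) or (0, K2)).
    """
    det = 1.0 - sys.alpha12 * sys.alpha21
    if det == 0.0:
        raise DegenerateEquilibriumError("alpha12*alpha21 = 1: parallel isoclines")
    n1 = (sys.K1 - sys.alpha12 * sys.K2) / det
    n2 = (sys.K2 - sys.alpha21 * sys.K1) / det
    if n1 <= 0 or n2 <= 0:
        raise DegenerateEquilibriumError(
            f"no positive interior equilibrium (solution ({n1:.4g}, {n2:.4g})); "
            "equilibria lie on the boundary"
        )
    return float(n1), float(n2)


def expected_mixture_capacity(K1: float, K2: float, p1: float) -> float:
    """Co-culture capacity expected from proportion-weighted monoculture capacities.

    Simply p1*K1 + (1-p1)*K2 — the null against which an observed co-culture
    capacity is compared (a one-sample t-test on replicate co-culture
    measurements serves as the significance check).
    """
    if not 0.0 < p1 < 1.0:
        raise ValueError("p1 must lie strictly in (0,1)")
    return p1 * K1 + (1.0 - p1) * K2


def simulate_lv(
    sys: LVSystem,
    init: tuple[float, float],
    duration: float,
    n_points: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the two-strain LV system from ``init`` for ``duration`` hours.

    Returns ``(times, densities)`` with densities of shape (n_points, 2).
    """
    n10, n20 = init
    if n10 < 0 or n20 < 0:
        raise ValueError("initial densities must be non-negative")

    def rhs(_t, y):
        n1, n2 = y
        return [
            sys.r1 * n1 * (1.0 - (n1 + sys.alpha12 * n2) / sys.K1),
            sys.r2 * n2 * (1.0 - (n2 + sys.alpha21 * n1) / sys.K2),
        ]

    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(rhs, (0.0, duration), [n10, n20], method="LSODA",
                    rtol=1e-10, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"LV integration failed: {sol.message}")
    return sol.t, sol.y.T
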