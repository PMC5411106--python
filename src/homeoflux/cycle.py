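"""Microscopic transporter cycle behind activity-dependent downregulation.

The cycle: external nutrient binds a free transporter (``T0 + S_ext ->
C1``, rate ``kon``; reverse ``koff``), the complex undergoes a conformational
change (``C1 -> C2``, rate ``kc``), and the inward-facing complex either
releases the nutrient into the cell and resets (``C2 -> T0 + S_int``, rate
``kr``) or is recognized in that conformation and irreversibly modified
(``C2 -> Tm``, rate ``km``), which downregulates it.

Because uptake and downregulation both exit from the same species ``C2``,
their fluxes are ``kr*C2`` and ``km*C2``: the ratio is ``km/kr`` exactly, at
every external concentration.  Coarse-graining the quasi-steady-state cycle
gives exactly the Michaelian uptake law with an activity-proportional
downregulation rate -- the microscopic justification for the
``kgammaT = kgTa * S_ext/(S_ext+Kext)`` term of the whole-cell models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .models import ModelSpec, ParameterSet, build_model

__all__ = [
    "CycleRates",
    "CycleState",
    "CycleFluxes",
    "CoarseGrained",
    "DeadEndCycleError",
    "cycle_fluxes",
    "coarse_grain",
    "whole_cell_cycle_steady_state",
    "whole_cell_cycle_rhs",
    "coarse_grained_model",
    "relax_whole_cell_cycle",
]


class DeadEndCycleError(ValueError):
    """Both exits from the inward-facing complex are closed (kr = km = 0)."""


@dataclass(frozen=True)
class CycleRates:
    """Mass-action rate constants of the transporter cycle.

    kon (1/concentration/time), koff (1/time), kc conformational change
    (1/time), kr nutrient release = uptake (1/time), km modification =
    downregulation (1/time).
    """

    kon: float = 1.0
    koff: float = 1.0
    kc: float = 1.0
    kr: float = 1.0
    km: float = 0.1

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "kc", "kr", "km"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"cycle rate {name!r} must be finite and >= 0")


@dataclass(frozen=True)
class CycleState:
    """Concentrations of the cycle species (all >= 0)."""

    T0: float   # free, outward-facing transporter
    C1: float   # nutrient-bound, outward-facing complex
    C2: float   # nutrient-bound, inward-facing complex
    Tm: float = 0.0  # modified (inactivated) transporter

    @property
    def total(self) -> float:
        return self.T0 + self.C1 + self.C2 + self.Tm


@dataclass(frozen=True)
class CycleFluxes:
    """Quasi-steady-state exit fluxes of the cycle."""

    uptake_flux: float          # kr * C2  (concentration/time)
    downregulation_flux: float  # km * C2  (concentration/time)
    effective_u: float          # uptake per active transporter (1/time)
    effective_kgT: float        # downregulation per active transporter (1/time)
    state: CycleState


@dataclass(frozen=True)
class CoarseGrained:
    """Michaelis-form parameters matching the cycle's uptake law."""

    kcat_eff: float
    Kext_eff: float
    kgTa_eff: float
    max_rel_fit_error: float
    worst_S_ext: float


def cycle_fluxes(rates: CycleRates, S_ext: float, total_T: float) -> CycleFluxes:
    """Quasi-steady-state fluxes for an active pool ``T0+C1+C2 = total_T``.

    The intermediate distribution solves the linear balance
    ``kon*S_ext*T0 = (koff+kc)*C1`` and ``kc*C1 = (kr+km)*C2``; modification
    is treated as a slow exit, so the active pool is held fixed.
    """
    if total_T <= 0:
        raise ValueError("total_T must be positive")
    if S_ext < 0:
        raise ValueError("S_ext must be >= 0")
    if rates.kr == 0 and rates.km == 0:
        raise DeadEndCycleError(
            "kr = km = 0: the inward-facing complex has no exit")
    a = rates.koff + rates.kc
    b = rates.kr + rates.km
    # Relative weights (T0 : C1 : C2) = (a*b : kon*S*b : kon*S*kc).
    w0 = a * b
    w1 = rates.kon * S_ext * b
    w2 = rates.kon * S_ext * rates.kc
    tot = w0 + w1 + w2
    T0 = total_T * w0 / tot
    C1 = total_T * w1 / tot
    C2 = total_T * w2 / tot
    return CycleFluxes(
        uptake_flux=rates.kr * C2,
        downregulation_flux=rates.km * C2,
        effective_u=rates.kr * C2 / total_T,
        effective_kgT=rates.km * C2 / total_T,
        state=CycleState(T0=T0, C1=C1, C2=C2),
    )


def coarse_grain(rates: CycleRates, total_T: float = 1.0,
                 fit_decades: float = 4.0, fit_points: int = 81,
                 tol: float = 0.01) -> CoarseGrained:
    """Reduce the cycle to the Michaelian whole-cell form.

    The quasi-steady-state uptake per transporter is exactly Michaelian::

        u(S_ext) = kcat_eff * S_ext / (S_ext + Kext_eff)
        kcat_eff = kr*kc / (kc + kr + km)
        Kext_eff = (koff+kc)*(kr+km) / (kon*(kc + kr + km))

    and ``kgTa_eff = kcat_eff * km/kr`` carries the exact flux-ratio identity.
    The closed form is verified against :func:`cycle_fluxes` on a log grid
    spanning ``fit_decades`` decades around ``Kext_eff``; a relative error
    above ``tol`` is reported with the worst point.
    """
    if rates.kr == 0 and rates.km == 0:
        raise DeadEndCycleError(
            "kr = km = 0: the inward-facing complex has no exit")
    denom = rates.kc + rates.kr + rates.km
    kcat_eff = rates.kr * rates.kc / denom
    kgTa_eff = rates.km * rates.kc / denom
    if rates.kon == 0:
        raise ValueError("kon must be positive to define Kext_eff")
    Kext_eff = (rates.koff + rates.kc) * (rates.kr + rates.km) / (rates.kon * denom)
    half = fit_decades / 2.0
    grid = Kext_eff * np.logspace(-half, half, fit_points)
    worst_err, worst_se = 0.0, grid[0]
    for se in grid:
        u_cycle = cycle_fluxes(rates, se, total_T).effective_u
        u_mm = kcat_eff * se / (se + Kext_eff)
        err = abs(u_cycle - u_mm) / max(u_mm, 1e-300)
        if err > worst_err:
            worst_err, worst_se = err, se
    cg = CoarseGrained(kcat_eff=kcat_eff, Kext_eff=Kext_eff,
                       kgTa_eff=kgTa_eff, max_rel_fit_error=worst_err,
                       worst_S_ext=worst_se)
    if worst_err > tol:
        raise RuntimeError(
            f"coarse-grained Michaelis fit off by {worst_err:.3%} at "
            f"S_ext={worst_se:g} (tolerance {tol:.0%}); diagnostics: {cg}")
    return cg


def whole_cell_cycle_rhs(rates: CycleRates, aT: float, kgS: float,
                         S_ext: float):
    """RHS of the embedded system (states: S_int, T0, C1, C2).

    Synthesis ``aT`` replenishes the free transporter pool, usage drains
    ``S_int`` at rate ``kgS``, and modified transporters leave the system.
    """
    def rhs(t, y):
        S_int, T0, C1, C2 = y
        bind = rates.kon * S_ext * T0
        return [
            rates.kr * C2 - kgS * S_int,
            aT - bind + rates.koff * C1 + rates.kr * C2,
            bind - (rates.koff + rates.kc) * C1,
            rates.kc * C1 - (rates.kr + rates.km) * C2,
        ]
    return rhs


def whole_cell_cycle_steady_state(rates: CycleRates, aT: float, kgS: float,
                                  S_ext: float) -> dict:
    """Closed-form steady state of the embedded cycle system.

    With modification the only transporter sink, synthesis balances it:
    ``aT = km*C2``, so ``S_int_ss = kr*aT/(km*kgS)`` -- independent of
    ``S_ext``, the mechanistic realization of perfect homeostasis.
    """
    if rates.km == 0:
        raise DeadEndCycleError(
            "km = 0: no transporter sink; the embedded system has no steady state")
    if S_ext <= 0 or rates.kon == 0 or rates.kc == 0:
        raise DeadEndCycleError("cycle stalls: no flux through C2 to balance synthesis")
    C2 = aT / rates.km
    C1 = (rates.kr + rates.km) * C2 / rates.kc
    T0 = (rates.koff + rates.kc) * C1 / (rates.kon * S_ext)
    S_int = rates.kr * C2 / kgS
    return {
        "S_int_ss": S_int,
        "state": CycleState(T0=T0, C1=C1, C2=C2),
        "active_T": T0 + C1 + C2,
    }


def coarse_grained_model(rates: CycleRates, aT: float = 1.0,
                         kgS: float = 1.0) -> ModelSpec:
    """Whole-cell activity-dependent model with cycle-derived parameters."""
    cg = coarse_grain(rates)
    params = ParameterSet(kcat=cg.kcat_eff, Kext=cg.Kext_eff, kgS=kgS,
                          aT=aT, kgTc=0.0, kgTa=cg.kgTa_eff)
    return build_model("activity_dependent", params)


def relax_whole_cell_cycle(rates: CycleRates, aT: float, kgS: float,
                           S_ext: float, y0=None, t_max: float = 1e4):
    """Integrate the embedded cycle system (numerical oracle)."""
    rhs = whole_cell_cycle_rhs(rates, aT, kgS, S_ext)
    if y0 is None:
        y0 = [0.0, 1.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_max), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    return sol
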