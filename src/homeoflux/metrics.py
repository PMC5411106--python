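"""Robustness and efficiency of homeostatic architectures.

*Robustness* ``r(S_ext)`` is the steady-state internal concentration at a
given external concentration divided by its supremum over all external
concentrations; ``r = 1`` everywhere is global perfect homeostasis, and
``0 <= r <= 1`` otherwise.  *Efficiency* ``e`` is the total nutrient carried
by a single transporter over its average lifetime, i.e. the uptake flux per
downregulation flux ``e = (T*u)/(kgammaT*T) = u/kgammaT`` at steady state.

For the monotone families (uptake enters only through the transporter
occupancy ``x = S_ext/(S_ext+Kext)`` and ``S_int_ss`` is nondecreasing in
``x``) the supremum is the analytic saturation limit ``x -> 1``, so the
normalizer never suffers grid truncation.  Sensor-based variants need not be
monotone, and their supremum is taken over a dense auxiliary grid plus the
saturation limit (flagged as such).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelSpec
from .steady import NoSteadyStateError, solve_steady_state

__all__ = [
    "RobustnessProfile",
    "EfficiencyValue",
    "InfiniteLifetimeError",
    "ProfileError",
    "MONOTONE_IN_X",
    "sint_saturation_limit",
    "sint_supremum",
    "robustness_profile",
    "normalized_Sint",
    "efficiency",
]

#: Variants whose steady-state S_int depends on S_ext only through the
#: occupancy x and is nondecreasing in it (supremum at saturation).
MONOTONE_IN_X = frozenset({
    "no_regulation", "activity_dependent", "synthesis_repression",
    "downreg_by_Sint", "combined", "internal_flux_sensor",
})

# Effectively infinite external concentration: occupancies round to 1.0.
_SATURATING_S_EXT = 1e30


class InfiniteLifetimeError(ZeroDivisionError):
    """Downregulation rate is zero at steady state: unbounded lifetime."""


class ProfileError(RuntimeError):
    """A steady state is missing at a named grid point."""


@dataclass
class RobustnessProfile:
    """Steady states and robustness on an external-concentration grid.

    ``normalizer`` is the supremum of ``S_int_ss`` used to normalize;
    ``normalizer_source`` records whether it is the analytic saturation limit
    or a (dense) grid maximum.  ``S0 = kcat*aT/(kgS*kgTc)`` is the reference
    internal concentration used to scale saturation constants.
    """

    grid: np.ndarray
    S_int_values: np.ndarray
    T_values: np.ndarray
    r_values: np.ndarray
    normalizer: float
    normalizer_source: str  # analytic_limit | grid_max
    S0: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "S_ext": self.grid,
            "S_int_ss": self.S_int_values,
            "T_ss": self.T_values,
            "r": self.r_values,
        })


@dataclass(frozen=True)
class EfficiencyValue:
    """Nutrient molecules transported per transporter over its lifetime."""

    e: float
    S_ext: float


def sint_saturation_limit(model: ModelSpec) -> float:
    """Steady-state S_int in the saturated limit S_ext -> infinity."""
    return solve_steady_state(model, _SATURATING_S_EXT).S_int_ss


def sint_supremum(model: ModelSpec, extra_grid=None) -> tuple[float, str]:
    """Supremum of ``S_int_ss`` over ``S_ext in (0, inf)`` and its provenance."""
    if model.name in MONOTONE_IN_X:
        return sint_saturation_limit(model), "analytic_limit"
    candidates = []
    try:
        candidates.append(sint_saturation_limit(model))
    except NoSteadyStateError:
        pass
    scan = np.geomspace(1e-6, 1e6, 481) * model.params.Kext
    if extra_grid is not None:
        scan = np.union1d(scan, np.asarray(extra_grid, dtype=float))
    for se in scan:
        try:
            candidates.append(solve_steady_state(model, se).S_int_ss)
        except NoSteadyStateError:
            continue
    if not candidates:
        raise ProfileError(f"{model.name}: no steady state anywhere on the scan")
    return max(candidates), "grid_max"


def _solve_grid(model: ModelSpec, grid: np.ndarray):
    S = np.empty_like(grid)
    Tv = np.empty_like(grid)
    for i, se in enumerate(grid):
        try:
            ss = solve_steady_state(model, se)
        except NoSteadyStateError as exc:
            raise ProfileError(
                f"{model.name}: no steady state at grid point "
                f"S_ext={se!r} (index {i})") from exc
        S[i], Tv[i] = ss.S_int_ss, ss.T_ss
    return S, Tv


def robustness_profile(model: ModelSpec, S_ext_grid) -> RobustnessProfile:
    """Robustness ``r = S_int_ss / sup S_int_ss`` on the given grid."""
    grid = np.asarray(S_ext_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("S_ext_grid must be strictly increasing and 1-D")
    S, Tv = _solve_grid(model, grid)
    norm, source = sint_supremum(model, extra_grid=grid)
    if norm <= 0:
        raise ProfileError(f"{model.name}: supremum of S_int_ss is zero")
    return RobustnessProfile(
        grid=grid, S_int_values=S, T_values=Tv, r_values=S / norm,
        normalizer=norm, normalizer_source=source, S0=model.params.S0)


def normalized_Sint(model: ModelSpec, S_ext_grid) -> np.ndarray:
    """S_int_ss normalized by its high-S_ext limit (may exceed 1).

    This is the variant of the robustness metric used for sensor-mismatch
    analyses, where the saturation limit is the natural reference even when
    it is not the maximum.
    """
    grid = np.asarray(S_ext_grid, dtype=float)
    S, _ = _solve_grid(model, grid)
    limit = sint_saturation_limit(model)
    if limit <= 0:
        raise ProfileError(f"{model.name}: high-S_ext limit of S_int_ss is zero")
    return S / limit


def efficiency(model: ModelSpec, S_ext: float) -> EfficiencyValue:
    """Per-transporter lifetime uptake ``e = u/kgammaT`` at steady state."""
    try:
        ss = solve_steady_state(model, S_ext)
    except NoSteadyStateError as exc:
        if float(model.kgT(S_ext, 1.0, 1.0)) == 0.0:
            raise InfiniteLifetimeError(
                f"{model.name}: downregulation rate is identically zero at "
                f"S_ext={S_ext}; transporter lifetime (and e) is unbounded"
            ) from exc
        raise
    u = float(model.u(S_ext, ss.S_int_ss, ss.T_ss))
    kgT = float(model.kgT(S_ext, ss.S_int_ss, ss.T_ss))
    if kgT <= 0:
        raise InfiniteLifetimeError(
            f"{model.name}: downregulation rate is zero at S_ext={S_ext}; "
            "transporter lifetime (and e) is unbounded")
    return EfficiencyValue(e=u / kgT, S_ext=float(S_ext))
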