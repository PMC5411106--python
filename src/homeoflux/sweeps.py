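"""Parameter sweeps: robustness heatmaps, sensor-mismatch surfaces,
iso-robustness contours and robustness-efficiency trade-off curves.

All sweeps drive the forward steady-state solver; closed forms never enter
here, so independent algebraic oracles can cross-check the output.  External
concentrations are reported normalized by ``Kext``; the activity-to-basal
downregulation ratio is ``rho = kgTa/kgTc``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .metrics import efficiency, robustness_profile, sint_saturation_limit, normalized_Sint
from .models import ModelSpec, ParameterSet, build_model
from .steady import solve_steady_state

__all__ = [
    "TradeoffCurve",
    "ContourSolution",
    "ContourRangeError",
    "robustness_heatmap",
    "sensor_mismatch_curve",
    "iso_robustness_contour",
    "tradeoff_curve",
    "robustness_at",
    "flatness",
    "DEFAULT_N_GRID",
]

DEFAULT_N_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)

#: Re-evaluation tolerance for contour solutions.
CONTOUR_TOL = 1e-6


class ContourRangeError(ValueError):
    """Requested robustness is outside the achievable interval."""


@dataclass
class ContourSolution:
    """(n, rho) pairs on an iso-robustness contour, with verification."""

    architecture: str
    r_target: float
    S_ext_normalized: float
    pairs: list[tuple[float, float]]          # (n, rho)
    r_achieved: list[float]                   # forward re-evaluation per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": [p[0] for p in self.pairs],
            "rho": [p[1] for p in self.pairs],
            "r_achieved": self.r_achieved,
            "r_target": self.r_target,
        })


@dataclass
class TradeoffCurve:
    """(rho, n, r, e) tuples at fixed normalized external concentration."""

    architecture: str
    n: float
    S_ext_normalized: float
    table: pd.DataFrame  # columns rho, n, r, e, e_normalized

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _arch_model(architecture: str, params: ParameterSet, n: float) -> ModelSpec:
    if architecture == "activity_dependent":
        return build_model("activity_dependent", params)
    if architecture in ("combined", "synthesis_repression"):
        return build_model(architecture, replace(params, n=float(n)))
    raise ValueError(f"unsupported contour architecture {architecture!r}")


def robustness_at(model: ModelSpec, S_ext: float) -> float:
    """Forward-solved robustness at a single external concentration."""
    s = solve_steady_state(model, S_ext).S_int_ss
    return s / sint_saturation_limit(model)


def robustness_heatmap(rho_grid, S_ext_grid,
                       params: ParameterSet | None = None,
                       family: str = "activity_dependent") -> pd.DataFrame:
    """Matrix of robustness ``r(rho, S_ext)`` for the basal-plus-activity family.

    Rows are ratios ``rho = kgTa/kgTc`` (``kgTc`` taken from ``params``),
    columns external concentrations.  Returned as a DataFrame indexed by rho
    with S_ext columns; rows are nondecreasing in rho, columns nondecreasing
    in S_ext for this family.
    """
    params = params or ParameterSet()
    if params.kgTc <= 0:
        raise ValueError("heatmap parameterization needs kgTc > 0 (rho = kgTa/kgTc)")
    rho_grid = np.asarray(rho_grid, dtype=float)
    S_ext_grid = np.asarray(S_ext_grid, dtype=float)
    if np.any(rho_grid < 0) or np.any(S_ext_grid <= 0):
        raise ValueError("grids must be positive (rho may include 0)")
    rows = []
    for rho in rho_grid:
        model = build_model(family, replace(params, kgTa=rho * params.kgTc))
        prof = robustness_profile(model, S_ext_grid)
        rows.append(prof.r_values)
    return pd.DataFrame(np.vstack(rows), index=pd.Index(rho_grid, name="rho"),
                        columns=pd.Index(S_ext_grid, name="S_ext"))


def flatness(values) -> float:
    """Max/min ratio of a positive profile; 1 means perfectly flat."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("flatness needs a nonempty positive profile")
    return float(v.max() / v.min())


def sensor_mismatch_curve(Ksensor_over_Kext_grid, S_ext_grid,
                          params: ParameterSet | None = None) -> pd.DataFrame:
    """Normalized S_int surface for external-sensor downregulation.

    For each affinity ratio, builds the sensor model (no basal degradation
    unless ``params`` says otherwise), normalizes S_int by its high-S_ext
    limit and records the profile plus its flatness (max/min across S_ext).
    Flatness is exactly 1 at ratio 1 and degrades away from it.
    """
    params = params or ParameterSet(kgTc=0.0)
    ratios = np.asarray(Ksensor_over_Kext_grid, dtype=float)
    grid = np.asarray(S_ext_grid, dtype=float)
    records = []
    for ratio in ratios:
        model = build_model(
            "external_sensor", replace(params, Ksensor=ratio * params.Kext))
        vals = normalized_Sint(model, grid)
        fl = flatness(vals)
        for se, v in zip(grid, vals):
            records.append({"Ksensor_over_Kext": ratio, "S_ext": se,
                            "S_int_normalized": v, "flatness": fl})
    return pd.DataFrame.from_records(records)


def _solve_rho_for_target(architecture: str, n: float, r_target: float,
                          S_ext: float, params: ParameterSet) -> float:
    def r_of(rho: float) -> float:
        model = _arch_model(architecture, replace(params, kgTa=rho * params.kgTc), n)
        return robustness_at(model, S_ext)

    r0 = r_of(0.0)
    if abs(r0 - r_target) <= CONTOUR_TOL:
        return 0.0
    if r_target < r0:
        raise ContourRangeError(
            f"r_target={r_target} is below the minimal robustness {r0:.6f} "
            f"reached at rho=0 (n={n}); no downregulation is needed")
    if r_target >= 1.0:
        raise ContourRangeError(
            "r_target = 1 is unreachable at finite rho with kgTc > 0")
    hi = 1.0
    while r_of(hi) < r_target:
        hi *= 4.0
        if hi > 1e14:
            raise ContourRangeError(
                f"r_target={r_target} not reached for rho up to 1e14 (n={n})")
    return brentq(lambda rho: r_of(rho) - r_target, 0.0, hi,
                  xtol=1e-12, rtol=1e-14, maxiter=200)


def _solve_n_for_target(r_target: float, S_ext: float,
                        params: ParameterSet) -> float:
    def r_of(n: float) -> float:
        return robustness_at(_arch_model("synthesis_repression", params, n), S_ext)

    r0 = r_of(0.0)
    if abs(r0 - r_target) <= CONTOUR_TOL:
        return 0.0
    if r_target < r0:
        raise ContourRangeError(
            f"r_target={r_target} is below the n=0 robustness {r0:.6f}")
    hi = 2.0
    while r_of(hi) < r_target:
        hi *= 2.0
        if hi > 128.0:
            raise ContourRangeError(
                f"r_target={r_target} not reached for Hill coefficients up to 128")
    return brentq(lambda n: r_of(n) - r_target, 0.0, hi,
                  xtol=1e-12, rtol=1e-14, maxiter=200)


def iso_robustness_contour(architecture: str, r_target: float,
                           S_ext_normalized: float, n_grid=None,
                           params: ParameterSet | None = None) -> ContourSolution:
    """Parameter pairs achieving a target robustness at fixed S_ext.

    For ``combined``, solves ``rho = kgTa/kgTc`` for every Hill coefficient in
    ``n_grid``; for ``activity_dependent`` the single pair ``(0, rho)``; for
    ``synthesis_repression`` the single pair ``(n, 0)`` with the Hill
    coefficient as the unknown.  Every solution is re-evaluated by an
    independent forward steady-state solve and must land within ``1e-6`` of
    the target.
    """
    params = params or ParameterSet()
    if params.kgTc <= 0 and architecture != "synthesis_repression":
        raise ValueError("contour solving needs kgTc > 0 (rho = kgTa/kgTc)")
    S_ext = S_ext_normalized * params.Kext
    if not 0.0 < r_target < 1.0:
        raise ContourRangeError("r_target must lie in (0, 1)")
    pairs: list[tuple[float, float]] = []
    if architecture == "combined":
        n_values = DEFAULT_N_GRID if n_grid is None else n_grid
        for n in n_values:
            rho = _solve_rho_for_target("combined", float(n), r_target, S_ext, params)
            pairs.append((float(n), rho))
    elif architecture == "activity_dependent":
        rho = _solve_rho_for_target("activity_dependent", 0.0, r_target, S_ext, params)
        pairs.append((0.0, rho))
    elif architecture == "synthesis_repression":
        n = _solve_n_for_target(r_target, S_ext, params)
        pairs.append((n, 0.0))
    else:
        raise ValueError(f"unsupported contour architecture {architecture!r}")

    achieved = []
    for n, rho in pairs:
        model = _arch_model(architecture,
                            replace(params, kgTa=rho * params.kgTc), n)
        r = robustness_at(model, S_ext)
        if abs(r - r_target) > CONTOUR_TOL:
            raise RuntimeError(
                f"contour verification failed: (n={n}, rho={rho}) re-evaluates "
                f"to r={r!r}, target {r_target} (|diff| > {CONTOUR_TOL})")
        achieved.append(r)
    return ContourSolution(architecture=architecture, r_target=r_target,
                           S_ext_normalized=S_ext_normalized, pairs=pairs,
                           r_achieved=achieved)


def tradeoff_curve(architecture: str, n: float, rho_grid,
                   S_ext_normalized: float,
                   params: ParameterSet | None = None) -> TradeoffCurve:
    """Robustness-efficiency pairs along increasing ``rho`` at fixed S_ext.

    Within a curve, ``r`` is nondecreasing and ``e`` nonincreasing in
    ``rho``; the ``rho = 0`` endpoint realizes minimal robustness and maximal
    efficiency.  ``e_normalized`` rescales efficiency by its maximum along
    the curve.
    """
    params = params or ParameterSet()
    if params.kgTc <= 0:
        raise ValueError("trade-off curves need kgTc > 0 (rho = kgTa/kgTc)")
    S_ext = S_ext_normalized * params.Kext
    rho_grid = np.asarray(rho_grid, dtype=float)
    recs = []
    for rho in rho_grid:
        model = _arch_model(architecture, replace(params, kgTa=rho * params.kgTc), n)
        recs.append({
            "rho": rho,
            "n": float(n) if architecture != "activity_dependent" else 0.0,
            "r": robustness_at(model, S_ext),
            "e": efficiency(model, S_ext).e,
        })
    table = pd.DataFrame.from_records(recs)
    table["e_normalized"] = table["e"] / table["e"].max()
    return TradeoffCurve(architecture=architecture, n=float(n),
                         S_ext_normalized=S_ext_normalized, table=table)
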