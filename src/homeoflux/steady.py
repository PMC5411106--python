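"""Steady states of the uptake systems: closed forms, root-finding, relaxation.

For every registry architecture the transporter equation fixes
``T_ss = alphaT(S_int)/kgammaT(S_ext, S_int)`` (or a closed form when
downregulation is nonlinear in ``T``), which reduces the steady-state problem
to one scalar equation in ``S_int``::

    G(S_int) = u(S_ext) * alphaT(S_int) - gammaS(S_int) * kgammaT(S_ext, S_int) = 0

``G`` is strictly decreasing for the Hill-regulated variants, so the root is
unique and bracketed root-finding suffices.  Reported states are always
verified against the right-hand side, and local stability is read off the
Jacobian eigenvalues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .models import ModelSpec, ParameterSet

__all__ = [
    "SteadyState",
    "Trajectory",
    "NoSteadyStateError",
    "SteadyStateError",
    "solve_steady_state",
    "relax_to_steady_state",
    "jacobian_eigenvalues",
    "classify_stability",
]

RESIDUAL_TOL = 1e-9
#: Non-hyperbolicity threshold on eigenvalue real parts.
HYPERBOLIC_TOL = 1e-9


class SteadyStateError(RuntimeError):
    """Solver failure unrelated to existence (bad bracket, no convergence)."""


class NoSteadyStateError(SteadyStateError):
    """The system has no finite steady state (e.g. T grows without bound when
    downregulation vanishes)."""


@dataclass(frozen=True)
class SteadyState:
    """A verified fixed point of the two-variable system.

    ``stable`` is ``True``/``False`` for hyperbolic fixed points and ``None``
    when an eigenvalue real part is (numerically) zero.  ``multiplicity`` is
    the number of nonnegative roots detected when root counting is requested.
    """

    S_int_ss: float
    T_ss: float
    stable: bool | None
    method: str  # closed_form | root_find | relaxation
    residual: float
    eigenvalues: tuple[complex, complex] = field(default=(0j, 0j))
    multiplicity: int = 1


@dataclass
class Trajectory:
    """Time course from :func:`relax_to_steady_state`."""

    t: np.ndarray
    S_int: np.ndarray
    T: np.ndarray
    converged: bool
    final_state: tuple[float, float]
    final_derivative_norm: float


def classify_stability(eigs, tol: float = HYPERBOLIC_TOL) -> bool | None:
    """Stability verdict from eigenvalues: True/False, None if non-hyperbolic."""
    re = [complex(e).real for e in eigs]
    scale = max(1.0, max(abs(r) for r in re))
    if any(abs(r) < tol * scale for r in re):
        return None
    return all(r < 0 for r in re)


def jacobian_eigenvalues(model: ModelSpec, S_ext: float, state) -> np.ndarray:
    """Eigenvalues of the 2x2 Jacobian of (dS_int/dt, dT/dt) at ``state``."""
    S_int, Tval = state
    J = np.asarray(model.jac(S_ext, S_int, Tval), dtype=float)
    return np.linalg.eigvals(J)


def _finish(model, S_ext, S_int, Tval, method, multiplicity=1) -> SteadyState:
    dS, dT = model.rhs(S_int, Tval, S_ext)
    residual = max(abs(dS), abs(dT))
    scale = max(1.0, S_int, Tval)
    if not residual < RESIDUAL_TOL * scale:
        raise SteadyStateError(
            f"{model.name}: candidate state ({S_int}, {Tval}) at S_ext={S_ext} "
            f"has residual {residual:.3e}")
    # Jacobian entries can be singular at exactly zero state (fractional Hill
    # exponents); nudge evaluation point in that case.
    eps = 1e-12
    eigs = jacobian_eigenvalues(
        model, max(S_ext, eps), (max(S_int, eps), max(Tval, eps)))
    return SteadyState(
        S_int_ss=S_int, T_ss=Tval, stable=classify_stability(eigs),
        method=method, residual=residual,
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        multiplicity=multiplicity)


def _T_given_S(model: ModelSpec, S_ext: float, S_int: float) -> float:
    """Transporter level solving dT/dt = 0 at fixed S_int."""
    aT = float(model.aT(S_ext, S_int, 0.0))
    if not model.kgT_depends_on_T:
        kgT = float(model.kgT(S_ext, S_int, 0.0))
        if kgT <= 0:
            if aT == 0:
                return 0.0
            raise NoSteadyStateError(
                f"{model.name}: downregulation rate is zero at S_ext={S_ext} "
                "while synthesis is positive; T grows without bound")
        return aT / kgT
    # Nonlinear-in-T downregulation: solve aT = kgT(S_ext,S_int,T)*T for T.
    g = lambda Tv: aT - float(model.kgT(S_ext, S_int, Tv)) * Tv
    if aT == 0:
        return 0.0
    hi = 1.0
    for _ in range(200):
        if g(hi) < 0:
            break
        hi *= 2.0
    else:
        raise NoSteadyStateError(
            f"{model.name}: downregulation flux never balances synthesis at "
            f"S_ext={S_ext}; T grows without bound")
    return brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def _scalar_G(model: ModelSpec, S_ext: float):
    """G(S_int) whose root is the steady state (monotone for registry models).

    Evaluated in float64 so that overflowing Hill powers saturate to ``inf``
    (and the Hill fractions to their limits) instead of raising.
    """
    S_ext = np.float64(S_ext)
    if not model.kgT_depends_on_T:
        def G(S_int: float) -> float:
            S_int = np.float64(S_int)
            u = float(model.u(S_ext, S_int, 0.0))
            return (u * float(model.aT(S_ext, S_int, 0.0))
                    - float(model.gS(S_ext, S_int, 0.0))
                    * float(model.kgT(S_ext, S_int, 0.0)))
    else:
        def G(S_int: float) -> float:
            S_int = np.float64(S_int)
            Tv = _T_given_S(model, S_ext, S_int)
            u = float(model.u(S_ext, S_int, Tv))
            return Tv * u - float(model.gS(S_ext, S_int, Tv))
    return G


def _upper_bracket(model: ModelSpec) -> float:
    """Safe upper bound on S_int: 10x the unregulated saturated level
    (uptake per transporter never exceeds kcat, so this bounds every
    synthesis-repressed variant; expansion handles weak downregulation)."""
    p = model.params
    kgTc = p.kgTc if p.kgTc and p.kgTc > 0 else None
    base = p.kcat * p.aT / p.kgS / (kgTc if kgTc else 1.0)
    return 10.0 * max(base, 1.0)


def solve_steady_state(
    model: ModelSpec,
    S_ext: float,
    params: ParameterSet | None = None,
    count_roots: bool = False,
) -> SteadyState:
    """Nonnegative steady state of ``model`` at external concentration ``S_ext``.

    Closed forms are used when the scalar reduction is linear in ``S_int``
    (constant synthesis, first-order usage, ``S_int``-independent
    downregulation); Hill-regulated variants fall back to bracketed
    root-finding on ``G``.  Raises :class:`NoSteadyStateError` when ``T``
    diverges (no basal downregulation and no activity), and reports root
    multiplicity when ``count_roots`` is set.
    """
    if params is not None:
        model = model.with_params(params)
    if S_ext < 0:
        raise ValueError("S_ext must be >= 0")

    name = model.name
    p = model.params
    u0 = float(model.u(S_ext, 0.0, 0.0))

    closed = name in (
        "no_regulation", "activity_dependent", "external_sensor",
        "external_linear", "internal_flux_sensor")
    if closed:
        if name == "internal_flux_sensor":
            if u0 <= 0:
                if p.aT == 0:
                    return _finish(model, S_ext, 0.0, 0.0, "closed_form")
                raise NoSteadyStateError(
                    f"{name}: no uptake at S_ext={S_ext}, activity-coupled "
                    "downregulation vanishes; T grows without bound")
            Tss = math.sqrt(p.aT / (p.ksens * u0))
        else:
            Tss = _T_given_S(model, S_ext, 0.0)  # kgT, aT independent of S_int
        if p.kgS == 0:
            if Tss * u0 > 0:
                raise NoSteadyStateError(f"{name}: kgS = 0 with positive uptake")
            Sss = 0.0
        else:
            Sss = Tss * u0 / p.kgS
        return _finish(model, S_ext, Sss, Tss, "closed_form")

    # Hill-regulated (or custom) variants: scalar root-finding in S_int.
    G = _scalar_G(model, S_ext)
    if u0 <= 0:
        # No uptake: S_int = 0 and T balances at S_int = 0 (may not exist).
        Tss = _T_given_S(model, S_ext, 0.0)
        return _finish(model, S_ext, 0.0, Tss, "closed_form")
    lo, hi = 0.0, _upper_bracket(model)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _root_find_branch(model, S_ext, G, lo, hi, count_roots)


def _root_find_branch(model, S_ext, G, lo, hi, count_roots) -> SteadyState:
    glo, ghi = G(lo), G(hi)
    if glo == 0.0:
        root = 0.0
    else:
        if glo * ghi > 0:
            hi *= 100.0  # expand once, then fail loudly
            ghi = G(hi)
            if glo * ghi > 0:
                if glo > 0 and ghi > 0:
                    raise NoSteadyStateError(
                        f"{model.name}: uptake exceeds usage for all "
                        f"S_int <= {hi}; no finite steady state at S_ext={S_ext}")
                raise SteadyStateError(
                    f"{model.name}: could not bracket steady state at "
                    f"S_ext={S_ext}")
        root = brentq(G, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    multiplicity = 1
    states = [root]
    if count_roots:
        grid = np.linspace(lo, hi, 257)
        vals = np.array([G(s) for s in grid])
        roots = []
        for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if va == 0.0 or va * vb < 0:
                r = a if va == 0.0 else brentq(G, a, b, xtol=1e-15,
                                               rtol=8.9e-16, maxiter=200)
                if not roots or abs(r - roots[-1]) > 1e-9 * max(1.0, r):
                    roots.append(r)
        if roots:
            multiplicity = len(roots)
            states = roots
    best = None
    for s in states:
        ss = _finish(model, S_ext, s, _T_given_S(model, S_ext, s),
                     "root_find", multiplicity)
        if best is None or (ss.stable and not best.stable):
            best = ss
    return best


def relax_to_steady_state(
    model: ModelSpec,
    S_ext: float,
    initial_state=(0.0, 1.0),
    t_max: float = 1e4,
    params: ParameterSet | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    deriv_tol: float = 1e-10,
) -> Trajectory:
    """Integrate the ODEs from ``initial_state`` and report the relaxed state.

    Serves as the numerical oracle for :func:`solve_steady_state`.  The run is
    flagged unconverged (partial trajectory still returned) if the final
    derivative norm exceeds ``deriv_tol`` times the state scale at ``t_max``.
    """
    if params is not None:
        model = model.with_params(params)
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    y0 = [float(initial_state[0]), float(initial_state[1])]
    if min(y0) < 0:
        raise ValueError("initial state must be nonnegative")
    sol = solve_ivp(
        model.ode_rhs, (0.0, float(t_max)), y0, args=(float(S_ext),),
        method="LSODA", rtol=rtol, atol=atol, dense_output=False)
    S_arr, T_arr = sol.y
    yf = (float(S_arr[-1]), float(T_arr[-1]))
    dS, dT = model.rhs(yf[0], yf[1], S_ext)
    norm = math.hypot(dS, dT)
    scale = max(1.0, abs(yf[0]), abs(yf[1]))
    return Trajectory(
        t=sol.t, S_int=S_arr, T=T_arr,
        converged=bool(sol.success) and norm < deriv_tol * scale,
        final_state=yf, final_derivative_norm=norm)
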