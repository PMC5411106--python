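"""Deciding global perfect homeostasis.

A system is *globally perfectly homeostatic* when the steady-state internal
nutrient concentration is invariant to the external concentration at every
external concentration: ``d S_int_ss / d S_ext = 0`` for all ``S_ext``.  Three
independent routes decide this:

1. **Reduced symbolic criterion** -- for systems where ``u`` depends only on
   ``S_ext``, ``gammaS`` only on ``S_int`` and fluxes are linear in ``T``, the
   necessary and sufficient condition is that
   ``kgammaT / alphaT`` factor as ``u(S_ext) * func(S_int)``, i.e.
   ``d/dS_ext [ kgammaT / (alphaT * u) ] == 0`` identically.  Equivalently:
   transporter levels at steady state are inversely proportional to the
   per-transporter uptake rate.
2. **Structural rank condition** -- the logarithmic S_ext-sensitivity column
   ``P`` of the four fluxes ``(T*u, gammaS, alphaT, kgammaT*T)`` must lie in
   the parameter-independent subspace ``I`` spanned by the logarithmic
   T-sensitivity column ``M`` and the steady-state flux pairing matrix ``K``:
   ``rank(P|I) = rank(I)`` identically in ``S_ext``.
3. **Numeric sensitivity** -- central-difference logarithmic derivative of
   the solved steady-state map on a grid; perfect when the maximum magnitude
   stays below ``1e-6``.

The three must agree on every architecture they apply to; downregulation that
is nonlinear in ``T`` (the internal flux sensor) is outside the symbolic
templates and is checked numerically only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .models import PARAM_SYMBOLS, S_EXT, S_INT, T, ModelSpec
from .steady import NoSteadyStateError, solve_steady_state

__all__ = [
    "CriterionReport",
    "SensitivityProfile",
    "StructuralMismatchError",
    "CriterionDisagreement",
    "GLOBALLY_PERFECT",
    "LOCALLY_PERFECT_ONLY",
    "NOT_HOMEOSTATIC",
    "PERFECT_SENSITIVITY_TOL",
    "check_reduced_criterion",
    "check_rank_condition",
    "numeric_sensitivity",
    "log_sensitivity_at",
    "default_S_ext_grid",
    "consensus_verdict",
]

GLOBALLY_PERFECT = "globally_perfect"
LOCALLY_PERFECT_ONLY = "locally_perfect_only"
NOT_HOMEOSTATIC = "not_homeostatic_structurally"

#: |d log S_int_ss / d log S_ext| below this counts as perfect.
PERFECT_SENSITIVITY_TOL = 1e-6

#: Seed for the exact-rational fallback of symbolic zero/rank testing.
ZERO_TEST_SEED = 20170417


class StructuralMismatchError(TypeError):
    """Model outside the symbolic template; use the numeric check instead."""


class CriterionDisagreement(AssertionError):
    """The symbolic, structural and numeric verdicts are inconsistent."""


@dataclass
class CriterionReport:
    """Outcome of a homeostasis check.

    ``residual_expr`` is the symbolic expression whose identical vanishing in
    ``S_ext`` would grant global perfection (``None`` when perfect);
    ``special_condition`` names a parameter constraint under which the verdict
    flips, when one exists.
    """

    verdict: str
    method: str
    residual_expr: sp.Expr | None = None
    numeric_max_sensitivity: float | None = None
    special_condition: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def perfect(self) -> bool:
        return self.verdict == GLOBALLY_PERFECT

    def render(self) -> str:
        lines = [f"verdict: {self.verdict}", f"method: {self.method}"]
        if self.residual_expr is not None:
            lines.append(f"residual: {sp.sstr(self.residual_expr)}")
        if self.numeric_max_sensitivity is not None:
            lines.append(
                f"max |dlog S_int/dlog S_ext|: {self.numeric_max_sensitivity:.3e}")
        if self.special_condition:
            lines.append(f"flips under: {self.special_condition}")
        lines.extend(self.notes)
        return "\n".join(lines)


@dataclass
class SensitivityProfile:
    """Per-point logarithmic sensitivity of the steady-state map."""

    grid: np.ndarray
    values: np.ndarray          # NaN where the steady state is missing
    missing: np.ndarray         # boolean mask of missing points

    @property
    def max_abs(self) -> float:
        finite = self.values[~self.missing]
        return float(np.max(np.abs(finite))) if finite.size else math.nan


def default_S_ext_grid(params, lo: float = 1e-2, hi: float = 1e2,
                       num: int = 41) -> np.ndarray:
    """Log-spaced external-concentration grid in units of ``Kext``."""
    return np.geomspace(lo, hi, num) * params.Kext


# ---------------------------------------------------------------------------
# symbolic zero testing

def _rational_points(symbols, n: int, rng: np.random.Generator):
    primes = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43]
    for _ in range(n):
        yield {
            s: sp.Rational(int(rng.integers(1, 97)),
                           int(primes[int(rng.integers(0, len(primes)))]))
            for s in symbols
        }


def _is_zero(expr: sp.Expr, n_samples: int = 50,
             seed: int = ZERO_TEST_SEED) -> bool:
    """Structural zero test: simplify, then exact rational sampling fallback.

    Sampling avoids false negatives from incomplete simplification; exact
    arithmetic avoids false positives from rounding.
    """
    expr = sp.together(sp.expand(expr))
    if expr == 0:
        return True
    simplified = sp.simplify(expr)
    if simplified == 0:
        return True
    syms = sorted(simplified.free_symbols, key=lambda s: s.name)
    if not syms:
        return sp.nsimplify(simplified) == 0
    rng = np.random.default_rng(seed)
    for point in _rational_points(syms, n_samples, rng):
        try:
            val = simplified.subs(point)
        except (ZeroDivisionError, ValueError):
            continue
        if sp.simplify(val) != 0:
            return False
    return True


# ---------------------------------------------------------------------------
# reduced criterion

def _assert_reduced_structure(model: ModelSpec) -> None:
    problems = []
    if S_INT in model.u_expr_sym.free_symbols or T in model.u_expr_sym.free_symbols:
        problems.append("u must depend on S_ext only")
    if S_EXT in model.gS_expr_sym.free_symbols or T in model.gS_expr_sym.free_symbols:
        problems.append("gammaS must depend on S_int only")
    if T in model.aT_expr_sym.free_symbols:
        problems.append("alphaT must be independent of T")
    if model.kgT_depends_on_T or T in model.kgT_expr_sym.free_symbols:
        problems.append("downregulation must be linear in T")
    if problems:
        raise StructuralMismatchError(
            f"{model.name}: outside the reduced template "
            f"({'; '.join(problems)}); use numeric_sensitivity instead")


# Candidate parameter constraints under which an imperfect architecture
# becomes perfect; scanned in order, most specific last.
_SPECIAL_CANDIDATES = (
    ({PARAM_SYMBOLS["kgTc"]: sp.Integer(0)}, "kgTc = 0"),
    ({PARAM_SYMBOLS["Ksensor"]: PARAM_SYMBOLS["Kext"]}, "Ksensor = Kext"),
    ({PARAM_SYMBOLS["kgTc"]: sp.Integer(0),
      PARAM_SYMBOLS["Ksensor"]: PARAM_SYMBOLS["Kext"]},
     "kgTc = 0 and Ksensor = Kext"),
)


def _constraint_already_met(model: ModelSpec, constraint: dict) -> bool:
    p = model.params
    for sym, target in constraint.items():
        if sym == PARAM_SYMBOLS["kgTc"] and p.kgTc != 0:
            return False
        if sym == PARAM_SYMBOLS["Ksensor"] and p.Ksensor != p.Kext:
            return False
    return True


def _steady_state_exists(model: ModelSpec) -> bool:
    try:
        solve_steady_state(model, model.params.Kext)
        return True
    except NoSteadyStateError:
        return False


def check_reduced_criterion(
    model: ModelSpec, compute_numeric: bool = True) -> CriterionReport:
    """Symbolic test of the factorization criterion on a reduced-form model.

    Forms ``Q = kgammaT / (alphaT * u)`` with the model's exact rational
    parameter values and asks whether ``dQ/dS_ext`` vanishes identically on
    the positive orthant.  When it does not, candidate parameter constraints
    (vanishing basal degradation; matched sensor and transporter affinities)
    are scanned on the parameter-symbolic form and reported as the
    ``special_condition`` under which the verdict would flip.
    """
    _assert_reduced_structure(model)
    Q = model.kgT_expr / (model.aT_expr * model.u_expr)
    residual = sp.together(sp.diff(Q, S_EXT))
    report = CriterionReport(verdict=NOT_HOMEOSTATIC, method="reduced_criterion")
    if compute_numeric:
        prof = numeric_sensitivity(model, default_S_ext_grid(model.params))
        report.numeric_max_sensitivity = prof.max_abs

    if _is_zero(residual):
        if _steady_state_exists(model):
            report.verdict = GLOBALLY_PERFECT
            if _constraint_already_met(
                    model, dict(_SPECIAL_CANDIDATES[1][0])) and \
                    PARAM_SYMBOLS["Ksensor"] in model.kgT_expr_sym.free_symbols:
                report.special_condition = "Ksensor = Kext"
            return report
        report.notes.append("criterion holds but no steady state exists")
        report.residual_expr = residual
        return report

    report.residual_expr = sp.simplify(residual)
    Q_sym = model.kgT_expr_sym / (model.aT_expr_sym * model.u_expr_sym)
    numeric_map = model.params.subs_map()
    for constraint, label in _SPECIAL_CANDIDATES:
        if _constraint_already_met(model, constraint):
            continue
        kgT_c = model.kgT_expr_sym.subs(constraint)
        if sp.simplify(kgT_c) == 0:
            continue  # constraint degenerates the model
        residual_c = sp.diff(Q_sym.subs(constraint), S_EXT)
        remaining = {s: v for s, v in numeric_map.items()
                     if s not in constraint}
        if _is_zero(residual_c.subs(remaining)):
            report.special_condition = label
            report.verdict = LOCALLY_PERFECT_ONLY
            return report
    return report


# ---------------------------------------------------------------------------
# rank condition

def _log_sensitivity_column(sigmas, var) -> list[sp.Expr]:
    out = []
    for s in sigmas:
        out.append(sp.cancel(var * sp.diff(s, var) / s))
    return out


def _normalize_column(col: sp.Matrix) -> sp.Matrix:
    for entry in col:
        if entry != 0:
            return sp.simplify(col / entry)
    return col


def _parameter_independent(col: sp.Matrix) -> bool:
    params = set(PARAM_SYMBOLS.values())
    return all(not (sp.sympify(e).free_symbols & params) for e in col)


def _generic_rank_equal(I_mat: sp.Matrix, P_col: sp.Matrix,
                        n_samples: int = 30,
                        seed: int = ZERO_TEST_SEED) -> bool:
    """rank(P|I) == rank(I) identically, decided by exact rational sampling.

    Both ranks are rational-function-field ranks; random rational evaluation
    points realize the generic rank with probability one, and exact
    arithmetic keeps the rank computation trustworthy.
    """
    aug = I_mat.row_join(P_col)
    syms = sorted(aug.free_symbols, key=lambda s: s.name)
    if not syms:
        return aug.rank() == I_mat.rank()
    base_rank = I_mat.rank() if not I_mat.free_symbols else None
    rng = np.random.default_rng(seed)
    checked = 0
    for point in _rational_points(syms, n_samples * 2, rng):
        try:
            aug_v = aug.subs(point)
            I_v = I_mat.subs(point) if base_rank is None else None
        except (ZeroDivisionError, ValueError):
            continue
        if any(not v.is_finite for v in aug_v):
            continue
        r_I = base_rank if base_rank is not None else I_v.rank()
        if aug_v.rank() != r_I:
            return False
        checked += 1
        if checked >= n_samples:
            break
    if checked == 0:
        raise RuntimeError("rank sampling found no admissible points")
    return True


def _rank_condition_holds(model: ModelSpec) -> tuple[bool, sp.Matrix, sp.Matrix]:
    sigmas_num = [T * model.u_expr, model.gS_expr, model.aT_expr,
                  model.kgT_expr * T]
    sigmas_sym = [T * model.u_expr_sym, model.gS_expr_sym, model.aT_expr_sym,
                  model.kgT_expr_sym * T]
    P = sp.Matrix(_log_sensitivity_column(sigmas_num, S_EXT))
    M = sp.Matrix(_log_sensitivity_column(sigmas_sym, T))
    # Steady-state flux pairing: uptake balances usage per state variable, so
    # the two columns reduce to the (1,1,0,0)/(0,0,1,1) pattern.
    aS0, aT0 = sp.symbols("alphaS0 alphaT0", positive=True)
    K = sp.Matrix([[aS0, 0], [aS0, 0], [0, aT0], [0, aT0]])
    candidates = [M] + [K[:, j] for j in range(K.cols)]
    I_cols: list[sp.Matrix] = []
    for col in candidates:
        ncol = _normalize_column(col)
        if not _parameter_independent(ncol):
            continue
        trial = sp.Matrix.hstack(*(I_cols + [ncol])) if I_cols else ncol
        if trial.rank() > (sp.Matrix.hstack(*I_cols).rank() if I_cols else 0):
            I_cols.append(ncol)
    I_mat = sp.Matrix.hstack(*I_cols)
    return _generic_rank_equal(I_mat, P), I_mat, P


def check_rank_condition(model: ModelSpec,
                         compute_numeric: bool = True) -> CriterionReport:
    """Structural rank test ``rank(P|I) = rank(I)`` on the four-flux template.

    ``P`` is built with the instance's rational parameter values; ``I`` is
    assembled greedily from the parameter-independent normalized columns of
    ``(M|K)``.  When the instance fails, the same candidate-constraint scan
    as the reduced criterion decides between a parameter-conditional
    (``locally_perfect_only``) and a structural failure.
    """
    if model.kgT_depends_on_T or T in model.aT_expr_sym.free_symbols:
        raise StructuralMismatchError(
            f"{model.name}: downregulation/synthesis nonlinear in T is outside "
            "the four-flux rank template; use numeric_sensitivity instead")
    holds, I_mat, P = _rank_condition_holds(model)
    report = CriterionReport(verdict=NOT_HOMEOSTATIC, method="rank_condition")
    if compute_numeric:
        prof = numeric_sensitivity(model, default_S_ext_grid(model.params))
        report.numeric_max_sensitivity = prof.max_abs
    if holds:
        if _steady_state_exists(model):
            report.verdict = GLOBALLY_PERFECT
            return report
        report.notes.append("rank condition holds but no steady state exists")
    # Residual witness: the determinant of (I|P) when I has corank one.
    if I_mat.cols == 3:
        report.residual_expr = sp.simplify(I_mat.row_join(P).det())
    else:
        report.residual_expr = sp.simplify(P)
    p = model.params
    for constraint, label in _SPECIAL_CANDIDATES:
        if _constraint_already_met(model, constraint):
            continue
        new = p
        if PARAM_SYMBOLS["kgTc"] in constraint:
            new = replace(new, kgTc=0.0)
        if PARAM_SYMBOLS["Ksensor"] in constraint:
            new = replace(new, Ksensor=new.Kext)
        try:
            constrained = model.with_params(new)
        except Exception:
            continue
        if sp.simplify(constrained.kgT_expr) == 0:
            continue
        if _rank_condition_holds(constrained)[0]:
            report.special_condition = label
            report.verdict = LOCALLY_PERFECT_ONLY
            return report
    return report


# ---------------------------------------------------------------------------
# numeric sensitivity

def log_sensitivity_at(model: ModelSpec, S_ext: float,
                       delta: float = 1e-4) -> float:
    """Central-difference ``d log S_int_ss / d log S_ext`` at one point."""
    hi = solve_steady_state(model, S_ext * math.exp(delta)).S_int_ss
    lo = solve_steady_state(model, S_ext * math.exp(-delta)).S_int_ss
    if hi <= 0 or lo <= 0:
        return math.nan
    return (math.log(hi) - math.log(lo)) / (2.0 * delta)


def numeric_sensitivity(model: ModelSpec, S_ext_grid,
                        delta: float = 1e-4) -> SensitivityProfile:
    """Logarithmic sensitivity of the solved steady-state map on a grid.

    Each point uses a multiplicative central difference with half-width
    ``delta`` (in log space); points whose steady state does not exist are
    marked missing rather than dropped.
    """
    grid = np.asarray(S_ext_grid, dtype=float)
    values = np.full(grid.shape, np.nan)
    missing = np.zeros(grid.shape, dtype=bool)
    for i, se in enumerate(grid):
        try:
            values[i] = log_sensitivity_at(model, se, delta=delta)
        except NoSteadyStateError:
            missing[i] = True
    missing |= ~np.isfinite(values)
    return SensitivityProfile(grid=grid, values=values, missing=missing)


# ---------------------------------------------------------------------------
# consensus

def consensus_verdict(model: ModelSpec, grid=None,
                      tol: float = PERFECT_SENSITIVITY_TOL) -> dict:
    """Run every applicable checker and verify they agree.

    Returns a dict with the individual reports, the numeric profile and the
    boolean ``perfect``.  Raises :class:`CriterionDisagreement` when the
    symbolic/structural verdicts contradict each other or the numeric check.
    """
    if grid is None:
        grid = default_S_ext_grid(model.params)
    prof = numeric_sensitivity(model, grid)
    numeric_perfect = prof.max_abs < tol
    out = {"numeric": prof, "perfect": numeric_perfect,
           "reduced": None, "rank": None}
    for key, fn in (("reduced", check_reduced_criterion),
                    ("rank", check_rank_condition)):
        try:
            out[key] = fn(model, compute_numeric=False)
        except StructuralMismatchError:
            continue
        if out[key].perfect != numeric_perfect:
            raise CriterionDisagreement(
                f"{model.name}: {key} verdict {out[key].verdict!r} "
                f"vs numeric max sensitivity {prof.max_abs:.3e}")
    if out["reduced"] is not None and out["rank"] is not None:
        if out["reduced"].verdict != out["rank"].verdict:
            raise CriterionDisagreement(
                f"{model.name}: reduced says {out['reduced'].verdict}, "
                f"rank says {out['rank'].verdict}")
    return out
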