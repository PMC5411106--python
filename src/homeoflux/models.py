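"""Registry of transporter-homeostasis model variants.

Every model is a two-variable dynamical system for the internal nutrient
concentration ``S_int`` and the plasma-membrane transporter concentration
``T`` in an environment with external nutrient ``S_ext``::

    dS_int/dt = T * u(S_ext)            - gammaS(S_int)
    dT/dt     = alphaT(S_int)           - kgammaT(S_ext, S_int, T) * T

where ``u`` is the uptake rate per transporter, ``gammaS`` the nutrient usage
flux, ``alphaT`` the transporter synthesis flux, and ``kgammaT`` the
(per-transporter) downregulation rate.  The registry covers the canonical
regulatory architectures -- no regulation, activity-dependent downregulation,
Hill repression of synthesis by internal nutrient, Hill activation of
downregulation by internal nutrient, the combination, and the two sensor-based
alternatives (external nutrient sensor, internal flux sensor).

All fluxes are held both as :mod:`sympy` expressions (with rate constants as
symbols and with exact rational parameter values substituted) and as fast
evaluable callables.  Concentrations are conventionally expressed in units of
the transporter Michaelis constant ``Kext`` and the reference internal level
``S0 = kcat*aT/(kgS*kgTc)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Callable

import sympy as sp

__all__ = [
    "S_EXT",
    "S_INT",
    "T",
    "PARAM_SYMBOLS",
    "REGISTRY",
    "ALL_VARIANTS",
    "ParameterSet",
    "ModelSpec",
    "ModelValidationError",
    "UnknownModelError",
    "build_model",
    "build_custom_model",
]

# State-variable symbols, shared across the package.  Declared positive so
# that sympy can simplify Hill-type expressions on the physical domain.
S_EXT, S_INT, T = sp.symbols("S_ext S_int T", positive=True)

_PARAM_NAMES = (
    "kcat", "Kext", "kgS", "aT", "kgTc", "kgTa",
    "Ksyn", "Kdeg", "n", "Ksensor", "ksens",
)
PARAM_SYMBOLS = {name: sp.Symbol(name, positive=True) for name in _PARAM_NAMES}


class ModelValidationError(ValueError):
    """A parameter is missing, negative, or non-finite for the requested variant."""


class UnknownModelError(KeyError):
    """The requested name is not in the model registry."""


@dataclass(frozen=True)
class ParameterSet:
    """Nonnegative rate and saturation constants shared by all variants.

    Parameters
    ----------
    kcat : maximal per-transporter uptake rate (1/time).
    Kext : transporter Michaelis constant for the external nutrient
        (concentration).
    kgS : internal-nutrient usage rate constant (1/time).
    aT : basal transporter synthesis flux (concentration/time).
    kgTc : basal downregulation/dilution rate constant (1/time).
    kgTa : maximal activity-dependent downregulation rate constant (1/time).
    Ksyn, Kdeg : half-saturation constants of the Hill feedback on synthesis
        and on downregulation (concentration).  ``None`` resolves to the
        reference internal concentration ``S0 = kcat*aT/(kgS*kgTc)``
        (``kcat*aT/kgS`` when ``kgTc`` is zero), the natural unit for these
        constants.  Note the feedback then only engages near transporter
        saturation; pass a smaller value for feedback that is active across
        the whole operating range.
    n : Hill coefficient of the internal-nutrient feedback (dimensionless,
        finite and >= 0; the perfect-homeostasis-by-synthesis limit
        ``n -> inf`` is a documented limit, never a parameter value).
    Ksensor : external-sensor Michaelis constant (concentration).
    ksens : sensor-mediated downregulation rate constant (1/time).
    """

    kcat: float = 1.0
    Kext: float = 1.0
    kgS: float = 1.0
    aT: float = 1.0
    kgTc: float = 1.0
    kgTa: float = 1.0
    Ksyn: float | None = None
    Kdeg: float | None = None
    n: float = 1.0
    Ksensor: float = 1.0
    ksens: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not math.isfinite(v):
                raise ModelValidationError(f"parameter {f.name!r} must be finite, got {v}")
            if v < 0:
                raise ModelValidationError(f"parameter {f.name!r} must be >= 0, got {v}")

    @property
    def S0(self) -> float:
        """Reference internal concentration: the saturated steady-state S_int
        of the unregulated system (``kcat*aT/(kgS*kgTc)``; the ``kgTc``-free
        analogue when basal degradation is absent)."""
        if self.kgS == 0:
            raise ModelValidationError("S0 undefined for kgS = 0")
        if self.kgTc > 0:
            return self.kcat * self.aT / (self.kgS * self.kgTc)
        return self.kcat * self.aT / self.kgS

    def resolved(self) -> "ParameterSet":
        """Return a copy with ``Ksyn``/``Kdeg`` defaults filled in (= S0).

        When S0 itself is undefined (degenerate ``kgS = 0``) the fields stay
        ``None``, so variants that need them fail validation explicitly.
        """
        if self.Ksyn is not None and self.Kdeg is not None:
            return self
        try:
            default = self.S0
        except ModelValidationError:
            return self
        return replace(
            self,
            Ksyn=self.Ksyn if self.Ksyn is not None else default,
            Kdeg=self.Kdeg if self.Kdeg is not None else default,
        )

    def subs_map(self) -> dict:
        """Exact rational substitution map symbol -> value (resolved).

        Unresolvable saturation constants map to 1; they can only remain
        unresolved for variants whose fluxes never reference them.
        """
        p = self.resolved()
        out = {}
        for name in _PARAM_NAMES:
            v = getattr(p, name)
            out[PARAM_SYMBOLS[name]] = sp.Rational(str(float(1.0 if v is None else v)))
        return out


def _require(params: ParameterSet, names: tuple[str, ...], variant: str) -> None:
    for name in names:
        v = getattr(params, name)
        if v is None:
            raise ModelValidationError(
                f"variant {variant!r} requires parameter {name!r}, got None"
            )


# Symbolic building blocks (parameter symbols, not values).
_p = PARAM_SYMBOLS
_x_ext = S_EXT / (S_EXT + _p["Kext"])          # transporter occupancy
_x_sens = S_EXT / (S_EXT + _p["Ksensor"])      # sensor occupancy
_u_mm = _p["kcat"] * _x_ext                    # Michaelian uptake per transporter
_gS_lin = _p["kgS"] * S_INT                    # first-order usage
_hill_syn = _p["Ksyn"] ** _p["n"] / (_p["Ksyn"] ** _p["n"] + S_INT ** _p["n"])
_hill_deg = S_INT ** _p["n"] / (_p["Kdeg"] ** _p["n"] + S_INT ** _p["n"])

_CORE = ("kcat", "Kext", "kgS", "aT")

# name -> (u, gS, aT, kgT, required params, kgT depends on T)
_VARIANT_TABLE: dict[str, tuple] = {
    "no_regulation": (
        _u_mm, _gS_lin, _p["aT"], _p["kgTc"],
        _CORE + ("kgTc",), False),
    "activity_dependent": (
        _u_mm, _gS_lin, _p["aT"], _p["kgTc"] + _p["kgTa"] * _x_ext,
        _CORE + ("kgTc", "kgTa"), False),
    "synthesis_repression": (
        _u_mm, _gS_lin, _p["aT"] * _hill_syn, _p["kgTc"],
        _CORE + ("kgTc", "Ksyn", "n"), False),
    "downreg_by_Sint": (
        _u_mm, _gS_lin, _p["aT"], _p["kgTc"] + _p["kgTa"] * _hill_deg,
        _CORE + ("kgTc", "kgTa", "Kdeg", "n"), False),
    "combined": (
        _u_mm, _gS_lin, _p["aT"] * _hill_syn,
        _p["kgTc"] + _p["kgTa"] * _x_ext,
        _CORE + ("kgTc", "kgTa", "Ksyn", "n"), False),
    "external_sensor": (
        _u_mm, _gS_lin, _p["aT"], _p["kgTc"] + _p["ksens"] * _x_sens,
        _CORE + ("kgTc", "ksens", "Ksensor"), False),
    # Downregulation flux ksens*u*T**2: an internal flux sensor reads the total
    # flux T*u, and per-transporter downregulation inherits the extra factor T.
    "internal_flux_sensor": (
        _u_mm, _gS_lin, _p["aT"], _p["ksens"] * _u_mm * T,
        _CORE + ("ksens",), True),
    # Interpretation of the "linear external nutrient based downregulation"
    # variant (no saturating sensor); used for qualitative comparisons only.
    "external_linear": (
        _u_mm, _gS_lin, _p["aT"], _p["kgTc"] + _p["ksens"] * S_EXT,
        _CORE + ("kgTc", "ksens"), False),
}

#: The canonical architectures analysed throughout.
REGISTRY: tuple[str, ...] = (
    "no_regulation",
    "activity_dependent",
    "synthesis_repression",
    "downreg_by_Sint",
    "combined",
    "external_sensor",
    "internal_flux_sensor",
)

#: Registry plus the linear-external-downregulation interpretation.
ALL_VARIANTS: tuple[str, ...] = REGISTRY + ("external_linear",)

# Per-variant defaults applied when build_model is called without parameters.
# downreg_by_Sint in its canonical form has no basal degradation channel.
_VARIANT_DEFAULTS: dict[str, dict] = {"downreg_by_Sint": {"kgTc": 0.0}}

_STATE = (S_EXT, S_INT, T)


@dataclass
class ModelSpec:
    """A concrete model: symbolic fluxes plus evaluable right-hand sides.

    ``*_expr`` carry exact rational parameter values; ``*_expr_sym`` keep the
    rate constants symbolic (used by the structural homeostasis checkers).
    All flux callables take ``(S_ext, S_int, T)``.
    """

    name: str
    params: ParameterSet
    u_expr: sp.Expr
    gS_expr: sp.Expr
    aT_expr: sp.Expr
    kgT_expr: sp.Expr
    u_expr_sym: sp.Expr
    gS_expr_sym: sp.Expr
    aT_expr_sym: sp.Expr
    kgT_expr_sym: sp.Expr
    kgT_depends_on_T: bool
    u: Callable = None
    gS: Callable = None
    aT: Callable = None
    kgT: Callable = None
    rhs: Callable = None
    jac: Callable = None

    def __post_init__(self) -> None:
        lam = lambda e: sp.lambdify(_STATE, e, modules="numpy")
        self.u = lam(self.u_expr)
        self.gS = lam(self.gS_expr)
        self.aT = lam(self.aT_expr)
        self.kgT = lam(self.kgT_expr)
        dS = T * self.u_expr - self.gS_expr
        dT = self.aT_expr - self.kgT_expr * T
        self._dS_expr, self._dT_expr = dS, dT
        f_dS, f_dT = lam(dS), lam(dT)
        self.rhs = lambda S_int, Tval, S_ext: (
            float(f_dS(S_ext, S_int, Tval)), float(f_dT(S_ext, S_int, Tval)))
        jac_mat = sp.Matrix([dS, dT]).jacobian([S_INT, T])
        self.jac = sp.lambdify(_STATE, jac_mat, modules="numpy")

    def ode_rhs(self, t: float, y, S_ext: float):
        """Right-hand side in the layout scipy integrators expect."""
        return self.rhs(y[0], y[1], S_ext)

    def with_params(self, params: ParameterSet) -> "ModelSpec":
        """Same architecture, new rate constants."""
        if self.name in _VARIANT_TABLE:
            return build_model(self.name, params)
        return build_custom_model(
            self.u_expr_sym, self.gS_expr_sym, self.aT_expr_sym,
            self.kgT_expr_sym, params, name=self.name)


def build_model(name: str, params: ParameterSet | None = None) -> ModelSpec:
    """Instantiate a registry variant.

    Parameters default to unit rate constants (and, for ``downreg_by_Sint``,
    no basal degradation).  Raises :class:`UnknownModelError` for names
    outside the registry and :class:`ModelValidationError` for missing or
    negative parameters, naming the offending field.
    """
    if name not in _VARIANT_TABLE:
        raise UnknownModelError(
            f"unknown model {name!r}; choose one of {sorted(_VARIANT_TABLE)}")
    if params is None:
        params = ParameterSet(**_VARIANT_DEFAULTS.get(name, {}))
    u_sym, gS_sym, aT_sym, kgT_sym, required, t_dep = _VARIANT_TABLE[name]
    _require(params.resolved(), required, name)
    sub = params.subs_map()
    return ModelSpec(
        name=name,
        params=params.resolved(),
        u_expr=u_sym.subs(sub),
        gS_expr=gS_sym.subs(sub),
        aT_expr=aT_sym.subs(sub),
        kgT_expr=kgT_sym.subs(sub),
        u_expr_sym=u_sym,
        gS_expr_sym=gS_sym,
        aT_expr_sym=aT_sym,
        kgT_expr_sym=kgT_sym,
        kgT_depends_on_T=t_dep,
    )


def build_custom_model(
    u_expr: sp.Expr,
    gS_expr: sp.Expr,
    aT_expr: sp.Expr,
    kgT_expr: sp.Expr,
    params: ParameterSet | None = None,
    name: str = "custom",
) -> ModelSpec:
    """Construct a model from user flux expressions (general uptake form).

    Expressions may use the shared state symbols and any of the named
    parameter symbols; remaining free symbols are rejected.  Nonnegativity of
    the four fluxes is checked by sampling a log-spaced nonnegative state
    grid (a sampled check, not a proof).
    """
    params = params or ParameterSet()
    sub = params.subs_map()
    allowed = set(_STATE) | set(PARAM_SYMBOLS.values())
    for e in (u_expr, gS_expr, aT_expr, kgT_expr):
        extra = sp.sympify(e).free_symbols - allowed
        if extra:
            raise ModelValidationError(f"unknown symbols in custom flux: {extra}")
    spec = ModelSpec(
        name=name,
        params=params.resolved(),
        u_expr=sp.sympify(u_expr).subs(sub),
        gS_expr=sp.sympify(gS_expr).subs(sub),
        aT_expr=sp.sympify(aT_expr).subs(sub),
        kgT_expr=sp.sympify(kgT_expr).subs(sub),
        u_expr_sym=sp.sympify(u_expr),
        gS_expr_sym=sp.sympify(gS_expr),
        aT_expr_sym=sp.sympify(aT_expr),
        kgT_expr_sym=sp.sympify(kgT_expr),
        kgT_depends_on_T=T in sp.sympify(kgT_expr).free_symbols,
    )
    pts = [0.0] + [10.0 ** k for k in range(-3, 3)]
    for se in pts:
        for si in pts:
            for tv in pts[:3]:
                for f, label in ((spec.u, "u"), (spec.gS, "gammaS"),
                                 (spec.aT, "alphaT"), (spec.kgT, "kgammaT")):
                    try:
                        v = float(f(se, si, tv))
                    except ZeroDivisionError:
                        continue
                    if math.isfinite(v) and v < -1e-12:
                        raise ModelValidationError(
                            f"custom flux {label} negative ({v}) at "
                            f"(S_ext={se}, S_int={si}, T={tv})")
    return spec
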