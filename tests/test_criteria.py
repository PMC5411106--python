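import numpy as np
import pytest
import sympy as sp

from homeoflux import ParameterSet, build_custom_model, build_model
from homeoflux.criteria import (GLOBALLY_PERFECT, LOCALLY_PERFECT_ONLY,
                                NOT_HOMEOSTATIC, StructuralMismatchError,
                                check_rank_condition, check_reduced_criterion,
                                consensus_verdict, default_S_ext_grid,
                                log_sensitivity_at, numeric_sensitivity)
from homeoflux.models import S_EXT, S_INT
from tests.conftest import draw_params

CASES = [
    # (variant, params, expected verdict, expected special condition)
    ("activity_dependent", ParameterSet(kgTc=0.0), GLOBALLY_PERFECT, None),
    ("activity_dependent", ParameterSet(), LOCALLY_PERFECT_ONLY, "kgTc = 0"),
    ("no_regulation", ParameterSet(), NOT_HOMEOSTATIC, None),
    ("synthesis_repression", ParameterSet(n=3.0), NOT_HOMEOSTATIC, None),
    ("synthesis_repression", ParameterSet(n=10.0), NOT_HOMEOSTATIC, None),
    ("downreg_by_Sint", ParameterSet(kgTc=0.0, n=2.0), NOT_HOMEOSTATIC, None),
    ("combined", ParameterSet(kgTc=0.0, n=2.0), GLOBALLY_PERFECT, None),
    ("external_sensor", ParameterSet(kgTc=0.0, Ksensor=5.0),
     LOCALLY_PERFECT_ONLY, "Ksensor = Kext"),
    ("external_sensor", ParameterSet(kgTc=0.0, Ksensor=1.0),
     GLOBALLY_PERFECT, None),
]


@pytest.mark.parametrize("name,params,verdict,special", CASES,
                         ids=[f"{c[0]}-{c[2]}" for c in CASES])
class TestSymbolicCheckers:
    def test_reduced_criterion(self, name, params, verdict, special):
        rep = check_reduced_criterion(build_model(name, params),
                                      compute_numeric=False)
        assert rep.verdict == verdict
        if special is not None:
            assert rep.special_condition == special
        if verdict != GLOBALLY_PERFECT:
            assert rep.residual_expr is not None
            assert sp.simplify(rep.residual_expr) != 0

    def test_rank_condition(self, name, params, verdict, special):
        rep = check_rank_condition(build_model(name, params),
                                   compute_numeric=False)
        assert rep.verdict == verdict
        if special is not None:
            assert rep.special_condition == special


class TestStructuralMismatch:
    def test_flux_sensor_outside_reduced_template(self):
        m = build_model("internal_flux_sensor")
        with pytest.raises(StructuralMismatchError):
            check_reduced_criterion(m)
        with pytest.raises(StructuralMismatchError):
            check_rank_condition(m)

    def test_Sint_dependent_uptake_outside_reduced_template(self):
        m = build_custom_model(S_EXT / (S_EXT + 1) / (1 + S_INT), S_INT,
                               sp.Integer(1), sp.Integer(1))
        with pytest.raises(StructuralMismatchError):
            check_reduced_criterion(m)


class TestNumericSensitivity:
    def test_unregulated_log_sensitivity_closed_form(self):
        # S_int proportional to x = S_ext/(S_ext+Kext):
        # dlog S_int/dlog S_ext = Kext/(S_ext+Kext)
        m = build_model("no_regulation", ParameterSet())
        assert log_sensitivity_at(m, 1.0) == pytest.approx(0.5, abs=1e-6)
        assert log_sensitivity_at(m, 100.0) == pytest.approx(1.0 / 101.0,
                                                             abs=1e-6)

    def test_perfect_model_sensitivity_below_threshold(self, perfect_model,
                                                       grid41):
        prof = numeric_sensitivity(perfect_model, grid41)
        assert not prof.missing.any()
        assert prof.max_abs < 1e-6

    def test_flux_sensor_needs_sensor_normalization(self, grid41):
        """Downregulation ~ u*T^2 (unnormalized internal flux sensor) leaves a
        strictly positive sensitivity: S_int_ss ~ sqrt(u(S_ext))."""
        m = build_model("internal_flux_sensor")
        prof = numeric_sensitivity(m, grid41)
        assert np.all(prof.values[~prof.missing] > 1e-3)
        # closed-form check at S_ext = Kext: 0.5 * Kext/(S_ext+Kext) = 0.25
        assert log_sensitivity_at(m, 1.0) == pytest.approx(0.25, abs=1e-6)

    def test_missing_points_marked_not_dropped(self, perfect_model):
        # no steady state at S_ext = 0 when kgTc = 0: marked, not dropped
        prof = numeric_sensitivity(perfect_model, np.array([0.0, 1.0, 10.0]))
        assert prof.values.shape == (3,)
        assert prof.missing[0] and np.isnan(prof.values[0])
        assert not prof.missing[1] and not prof.missing[2]


def test_general_criterion_custom_model_is_perfect(grid41):
    """Any system with kgammaT/alphaT = c * u(S_ext) * func(S_int) adapts
    perfectly, whatever func is."""
    u = S_EXT / (S_EXT + 2)
    func = S_INT ** 2 / (1 + S_INT)
    m = build_custom_model(u, S_INT, sp.Integer(1), 3 * u * func)
    rep = check_reduced_criterion(m, compute_numeric=False)
    assert rep.verdict == GLOBALLY_PERFECT
    prof = numeric_sensitivity(m, grid41)
    assert prof.max_abs < 1e-6


def test_saturated_uptake_is_trivially_perfect(grid41):
    """If u does not depend on S_ext (fully saturated transporter), there is
    no perturbation to reject and every architecture is perfect."""
    m = build_custom_model(sp.Integer(1), S_INT, sp.Integer(1), sp.Integer(1))
    assert check_reduced_criterion(m, compute_numeric=False).perfect
    assert check_rank_condition(m, compute_numeric=False).perfect
    assert numeric_sensitivity(m, grid41).max_abs < 1e-6


def test_tri_oracle_agreement_random_draws():
    """Reduced criterion, rank condition and numeric sensitivity must give
    one verdict per architecture; disagreement raises."""
    rng = np.random.default_rng(42)
    from homeoflux import REGISTRY
    for name in REGISTRY:
        for k in range(4):
            params = draw_params(rng, kgTc_zero=(k == 0 and name in
                                                 ("activity_dependent", "combined")))
            model = build_model(name, params)
            res = consensus_verdict(model)  # raises on disagreement
            if name in ("activity_dependent", "combined") and params.kgTc == 0:
                assert res["perfect"]
            if name in ("no_regulation", "synthesis_repression"):
                assert not res["perfect"]
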