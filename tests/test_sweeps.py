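import numpy as np
import pytest
from click.testing import CliRunner

from homeoflux import (ParameterSet, build_model, iso_robustness_contour,
                       robustness_heatmap, robustness_profile,
                       sensor_mismatch_curve, tradeoff_curve)
from homeoflux.cli import main as cli_main
from homeoflux.metrics import normalized_Sint
from homeoflux.sweeps import ContourRangeError, flatness


class TestHeatmap:
    def test_large_rho_approaches_perfect(self, grid41):
        # 1 - r = (1-x)/(1+rho*x): dominance of activity-dependent
        # downregulation drives r -> 1 at every grid point
        mat = robustness_heatmap([1e6], grid41)
        assert np.all(np.abs(mat.to_numpy() - 1.0) < 1e-3)

    def test_zero_rho_row_is_occupancy(self, grid41):
        mat = robustness_heatmap([0.0], grid41)
        assert mat.to_numpy()[0] == pytest.approx(grid41 / (grid41 + 1.0),
                                                  rel=1e-9)

    def test_monotone_rows_and_columns(self, grid41):
        rhos = np.geomspace(1e-2, 1e4, 13)
        mat = robustness_heatmap(rhos, grid41[::4]).to_numpy()
        assert np.all(np.diff(mat, axis=0) >= -1e-12)  # along rho
        assert np.all(np.diff(mat, axis=1) >= -1e-12)  # along S_ext

    def test_single_cell_consistent_with_profile(self):
        mat = robustness_heatmap([2.0], [1.0])
        m = build_model("activity_dependent", ParameterSet(kgTa=2.0))
        prof = robustness_profile(m, np.array([1.0]))
        assert mat.iloc[0, 0] == pytest.approx(prof.r_values[0], rel=1e-12)


class TestSensorMismatch:
    def test_flat_exactly_at_matched_affinity(self, grid41):
        df = sensor_mismatch_curve([1.0], grid41)
        assert df["flatness"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_mismatch_degrades_symmetrically_in_log_ratio(self, grid41):
        df = sensor_mismatch_curve([0.1, 10.0], grid41)
        f_lo = df[df.Ksensor_over_Kext == 0.1]["flatness"].iloc[0]
        f_hi = df[df.Ksensor_over_Kext == 10.0]["flatness"].iloc[0]
        assert f_lo > 1.5 and f_hi > 1.5
        assert f_lo == pytest.approx(f_hi, rel=0.15)

    def test_single_point_profile_is_flat_by_definition(self):
        df = sensor_mismatch_curve([3.0], [1.0])
        assert df["flatness"].iloc[0] == 1.0


class TestContours:
    def test_pure_activity_inversion(self):
        # invert r = x(1+rho)/(1+rho*x) at x = 1/2: rho = (r-x)/(x(1-r)) = 3
        sol = iso_robustness_contour("activity_dependent", 0.8, 1.0)
        assert sol.pairs[0][1] == pytest.approx(3.0, abs=1e-6)
        assert sol.r_achieved[0] == pytest.approx(0.8, abs=1e-6)

    def test_target_at_minimal_robustness_needs_no_downregulation(self):
        sol = iso_robustness_contour("activity_dependent", 0.5, 1.0)
        assert sol.pairs[0][1] == 0.0

    def test_below_minimal_robustness_is_a_range_error(self):
        with pytest.raises(ContourRangeError, match="minimal robustness"):
            iso_robustness_contour("activity_dependent", 0.3, 1.0)

    def test_unit_target_unreachable(self):
        with pytest.raises(ContourRangeError):
            iso_robustness_contour("activity_dependent", 1.0, 1.0)

    def test_combined_needs_less_downregulation_than_pure(self):
        pure = iso_robustness_contour("activity_dependent", 0.95, 1.0)
        assert pure.pairs[0][1] == pytest.approx(18.0, abs=1e-6)
        comb = iso_robustness_contour("combined", 0.95, 1.0, n_grid=[1.0])
        assert comb.pairs[0][1] < pure.pairs[0][1]

    def test_every_solution_reevaluates_to_target(self):
        sol = iso_robustness_contour("combined", 0.8, 1.0,
                                     n_grid=[0.0, 1.0, 2.0, 4.0])
        for r in sol.r_achieved:
            assert abs(r - 0.8) < 1e-6

    def test_synthesis_repression_solves_for_hill_coefficient(self):
        # feedback half-point well below S0 so repression shapes the whole
        # operating range; deep-repression estimate r ~ x^(1/(n+1)) puts the
        # 0.8 contour near n ~ 3
        sol = iso_robustness_contour("synthesis_repression", 0.8, 1.0,
                                     params=ParameterSet(Ksyn=0.2))
        n, rho = sol.pairs[0]
        assert rho == 0.0 and 1.0 < n < 10.0
        assert sol.r_achieved[0] == pytest.approx(0.8, abs=1e-6)

    def test_synthesis_repression_with_weak_feedback_hits_range_error(self):
        # with Ksyn = S0 the repression engages only at saturation and no
        # finite n reaches r = 0.8
        with pytest.raises(ContourRangeError):
            iso_robustness_contour("synthesis_repression", 0.8, 1.0)


class TestTradeoff:
    def test_closed_form_endpoints(self):
        curve = tradeoff_curve("activity_dependent", 0.0, [0.0, 3.0], 1.0)
        t = curve.table
        assert t.loc[0, ["r", "e"]].to_numpy() == pytest.approx([0.5, 0.5],
                                                                rel=1e-9)
        assert t.loc[1, ["r", "e"]].to_numpy() == pytest.approx([0.8, 0.2],
                                                                rel=1e-9)

    def test_monotone_along_rho_and_extremal_endpoint(self):
        rhos = np.concatenate([[0.0], np.geomspace(0.01, 100.0, 15)])
        t = tradeoff_curve("combined", 2.0, rhos, 1.0).table
        assert np.all(np.diff(t["r"]) >= -1e-12)
        assert np.all(np.diff(t["e"]) <= 1e-12)
        assert t["r"].iloc[0] == t["r"].min()
        assert t["e"].iloc[0] == t["e"].max()


def test_flat_response_classification(grid41):
    """Among the canonical architectures, exactly activity-dependent and
    combined downregulation (each without basal degradation) keep S_int
    perfectly flat across external concentrations."""
    flat_expected = {
        "activity_dependent": True, "combined": True,
        "no_regulation": False, "synthesis_repression": False,
        "external_linear": False,
    }
    for name, expect_flat in flat_expected.items():
        params = ParameterSet(kgTc=0.0, n=2.0) if expect_flat else ParameterSet(n=2.0)
        m = build_model(name, params)
        vals = np.array([v for v in normalized_Sint(m, grid41)])
        is_flat = abs(flatness(vals) - 1.0) < 1e-6
        assert is_flat == expect_flat, name


class TestCli:
    def _write(self, tmp_path, text, name="cfg.yaml"):
        p = tmp_path / name
        p.write_text(text)
        return str(p)

    def test_criterion_subcommand_reports_perfect(self, tmp_path):
        cfg = self._write(tmp_path,
                          "model: activity_dependent\nkgTc: 0.0\nS_ext_points: 7\n")
        res = CliRunner().invoke(cli_main, ["criterion", cfg])
        assert res.exit_code == 0, res.output
        assert "globally_perfect" in res.output

    def test_robustness_table_matches_occupancy(self, tmp_path):
        cfg = self._write(tmp_path, "model: no_regulation\nS_ext_points: 5\n")
        out = tmp_path / "r.tsv"
        res = CliRunner().invoke(cli_main, ["robustness", cfg, "-o", str(out)])
        assert res.exit_code == 0, res.output
        import pandas as pd
        df = pd.read_csv(out, sep="\t", comment="#")
        assert df["r"].to_numpy() == pytest.approx(
            df["S_ext"] / (df["S_ext"] + 1.0), rel=1e-9)
        # config echoed bit-exactly in the header
        header = out.read_text()
        assert "# model: no_regulation" in header

    def test_contour_subcommand(self, tmp_path):
        cfg = self._write(tmp_path,
                          "architecture: activity_dependent\nr_target: 0.8\n")
        res = CliRunner().invoke(cli_main, ["contour", cfg])
        assert res.exit_code == 0, res.output
        assert "3.000" in res.output

    def test_unknown_subcommand_usage_error(self):
        res = CliRunner().invoke(cli_main, ["frobnicate"])
        assert res.exit_code == 2
        assert "Usage" in res.output or "No such command" in res.output

    def test_malformed_config_nonzero_exit(self, tmp_path):
        cfg = self._write(tmp_path, "model: [unclosed\n")
        res = CliRunner().invoke(cli_main, ["steady", cfg])
        assert res.exit_code != 0
        assert "YAML" in res.output or "yaml" in res.output
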