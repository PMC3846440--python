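import numpy as np
import pytest

from sbmlfuse.mathexpr import Apply, Num, Sym
from sbmlfuse.model import Parameter
from sbmlfuse.modelgen import group_model, parse_scheme, scheme_to_model
from sbmlfuse.simulator import (
    SimulationError,
    SimulationSettings,
    UnsupportedModelError,
    build_ode_system,
    load_experimental_csv,
    overlay,
    simulate,
    simulate_reference,
)

from conftest import bare_model


class TestSettings:
    def test_defaults_mirror_engine(self):
        s = SimulationSettings()
        assert s.abs_tol == 1e-16 and s.rel_tol == 1e-6 and s.n_points == 100

    def test_bad_time_window(self):
        with pytest.raises(SimulationError):
            SimulationSettings(t_start=5, t_end=1).validate()

    def test_nonpositive_initial_override(self):
        with pytest.raises(SimulationError, match="positive"):
            SimulationSettings(initial_overrides={"S1": 0.0}).validate()

    def test_from_dict(self):
        s = SimulationSettings.from_dict(
            {"tEnd": 2.5, "nPoints": 10, "parameterOverrides": {"k1": "0.5"}}
        )
        assert s.t_end == 2.5 and s.parameter_overrides == {"k1": 0.5}


class TestOdeSystem:
    def test_no_reactions_zero_derivative(self):
        m = bare_model("m", ["S1"])
        system = build_ode_system(m)
        assert np.allclose(system(0.0, system.y0), 0.0)

    def test_mass_action_derivative(self, decay_model):
        # S1 -> S2, k=1, size 1: d[S1]/dt = -[S1]
        system = build_ode_system(decay_model)
        dy = system(0.0, np.array([2.0, 0.0]))
        assert dy[0] == pytest.approx(-2.0)
        assert dy[1] == pytest.approx(2.0)

    def test_boundary_species_zero_derivative_but_drives_rate(self):
        m = scheme_to_model(parse_scheme("X0 -> T, T -> X1"), "b", {"k1": 1.0, "k2": 0.5})
        system = build_ode_system(m)
        y = system.y0.copy()
        dy = system(0.0, y)
        idx = {sid: i for i, sid in enumerate(system.species_ids)}
        assert dy[idx["X0"]] == 0.0 and dy[idx["X1"]] == 0.0
        assert dy[idx["T"]] == pytest.approx(1.0 * 1.0 - 0.5 * 1.0)

    def test_missing_kinetic_law_rejected(self, decay_model):
        decay_model.reactions[0].kinetic_math = None
        with pytest.raises(SimulationError, match="reaction1"):
            build_ode_system(decay_model)

    def test_unresolved_identifier_rejected(self, decay_model):
        decay_model.reactions[0].kinetic_math = Sym("mystery")
        with pytest.raises(SimulationError, match="mystery"):
            build_ode_system(decay_model)

    def test_local_parameter_shadows_global(self, decay_model):
        decay_model.parameters[0].value = 99.0
        decay_model.reactions[0].local_parameters.append(Parameter(id="k1", value=1.0))
        system = build_ode_system(decay_model)
        assert system(0.0, np.array([1.0, 0.0]))[0] == pytest.approx(-1.0)

    def test_compartment_size_divides(self):
        m = scheme_to_model(parse_scheme("S1 -> S2"), "m", {"k1": 1.0})
        m.compartments[0].size = 2.0
        system = build_ode_system(m)
        # v = k*size*[S1] (substance/time); d[S1]/dt = -v/size = -[S1]
        assert system(0.0, np.array([1.0, 0.0]))[0] == pytest.approx(-1.0)

    def test_event_rejected(self):
        import xml.etree.ElementTree as ET

        from sbmlfuse.model import OpaqueElement

        m = scheme_to_model(parse_scheme("S1 -> S2"), "m", {"k1": 1.0})
        m.other_elements.append(
            OpaqueElement("listOfEvents", ET.Element("{ns}event", {"id": "e1"}))
        )
        with pytest.raises(UnsupportedModelError, match="event"):
            build_ode_system(m)


class TestSimulate:
    def test_decay_matches_closed_form(self, decay_model):
        settings = SimulationSettings(t_start=0.0, t_end=5.0, n_points=100)
        result = simulate(decay_model, settings)
        expected = np.exp(-result.time_grid)
        tol = max(1e-4, 100 * settings.rel_tol)
        assert np.max(np.abs(result.species_series["S1"] - expected)) < tol

    def test_enzyme_conservation(self, enzyme_model):
        result = simulate(enzyme_model, SimulationSettings(t_end=10.0))
        total_e = result.species_series["E"] + result.species_series["ES"]
        total_s = (
            result.species_series["S"]
            + result.species_series["ES"]
            + result.species_series["P"]
        )
        assert np.ptp(total_e) < 1e-6
        assert np.ptp(total_s) < 1e-6

    def test_zero_rate_override_freezes_species(self, decay_model):
        settings = SimulationSettings(parameter_overrides={"k1": 0.0}, t_end=5.0)
        result = simulate(decay_model, settings)
        assert np.ptp(result.species_series["S1"]) == 0.0

    def test_initial_override(self, decay_model):
        settings = SimulationSettings(initial_overrides={"S1": 2.0}, t_end=1.0)
        result = simulate(decay_model, settings)
        assert result.species_series["S1"][0] == 2.0

    def test_grid_contract(self, decay_model):
        settings = SimulationSettings(t_start=1.0, t_end=3.0, n_points=7)
        result = simulate(decay_model, settings)
        assert len(result.time_grid) == 7
        assert result.time_grid[0] == 1.0 and result.time_grid[-1] == 3.0
        assert all(len(s) == 7 for s in result.species_series.values())

    def test_flux_series(self, decay_model):
        result = simulate(decay_model, SimulationSettings(t_end=5.0))
        flux = result.flux_series["reaction1"]
        # v = k1*[S1] with k1 = 1
        assert np.allclose(flux, result.species_series["S1"], atol=1e-9)

    def test_selection(self, decay_model):
        settings = SimulationSettings(selected_species={"S2"}, selected_fluxes=set())
        result = simulate(decay_model, settings)
        assert list(result.species_series) == ["S2"]
        assert result.flux_series == {}


class TestReferenceOracle:
    def test_adaptive_agrees_with_rk4(self, enzyme_model):
        settings = SimulationSettings(t_end=10.0, n_points=50)
        adaptive = simulate(enzyme_model, settings)
        reference = simulate_reference(enzyme_model, settings)
        tol = max(1e-4, 100 * settings.rel_tol)
        for sid in adaptive.species_series:
            scale = np.maximum(np.abs(reference.species_series[sid]), 1.0)
            err = np.abs(adaptive.species_series[sid] - reference.species_series[sid]) / scale
            assert np.max(err) < tol

    @pytest.mark.parametrize("group", [1, 7, 12, 24, 31, 38])
    def test_oracle_agreement_sample_groups(self, group):
        m = group_model(group, seed=group)
        settings = SimulationSettings(t_end=1.0, n_points=30)
        adaptive = simulate(m, settings)
        reference = simulate_reference(m, settings)
        tol = max(1e-4, 100 * settings.rel_tol)
        for sid in adaptive.species_series:
            scale = np.maximum(np.abs(reference.species_series[sid]), 1.0)
            assert np.max(np.abs(adaptive.species_series[sid] - reference.species_series[sid]) / scale) < tol

    def test_tolerance_monotonicity(self, enzyme_model):
        """Tightening relTol by 10x never increases error vs the oracle."""
        reference = simulate_reference(enzyme_model, SimulationSettings(t_end=10.0, n_points=50))

        def error(rel_tol):
            result = simulate(
                enzyme_model,
                SimulationSettings(t_end=10.0, n_points=50, rel_tol=rel_tol, abs_tol=1e-12),
            )
            return max(
                np.max(np.abs(result.species_series[s] - reference.species_series[s]))
                for s in result.species_series
            )

        errs = [error(rt) for rt in (1e-3, 1e-4, 1e-5)]
        assert errs[1] <= errs[0] + 1e-12
        assert errs[2] <= errs[1] + 1e-12

    def test_mass_conservation_closed_network(self):
        # S1+S2 -> S3+S4, S3+S4 -> S1+S2 conserves total S-moiety count
        m = group_model(7, seed=3)
        result = simulate(m, SimulationSettings(t_end=5.0))
        total = sum(result.species_series[s] for s in ("S1", "S2", "S3", "S4"))
        assert np.ptp(total) < 1e-6


class TestExperimentalData:
    def test_basic_csv(self):
        series = load_experimental_csv("t,S1\n0,1\n1,0.5\n")
        assert list(series.time) == [0.0, 1.0]
        assert list(series.columns) == ["S1"]
        assert list(series.columns["S1"]) == [1.0, 0.5]

    def test_headerless_positional_labels(self):
        series = load_experimental_csv("0,1\n1,0.5\n")
        assert list(series.columns) == ["col1"]

    def test_rows_sorted_by_time(self):
        series = load_experimental_csv("t,S1\n2,0.2\n0,1\n1,0.5\n")
        assert list(series.time) == [0.0, 1.0, 2.0]
        assert list(series.columns["S1"]) == [1.0, 0.5, 0.2]

    def test_ragged_row_errors_with_line(self):
        with pytest.raises(ValueError, match="line 3"):
            load_experimental_csv("t,S1\n0,1\n1\n")

    def test_non_numeric_cell(self):
        with pytest.raises(ValueError, match="non-numeric"):
            load_experimental_csv("t,S1\n0,abc\n")


class TestOverlay:
    def test_self_consistency_rms(self, decay_model):
        settings = SimulationSettings(t_end=5.0, n_points=100)
        result = simulate(decay_model, settings)
        rows = ["t,S1"] + [
            f"{t},{v}" for t, v in zip(result.time_grid[::10], result.species_series["S1"][::10])
        ]
        aligned = overlay(result, load_experimental_csv("\n".join(rows)))
        assert aligned.rms["S1"] < 1e-6

    def test_empty_experimental(self, decay_model):
        result = simulate(decay_model, SimulationSettings(t_end=1.0, n_points=10))
        aligned = overlay(result, load_experimental_csv(""))
        assert len(aligned.table) == 10
        assert aligned.rms == {} and aligned.unmatched == []

    def test_unmatched_label_flagged(self, decay_model):
        result = simulate(decay_model, SimulationSettings(t_end=1.0, n_points=10))
        aligned = overlay(result, load_experimental_csv("t,ghost\n0,1\n1,2\n"))
        assert aligned.unmatched == ["ghost"]
        assert "exp:ghost" in aligned.table.columns


def test_assignment_rule_applied():
    import xml.etree.ElementTree as ET

    from sbmlfuse.mathexpr import MATHML_NS
    from sbmlfuse.model import OpaqueElement

    m = scheme_to_model(parse_scheme("S1 -> S2"), "m", {"k1": 1.0})
    m.parameters.append(Parameter(id="kdyn"))
    rule = ET.fromstring(
        f'<assignmentRule variable="kdyn">'
        f'<math xmlns="{MATHML_NS}"><cn>3</cn></math></assignmentRule>'
    )
    m.other_elements.append(OpaqueElement("listOfRules", rule))
    m.reactions[0].kinetic_math = Apply("times", (Sym("kdyn"), Sym("S1")))
    system = build_ode_system(m)
    assert system(0.0, np.array([1.0, 0.0]))[0] == pytest.approx(-3.0)
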