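"""Binding-network construction, ODEs, steady states and cycle checks."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rimsys.models import ConfigurationError, make_model
from rimsys.network import (
    BindingReaction,
    NetworkError,
    ReactionNetwork,
    Species,
    build_odes,
    check_thermodynamic_consistency,
    equilibrium_concentrations,
    pairwise_bound_fraction,
    solve_steady_state,
)

from conftest import square_network


class TestPairwiseBoundFraction:
    @pytest.mark.parametrize(
        "rt, lt, kd, expected",
        [
            # the cdG/RimK assay condition: rounds to 96% occupancy
            (2.5, 25.0, 1.0, 0.9576),
            (1.0, 1.0, 1.0, (3.0 - math.sqrt(5.0)) / 2.0),
            (1.0, 0.0, 1.0, 0.0),
            (0.0, 25.0, 1.0, 0.0),
        ],
    )
    def test_exact_quadratic(self, rt, lt, kd, expected):
        assert pairwise_bound_fraction(rt, lt, kd) == pytest.approx(
            expected, abs=1e-4
        )

    def test_zero_kd_rejected(self):
        with pytest.raises(ValueError):
            pairwise_bound_fraction(1.0, 1.0, 0.0)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            pairwise_bound_fraction(-1.0, 1.0, 1.0)

    def test_monotone_in_ligand_and_kd(self):
        ligands = np.linspace(0.0, 50.0, 30)
        fracs = [pairwise_bound_fraction(2.5, lt, 1.0) for lt in ligands]
        assert np.all(np.diff(fracs) >= 0)
        kds = np.linspace(0.1, 50.0, 30)
        fracs = [pairwise_bound_fraction(2.5, 25.0, kd) for kd in kds]
        assert np.all(np.diff(fracs) <= 0)


class TestBuildOdes:
    def test_no_reactions_derivative_is_zero(self):
        net = ReactionNetwork([Species("A", 1.0), Species("B", 2.0)])
        rhs = build_odes(net)
        assert np.all(rhs(0.0, net.initial_concentrations()) == 0.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(NetworkError):
            ReactionNetwork(
                [Species("A", 1.0), Species("AB")],
                [BindingReaction("A", "B", "AB", 1.0)],
            )

    def test_unreachable_complex_rejected(self):
        # C and D are each only formed from the other: neither is reachable
        with pytest.raises(NetworkError, match="not reachable"):
            ReactionNetwork(
                [Species("X", 1.0), Species("C"), Species("D")],
                [
                    BindingReaction("X", "C", "D", 1.0),
                    BindingReaction("X", "D", "C", 1.0),
                ],
            )

    def test_integration_matches_quadratic_closed_form(
        self, one_reaction_network
    ):
        net = one_reaction_network
        rhs = build_odes(net)
        sol = solve_ivp(
            rhs,
            (0.0, 0.05),
            net.initial_concentrations(),
            method="DOP853",
            rtol=1e-10,
            atol=1e-12,
        )
        bound = sol.y[net.index["RL"], -1]
        expected = 2.5 * pairwise_bound_fraction(2.5, 25.0, 1.0)
        assert bound == pytest.approx(expected, rel=1e-6)

    def test_moiety_totals_constant_along_integration(self, one_reaction_network):
        net = one_reaction_network
        rhs = build_odes(net)
        sol = solve_ivp(
            rhs, (0.0, 0.01), net.initial_concentrations(), method="DOP853",
            rtol=1e-8, atol=1e-10,
        )
        t0 = net.moiety_totals()
        for k in range(sol.y.shape[1]):
            tk = net.moiety_totals(sol.y[:, k])
            for m in t0:
                assert tk[m] == pytest.approx(t0[m], rel=1e-9)

    def test_conservation_drift_over_long_horizon(self):
        # slow binding constants so that 1e6 s is integrable explicitly
        rng = np.random.default_rng(42)
        for _ in range(5):
            kds = 10.0 ** rng.uniform(-1, 1, size=2)
            conc = {k: float(10.0 ** rng.uniform(-1, 1)) for k in "KAG"}
            net = square_network(kds[0], kds[1], conc=conc, kf=1e3)
            rhs = build_odes(net)
            sol = solve_ivp(
                rhs, (0.0, 1e6), net.initial_concentrations(),
                method="DOP853", rtol=1e-10, atol=1e-12,
            )
            t0 = net.moiety_totals()
            tend = net.moiety_totals(sol.y[:, -1])
            for m in t0:
                assert abs(tend[m] - t0[m]) / t0[m] < 1e-8


class TestThermodynamicConsistency:
    def test_cycle_constrained_square_passes(self):
        report = check_thermodynamic_consistency(square_network(0.2, 1.0))
        assert len(report.cycles) == 1
        assert report.passed

    def test_perturbed_cycle_reports_ratio_two(self):
        net = square_network(1.0, 1.0, kd_g2=2.0, kd_a2=1.0)
        report = check_thermodynamic_consistency(net)
        assert not report.passed
        assert report.cycles[0].ratio == pytest.approx(2.0, rel=1e-12)

    def test_acyclic_network_empty_report(self, one_reaction_network):
        report = check_thermodynamic_consistency(one_reaction_network)
        assert report.cycles == ()
        assert report.passed


class TestSteadyState:
    def test_single_reaction_equilibrium(self, one_reaction_network):
        ss = solve_steady_state(one_reaction_network)
        # smaller root of x^2 - 28.5 x + 62.5 = 0
        assert ss["RL"] == pytest.approx(2.3941, abs=1e-4)
        assert ss["R"] + ss["RL"] == pytest.approx(2.5, rel=1e-9)
        assert ss["L"] + ss["RL"] == pytest.approx(25.0, rel=1e-9)

    def test_zero_ligand_leaves_receptor_free(self):
        net = ReactionNetwork(
            [Species("R", 2.5), Species("L", 0.0), Species("RL")],
            [BindingReaction("R", "L", "RL", 1.0)],
        )
        ss = solve_steady_state(net)
        assert ss["RL"] == pytest.approx(0.0, abs=1e-12)
        assert ss["R"] == pytest.approx(2.5, rel=1e-12)

    def test_four_state_rimk_total_conserved(self):
        net, _ = make_model("four_state", concentrations={"cdG": 25.0})
        ss = solve_steady_state(net)
        total = (
            ss["RimK"] + ss["RimK.cdG"] + ss["RimK.RimA"] + ss["RimK.RimA.cdG"]
        )
        assert total == pytest.approx(1.0, rel=1e-9)
        assert all(v >= 0 for v in ss.values())

    def test_ode_route_agrees_with_algebraic_equilibrium(self):
        net, _ = make_model(
            "four_state", concentrations={"cdG": 25.0}, kd={"rima": 0.2}
        )
        ss = solve_steady_state(net)
        eq = equilibrium_concentrations(net)
        for name in net.names:
            assert eq[name] == pytest.approx(ss[name], rel=1e-6, abs=1e-12)

    def test_agrees_with_quadratic_over_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            rt = float(10.0 ** rng.uniform(-1, 1.5))
            lt = float(10.0 ** rng.uniform(-1, 1.5))
            kd = float(10.0 ** rng.uniform(-2, 2))
            net = ReactionNetwork(
                [Species("R", rt), Species("L", lt), Species("RL")],
                [BindingReaction("R", "L", "RL", kd)],
            )
            ss = solve_steady_state(net)
            expected = rt * pairwise_bound_fraction(rt, lt, kd)
            assert ss["RL"] == pytest.approx(expected, rel=1e-6, abs=1e-12)


class TestMakeModel:
    def test_two_state_has_two_activity_states(self):
        net, roster = make_model("two_state")
        assert roster.labels == ("basal", "active")
        assert len(roster.members["active"]) == 3
        assert check_thermodynamic_consistency(net).passed

    def test_four_state_has_four_states_and_closed_cycle(self):
        net, roster = make_model("four_state")
        assert len(roster.labels) == 4
        assert check_thermodynamic_consistency(net).passed
        kd = {r.complex: r.kd for r in net.reactions}
        assert kd["RimK.cdG"] == 1.0  # measured cdG affinity

    def test_rimb_extended_adds_rimb_state(self):
        net, roster = make_model("rimb_extended")
        assert "rimb" in roster.labels
        assert "RimK.RimB" in net.names

    def test_trigger_without_rimb_reduces_to_four_state(self):
        net4, _ = make_model("four_state", concentrations={"cdG": 25.0})
        nett, _ = make_model(
            "trigger", concentrations={"cdG": 25.0, "RimB": 0.0}
        )
        ss4 = solve_steady_state(net4)
        sst = solve_steady_state(nett)
        for name in ss4:
            assert sst[name] == pytest.approx(ss4[name], rel=1e-9, abs=1e-12)

    def test_trigger_sequesters_rima_at_high_cdg(self):
        net4, _ = make_model("four_state", concentrations={"cdG": 25.0})
        nett, _ = make_model("trigger", concentrations={"cdG": 25.0})
        assert (
            solve_steady_state(nett)["RimK.RimA.cdG"]
            < solve_steady_state(net4)["RimK.RimA.cdG"]
        )

    def test_trigger_ternary_arrangement_is_cycle_consistent(self):
        net, roster = make_model("trigger", arrangement="ternary")
        assert check_thermodynamic_consistency(net).passed
        assert "RimK.RimA.cdG_A" in roster.members["apo"]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kd": {"rimb": 2.0}},  # no RimB state in four_state
            {"concentrations": {"RimB": 1.0}},
            {"arrangement": "nonsense"},
        ],
    )
    def test_invalid_overrides_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            make_model("four_state", **kwargs)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            make_model("five_state")


class TestExternalInterfaces:
    def test_yaml_round_trip_and_tsv_report(self, tmp_path):
        from rimsys.network import load_network, write_steady_state_tsv

        cfg = tmp_path / "net.yaml"
        cfg.write_text(
            "species:\n"
            "  - {name: R, conc_uM: 2.5}\n"
            "  - {name: L, conc_uM: 25.0}\n"
            "  - {name: RL, conc_uM: 0.0}\n"
            "reactions:\n"
            "  - {a: R, b: L, complex: RL, Kd_uM: 1.0}\n"
        )
        net = load_network(str(cfg))
        assert net.names == ("R", "L", "RL")
        assert net.reactions[0].kf == 1e9  # diffusion-limited default
        ss = solve_steady_state(net)
        out = tmp_path / "ss.tsv"
        write_steady_state_tsv(ss, str(out))
        lines = out.read_text().splitlines()
        assert lines[0] == "species\tconcentration_uM"
        assert lines[3].startswith("RL\t2.394094")
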