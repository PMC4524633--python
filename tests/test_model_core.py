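"""Network structure, GMA kinetics, simulation and steady-state solving."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ceraflux as cf
from ceraflux.model_core import EXPECTED_CLASS_COUNTS

from conftest import rhs_bruteforce


class TestTopology:
    def test_default_network_dimensions(self, model):
        assert model.n_fluxes == 53
        assert model.n_pools == 15
        assert model.S.shape == (15, 53)

    @pytest.mark.parametrize("enzyme_class,count",
                             sorted(EXPECTED_CLASS_COUNTS.items()))
    def test_enzyme_class_counts(self, model, enzyme_class, count):
        assert len(model.class_members(enzyme_class)) == count

    def test_fig_groupings(self, model):
        assert model.class_members("ceramide_synthase") == \
            [1, 6, 11, 16, 21, 26, 30, 34, 38, 42]
        assert model.class_members("dihydroceramidase") == [3, 8, 13, 18, 23]
        assert model.class_members("DHC_hydroxylase") == [4, 9, 14, 19, 24]

    def test_pool_block_layout(self, model):
        roles = [p.role for p in model.pools]
        assert roles == ["DHC"] * 5 + ["PHC"] * 5 + ["FattyAcylCoA"] * 5
        for block in (model.pools[:5], model.pools[5:10], model.pools[10:]):
            assert tuple(p.chain for p in block) == cf.CHAIN_CLASSES

    def test_internal_columns_mass_balanced(self, model):
        for j, fx in enumerate(model.fluxes):
            if not fx.is_boundary:
                assert model.S[:, j].sum() == 0

    def test_out_of_range_pool_is_named(self):
        cfg = cf.default_topology()
        cfg["fluxes"][4]["consumes"] = [99]
        with pytest.raises(cf.TopologyError, match="V5.*99"):
            cf.build_ceramide_network(cfg)

    def test_duplicate_flux_id_rejected(self):
        cfg = cf.default_topology()
        cfg["fluxes"][1]["id"] = 1
        with pytest.raises(cf.TopologyError, match="duplicate flux id V1"):
            cf.build_ceramide_network(cfg)

    def test_topology_yaml_roundtrip(self, tmp_path, model):
        path = tmp_path / "topo.yaml"
        cf.save_topology(cf.default_topology(), path)
        m2 = cf.build_ceramide_network(cf.load_topology(path))
        assert np.array_equal(m2.S, model.S)
        assert m2.groups == model.groups


class TestFluxEvaluation:
    def test_zero_activities_zero_rates(self, model, baseline):
        rates = cf.evaluate_fluxes(model, baseline, np.zeros(53), 0.0)
        assert np.all(rates == 0)

    def test_first_order_in_substrate(self, model, baseline):
        """Doubling a ceramidase flux's single substrate doubles its rate."""
        a = np.ones(53)
        r1 = cf.evaluate_fluxes(model, baseline, a, 0.0)
        x2 = baseline.copy()
        x2[0] *= 2  # pool 1 = C14/C16 DHC, substrate of V3 (dihydroceramidase)
        r2 = cf.evaluate_fluxes(model, x2, a, 0.0)
        assert r2[2] == pytest.approx(2 * r1[2])

    def test_synthase_rate_hand_computed(self, model, baseline):
        """V1 = activity * DHS driver * C14/C16 acyl-CoA pool (pool 11)."""
        a = np.zeros(53)
        a[0] = 0.7
        dhs = model.boundary_drivers["DHS"](0.0)
        expected = 0.7 * dhs * baseline[10]
        rates = cf.evaluate_fluxes(model, baseline, a, 0.0)
        assert rates[0] == pytest.approx(expected, rel=1e-12)
        assert np.all(rates[1:] == 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_homogeneous_in_activities(self, model, baseline, c):
        a = np.linspace(0.1, 2.0, 53)
        r1 = cf.evaluate_fluxes(model, baseline, a, 0.0)
        rc = cf.evaluate_fluxes(model, baseline, c * a, 0.0)
        np.testing.assert_allclose(rc, c * r1, rtol=1e-12)

    def test_negative_state_rejected(self, model):
        x = np.ones(15)
        x[3] = -0.1
        with pytest.raises(ValueError, match="negative state"):
            cf.evaluate_fluxes(model, x, np.ones(53), 0.0)


class TestRhs:
    def test_zero_activities_zero_derivative(self, model, baseline):
        assert np.all(cf.rhs(model, baseline, np.zeros(53), 0.0) == 0)

    def test_hydroxylase_only_transfers_dhc_to_phc(self, model, baseline):
        a = np.zeros(53)
        for fid in model.class_members("DHC_hydroxylase"):
            a[fid - 1] = 1.0
        dx = cf.rhs(model, baseline, a, 0.0)
        np.testing.assert_allclose(dx[:5], -dx[5:10])
        assert np.all(dx[10:] == 0)

    def test_matches_bruteforce_assembly(self, model):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.uniform(0.1, 10, 15)
            a = rng.uniform(0, 3, 53)
            np.testing.assert_allclose(
                cf.rhs(model, x, a, 0.0), rhs_bruteforce(model, x, a), rtol=1e-12)


class TestSimulate:
    def test_steady_state_stays_constant(self, model, baseline,
                                         baseline_activities):
        traj = cf.simulate(model, lambda t: baseline_activities, baseline,
                           np.arange(0.0, 31.0))
        np.testing.assert_allclose(traj, np.tile(baseline, (31, 1)),
                                   rtol=1e-6)

    def test_two_pool_closed_form(self):
        """in -> A -> B -> out with constant coefficients has the classic
        linear-ODE solution; trajectory must match it."""
        cfg = dict(
            pools=[dict(id=1, role="DHC", chain="C18"),
                   dict(id=2, role="DHC", chain="C18:1")],
            fluxes=[
                dict(id=1, enzyme_class="remodelase", produces=[1],
                     boundary_inputs=["FA"]),
                dict(id=2, enzyme_class="elongase", consumes=[1], produces=[2]),
                dict(id=3, enzyme_class="elongase", consumes=[2]),
            ],
            drivers={"FA": 1.0},
        )
        m = cf.build_ceramide_network(cfg)
        vin, k1, k2 = 2.0, 0.5, 0.25
        a = np.array([vin, k1, k2])
        x0 = np.array([1.0, 1.0])
        t = np.linspace(0, 10, 21)
        traj = cf.simulate(m, lambda _: a, x0, t)

        # closed form: A(t) = vin/k1 + (A0 - vin/k1) e^{-k1 t};
        # B' = k1 A - k2 B solved by variation of constants
        A = vin / k1 + (x0[0] - vin / k1) * np.exp(-k1 * t)
        c = k1 * (x0[0] - vin / k1)
        B = (vin / k2
             + c / (k2 - k1) * np.exp(-k1 * t)
             + (x0[1] - vin / k2 - c / (k2 - k1)) * np.exp(-k2 * t))
        np.testing.assert_allclose(traj[:, 0], A, rtol=1e-6)
        np.testing.assert_allclose(traj[:, 1], B, rtol=1e-6)

    def test_finite_difference_consistency(self, model, baseline,
                                           baseline_activities):
        """Central-difference slope of a dynamic trajectory matches rhs at
        interior grid points."""
        fold = lambda t: 1.0 + 0.5 * np.sin(t / 5.0)
        act = lambda t: baseline_activities * fold(t)
        t = np.linspace(0, 10, 201)
        traj = cf.simulate(model, act, baseline, t)
        h = t[1] - t[0]
        for i in (50, 100, 150):
            fd = (traj[i + 1] - traj[i - 1]) / (2 * h)
            dx = cf.rhs(model, traj[i], act(t[i]), t[i])
            np.testing.assert_allclose(fd, dx, rtol=1e-3, atol=1e-8)

    def test_negative_x0_rejected(self, model):
        with pytest.raises(ValueError):
            cf.simulate(model, lambda t: np.ones(53), -np.ones(15), [0.0, 1.0])


class TestBaselineSteadyState:
    def test_defining_property(self, model, baseline, baseline_activities):
        dx = cf.rhs(model, baseline, baseline_activities, 0.0)
        assert np.abs(dx).max() <= 1e-8

    def test_toy_chain_hand_solved(self, toy_chain):
        """With inflow group pinned at 2.0, every chain flux carries 2.0 and
        activities are flux / (driver or substrate)."""
        x0 = np.array([1.0, 2.0, 4.0])
        a = cf.solve_baseline_steady_state(toy_chain, x0,
                                           boundary_values={"inflow": 2.0})
        v = cf.evaluate_fluxes(toy_chain, x0, a, 0.0)
        np.testing.assert_allclose(v, [2.0, 2.0, 2.0, 2.0], atol=1e-9)
        # V1 = a1 * FA driver (2.0); V2 = a2 * x1; V4 = a4 * x3
        np.testing.assert_allclose(a, [1.0, 2.0, 1.0, 0.5], atol=1e-9)

    def test_boundary_scaling_linearity(self, toy_chain):
        x0 = np.array([1.0, 2.0, 4.0])
        a1 = cf.solve_baseline_steady_state(toy_chain, x0, {"inflow": 2.0})
        a2 = cf.solve_baseline_steady_state(toy_chain, x0, {"inflow": 4.0})
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-9)

    def test_infeasible_reported(self, toy_chain):
        """A chain cannot simultaneously balance and violate its own
        conservation: pin the inflow group to an impossible set."""
        x0 = np.array([1.0, 2.0, 4.0])
        from ceraflux.model_core import InfeasibleSteadyStateError
        with pytest.raises(InfeasibleSteadyStateError):
            # nonnegative fluxes cannot sum to a negative inflow
            cf.solve_baseline_steady_state(toy_chain, x0, {"inflow": -5.0})
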