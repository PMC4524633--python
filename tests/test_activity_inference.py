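"""Activity proxies, smoothing and windowed multiple-shooting refinement."""

import numpy as np
import pytest

import ceraflux as cf
from ceraflux.activity_inference import (
    MINUTES, _FastSim, refined_activity_course, window_of,
)


@pytest.fixture(scope="module")
def flat_course(model, baseline, baseline_activities, baseline_fluxes):
    """Steady-state flux course / concentrations (31 minutes)."""
    course = np.tile(baseline_fluxes, (31, 1))
    conc = np.tile(baseline, (31, 1))
    return course, conc


class TestProxies:
    def test_unit_activity_recovered(self, model, flat_course, baseline_activities):
        course, conc = flat_course
        profiles = cf.compute_activity_proxies(course, conc, model)
        for fid, prof in profiles.items():
            if prof.missing.any():
                continue
            np.testing.assert_allclose(prof.proxy,
                                       baseline_activities[fid - 1],
                                       rtol=1e-10)
            if prof.proxy[0] > 0:  # zero-baseline fluxes have no fold scale
                np.testing.assert_allclose(prof.fold, 1.0, rtol=1e-10)

    def test_recomposition_exact(self, model, baseline):
        """proxy x substrate product gives back the input flux minute-wise."""
        rng = np.random.default_rng(8)
        course = rng.uniform(0.1, 2.0, (31, 53))
        conc = np.tile(baseline, (31, 1)) * rng.uniform(0.5, 2.0, (31, 15))
        profiles = cf.compute_activity_proxies(course, conc, model)
        for i in range(31):
            act = np.array([profiles[j + 1].proxy[i] for j in range(53)])
            recomposed = cf.evaluate_fluxes(model, conc[i], act, float(i))
            np.testing.assert_allclose(recomposed, course[i], rtol=1e-9)

    def test_zero_substrate_flagged_missing(self, model, flat_course):
        course, conc = flat_course
        conc = conc.copy()
        conc[7, 0] = 0.0  # C14/C16 DHC vanishes at minute 7
        with pytest.warns(UserWarning, match="V3.*7"):
            profiles = cf.compute_activity_proxies(course, conc, model)
        assert profiles[3].missing[7]
        assert not profiles[3].missing[6]


class TestSmoothing:
    def test_constant_proxies_constant_function(self, model, flat_course):
        course, conc = flat_course
        profiles = cf.compute_activity_proxies(course, conc, model)
        f_set = cf.smooth_activities(profiles)
        t = np.linspace(0, 30, 61)
        for fid, f in f_set.items():
            np.testing.assert_allclose(f(t), profiles[fid].proxy[0],
                                       rtol=1e-6, atol=1e-12)

    def test_smoothing_contract_rmse(self, model, baseline):
        rng = np.random.default_rng(5)
        course = np.tile(np.linspace(1, 2, 31)[:, None], (1, 53))
        course *= rng.uniform(0.9, 1.1, (31, 53))
        conc = np.tile(baseline, (31, 1))
        profiles = cf.compute_activity_proxies(course, conc, model)
        f_set = cf.smooth_activities(profiles)
        for fid in (1, 25, 47):
            prof = profiles[fid]
            resid = f_set[fid](MINUTES) - prof.proxy
            assert np.sqrt(np.mean(resid**2)) <= prof.proxy.std() + 1e-12

    def test_interpolation_limit(self, model, flat_course):
        course, conc = flat_course
        course = course * (1 + 0.3 * np.sin(MINUTES / 5))[:, None]
        profiles = cf.compute_activity_proxies(course, conc, model)
        f_set = cf.smooth_activities(profiles, smoothing=1e-8)
        for fid in (2, 30):
            prof = profiles[fid]
            if np.all(prof.proxy > 0):
                np.testing.assert_allclose(f_set[fid](MINUTES), prof.proxy,
                                           rtol=0.01)

    def test_too_few_points_excluded(self, model, flat_course):
        course, conc = flat_course
        profiles = cf.compute_activity_proxies(course, conc, model)
        profiles[5].missing[:28] = True
        with pytest.warns(UserWarning, match="V5"):
            f_set = cf.smooth_activities(profiles)
        assert 5 not in f_set


class TestWindows:
    def test_window_assignment(self):
        assert window_of(0.0) == 0
        assert window_of(1.0) == 0
        assert window_of(3.0) == 0
        assert window_of(3.5) == 1
        assert window_of(9.0) == 2
        assert window_of(10.0) == 3
        assert window_of(30.0) == 9

    def test_identity_coefficients_reproduce_windowed_simulation(
            self, model, baseline, baseline_activities):
        """C == 1 equals the plain simulation restarted at window starts."""
        scen = cf.make_scenario(model, "heat_stress_demo")
        act_fn = scen.activity_fn(baseline_activities)
        traj = cf.simulate(model, act_fn, baseline, MINUTES)
        fine = np.arange(0.0, 30.0001, 0.01)
        table = (baseline_activities * scen.fold(fine)).T
        sim = _FastSim(model, table, fine)
        for s in (0.0, 12.0, 27.0):
            seg = sim.simulate(traj[int(s)], (s, s + 3.0),
                               np.arange(s + 1, s + 3.1))
            expect = cf.simulate(model, act_fn, traj[int(s)],
                                 np.arange(s, s + 3.1))[1:]
            # fixed-step midpoint-exponential stepper is ~1e-4 accurate
            np.testing.assert_allclose(seg, expect, rtol=1e-3, atol=1e-8)

    def test_refined_course_uses_window_coefficient(self, model,
                                                    baseline_activities):
        f_set = {j + 1: (lambda t, j=j: np.full(np.shape(np.atleast_1d(t)),
                                                baseline_activities[j]))
                 for j in range(53)}
        co = cf.WindowCoefficients(
            window_starts=np.arange(0.0, 30.0, 3.0), window_len=3.0,
            coefficients=np.ones((10, 53)),
            ensemble=np.ones((10, 1, 53)), sse=np.zeros((10, 1)),
            best=np.zeros(10, dtype=int))
        co.coefficients[4, 0] = 2.0  # window 12-15, V1
        course = refined_activity_course(co, f_set)
        # minute 12 closes window 9-12; minutes 13-15 belong to window 12-15
        assert course[12, 0] == pytest.approx(baseline_activities[0])
        assert course[13, 0] == pytest.approx(2 * baseline_activities[0])
        assert course[15, 0] == pytest.approx(2 * baseline_activities[0])
        assert course[16, 0] == pytest.approx(baseline_activities[0])


class TestReport:
    @pytest.fixture()
    def simple_coeffs(self):
        rng = np.random.default_rng(2)
        ens = rng.uniform(0.5, 2.0, (10, 3, 53))
        return cf.WindowCoefficients(
            window_starts=np.arange(0.0, 30.0, 3.0), window_len=3.0,
            coefficients=ens[:, 0, :], ensemble=ens,
            sse=np.zeros((10, 3)), best=np.zeros(10, dtype=int))

    def test_report_has_one_trend_per_flux(self, model, simple_coeffs,
                                           baseline_activities):
        f_set = {j + 1: (lambda t, j=j: np.full(np.shape(np.atleast_1d(t)),
                                                baseline_activities[j]))
                 for j in range(53)}
        summary, individuals = cf.assemble_activity_report(
            simple_coeffs, f_set, model)
        assert summary["flux_id"].nunique() == 53
        assert individuals["member"].nunique() == 3
        t0 = summary[summary["time_min"] == 0]
        # fold is 1 at t=0 wherever it is defined (zero-baseline-activity
        # fluxes have no fold scale and stay NaN)
        defined = t0["fold_change_mean"].notna()
        assert np.allclose(t0.loc[defined, "fold_change_mean"], 1.0)
        zero_base = np.asarray(baseline_activities)[
            t0.loc[~defined, "flux_id"].to_numpy() - 1]
        assert np.all(zero_base == 0)

    def test_average_is_mean_of_individuals(self, model, simple_coeffs,
                                            baseline_activities):
        f_set = {j + 1: (lambda t, j=j: np.full(np.shape(np.atleast_1d(t)),
                                                baseline_activities[j]))
                 for j in range(53)}
        summary, individuals = cf.assemble_activity_report(
            simple_coeffs, f_set, model)
        for (t, fid) in ((7, 3), (22, 41)):
            got = summary[(summary["time_min"] == t)
                          & (summary["flux_id"] == fid)]
            members = individuals[(individuals["time_min"] == t)
                                  & (individuals["flux_id"] == fid)]
            assert got["fold_change_mean"].iloc[0] == pytest.approx(
                members["fold_change"].mean())

    def test_single_member_average_equals_individual(self, model,
                                                     baseline_activities):
        ens = np.full((10, 1, 53), 1.3)
        co = cf.WindowCoefficients(
            window_starts=np.arange(0.0, 30.0, 3.0), window_len=3.0,
            coefficients=ens[:, 0, :], ensemble=ens,
            sse=np.zeros((10, 1)), best=np.zeros(10, dtype=int))
        f_set = {j + 1: (lambda t, j=j: np.full(np.shape(np.atleast_1d(t)),
                                                baseline_activities[j]))
                 for j in range(53)}
        summary, individuals = cf.assemble_activity_report(co, f_set, model)
        merged = summary.merge(individuals, on=["time_min", "flux_id"])
        np.testing.assert_allclose(merged["fold_change_mean"],
                                   merged["fold_change"])


class TestReconstruction:
    def test_steady_fluxes_keep_baseline(self, model, baseline,
                                         baseline_fluxes):
        course = np.tile(baseline_fluxes, (31, 1))
        states = cf.reconstruct_unmeasured(model, baseline, course)
        np.testing.assert_allclose(states, np.tile(baseline, (31, 1)),
                                   atol=1e-9)
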