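"""Tests of the Wiener density, static fits and the piecewise model."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

from cbgtclaw import ddm
from cbgtclaw.errors import InfeasibleScheduleError, ParameterError


class TestWfptDensity:
    def test_zero_before_onset(self):
        p = ddm.DdmParams(a=1.0, v=1.0, tr=0.3, z=0.5)
        assert ddm.wfpt_density(0.2, p, "upper") == 0.0
        assert ddm.wfpt_density(0.3, p, "lower") == 0.0

    def test_driftless_symmetry(self):
        p = ddm.DdmParams(a=1.0, v=0.0, tr=0.0, z=0.5)
        t = np.linspace(0.01, 5, 200)
        up = ddm.wfpt_density(t, p, "upper")
        lo = ddm.wfpt_density(t, p, "lower")
        assert np.allclose(up, lo)

    @pytest.mark.parametrize(
        "params",
        [
            ddm.DdmParams(a=1.0, v=0.0, tr=0.0, z=0.5),
            ddm.DdmParams(a=1.2, v=1.5, tr=0.25, z=0.5),
            ddm.DdmParams(a=0.8, v=-1.0, tr=0.1, z=0.35),
        ],
    )
    def test_normalisation_by_quadrature(self, params):
        total = sum(
            quad(lambda t: ddm.wfpt_density(t, params, b),
                 params.tr + 1e-9, 60, limit=300)[0]
            for b in ("upper", "lower")
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_driftless_mean_first_passage_is_a_squared(self):
        """Classical first-exit: E[T] = a^2 for sigma=1, start at 0."""
        p = ddm.DdmParams(a=1.0, v=0.0, tr=0.0, z=0.5)
        mean = quad(
            lambda t: t * (ddm.wfpt_density(t, p, "upper")
                           + ddm.wfpt_density(t, p, "lower")),
            1e-9, 60, limit=300,
        )[0]
        assert mean == pytest.approx(1.0, abs=1e-4)

    def test_density_matches_euler_simulation(self):
        """Analytic density vs a large Euler sample (CDF sup-distance)."""
        p = ddm.DdmParams(a=1.2, v=1.5, tr=0.25, z=0.5)
        # fine step: the Euler scheme's boundary-crossing bias is O(sqrt(dt))
        sim = ddm.simulate_static(p, 50_000, seed=0, dt_ms=0.1)
        ok = ~np.isnan(sim["rt"])
        rt_up = np.sort(sim["rt"][ok & (sim["choice"] > 0)])
        grid = np.linspace(p.tr + 0.01, 4.0, 80)
        fine = np.linspace(p.tr + 1e-6, 4.0, 8000)
        dens = ddm.wfpt_density(fine, p, "upper")
        cdf_fine = np.cumsum(dens) * (fine[1] - fine[0])
        cdf_analytic = np.interp(grid, fine, cdf_fine)
        cdf_emp = np.searchsorted(rt_up, grid) / ok.sum()
        assert np.max(np.abs(cdf_analytic - cdf_emp)) < 0.02


class TestStaticFit:
    def test_parameter_recovery_within_ten_percent(self):
        true = ddm.DdmParams(a=1.2, v=1.5, tr=0.25, z=0.5)
        sim = ddm.simulate_static(true, 2000, seed=3)
        ok = ~np.isnan(sim["rt"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ddm.fit_static(
                np.where(sim["choice"][ok] > 0, "L", "R"), sim["rt"][ok]
            )
        f = fit.params
        assert f.a == pytest.approx(true.a, rel=0.10)
        assert f.v == pytest.approx(true.v, rel=0.10)
        assert f.tr == pytest.approx(true.tr, rel=0.10)
        assert f.z == pytest.approx(true.z, rel=0.10)

    def test_refit_self_consistency(self):
        """Refitting data simulated from a fit stays within a couple of
        nats per comparable sample."""
        true = ddm.DdmParams(a=1.0, v=1.0, tr=0.2, z=0.5)
        sim = ddm.simulate_static(true, 1500, seed=4)
        ok = ~np.isnan(sim["rt"])
        ch = np.where(sim["choice"][ok] > 0, "L", "R")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit1 = ddm.fit_static(ch, sim["rt"][ok])
            sim2 = ddm.simulate_static(fit1.params, 1500, seed=5)
            ok2 = ~np.isnan(sim2["rt"])
            fit2 = ddm.fit_static(
                np.where(sim2["choice"][ok2] > 0, "L", "R"), sim2["rt"][ok2]
            )
        per_trial = abs(fit1.loglike / ok.sum() - fit2.loglike / ok2.sum())
        assert per_trial < 0.1

    def test_degenerate_all_upper_flags_bound(self):
        rng = np.random.default_rng(0)
        rts = 0.5 + 0.01 * rng.random(100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ddm.StaticDDM().fit(["L"] * 100, rts)
        assert est.result_.at_bound

    def test_consolidation_flag_requires_data(self):
        with pytest.raises(Exception):
            ddm.fit_static(["L"] * 60, np.ones(60), include_consolidation=True)


class TestPhaseSolver:
    def test_zero_changes_return_static_exactly(self):
        static = ddm.DdmParams(a=1.3, v=0.7, tr=0.2, z=0.5)
        sch = ddm.PhaseSchedule(
            zones=["I", "II", "III"], dwell_ms=[40, 30, 30],
            boundary_pct=[0, 0], drift_pct=[0, 0],
        )
        dp = ddm.solve_phase_params(sch, static)
        assert dp.a == pytest.approx([1.3, 1.3, 1.3])
        assert dp.v == pytest.approx([0.7, 0.7, 0.7])

    def test_printed_example_values(self):
        """Direct-substitution oracle: DT=100, t=(50,30,20), x=10, y=20."""
        static = ddm.DdmParams(a=1.0, v=1.0, tr=0.1, z=0.5)
        sch = ddm.PhaseSchedule(
            zones=["I", "II", "III"], dwell_ms=[50, 30, 20],
            boundary_pct=[10, 20], drift_pct=[0, 0],
        )
        dp = ddm.solve_phase_params(sch, static)
        assert dp.a[0] == pytest.approx(1.0941, abs=1e-4)
        assert dp.a[1] == pytest.approx(0.9847, abs=1e-4)
        assert dp.a[2] == pytest.approx(0.7878, abs=1e-4)

    def test_time_weighted_constraint_on_random_schedules(self):
        """The solver inverts the time-weighted average to 1e-12."""
        rng = np.random.default_rng(1)
        static = ddm.DdmParams(a=1.1, v=-0.9, tr=0.15, z=0.45)
        for _ in range(1000):
            n = rng.choice([2, 3])
            dwell = rng.uniform(5, 200, n).tolist()
            pct = rng.uniform(-80, 80, n - 1).tolist()
            pct_v = rng.uniform(-80, 80, n - 1).tolist()
            sch = ddm.PhaseSchedule(
                zones=["I", "II", "III"][:n], dwell_ms=dwell,
                boundary_pct=pct, drift_pct=pct_v,
            )
            try:
                dp = ddm.solve_phase_params(sch, static)
            except InfeasibleScheduleError:
                continue
            frac = np.asarray(dwell) / np.sum(dwell)
            assert abs(float(frac @ dp.a) - static.a) < 1e-12
            assert abs(float(frac @ dp.v) - static.v) < 1e-12

    def test_two_phase_schedule(self):
        static = ddm.DdmParams(a=1.0, v=1.0, tr=0.1, z=0.5)
        sch = ddm.PhaseSchedule(
            zones=["I", "III"], dwell_ms=[60, 40],
            boundary_pct=[25], drift_pct=[0],
        )
        dp = ddm.solve_phase_params(sch, static)
        assert dp.a[1] == pytest.approx(0.75 * dp.a[0])
        assert 0.6 * dp.a[0] + 0.4 * dp.a[1] == pytest.approx(1.0)

    def test_percent_decrease_at_or_beyond_100_rejected(self):
        with pytest.raises(ParameterError):
            ddm.PhaseSchedule(
                zones=["I", "II"], dwell_ms=[50, 50],
                boundary_pct=[100], drift_pct=[0],
            )


class TestDynamicSimulation:
    def _static(self):
        return ddm.DdmParams(a=1.2, v=1.5, tr=0.25, z=0.5)

    def test_driftless_symmetric_choices(self):
        static = ddm.DdmParams(a=1.0, v=0.0, tr=0.1, z=0.5)
        sch = ddm.PhaseSchedule(
            zones=["I", "II"], dwell_ms=[50, 50],
            boundary_pct=[10], drift_pct=[0],
        )
        dp = ddm.solve_phase_params(sch, static)
        sim = ddm.simulate_dynamic(dp, sch, static, 4000, seed=0)
        kept = sim["kept"]
        p_up = (sim["choice"][kept] > 0).mean()
        se = np.sqrt(0.25 / kept.sum())
        assert abs(p_up - 0.5) < 3 * se + 0.01

    def test_zero_change_reduces_to_static(self):
        """With x=y=0, the piecewise sample is KS-indistinguishable from
        the static simulator."""
        static = self._static()
        sch = ddm.PhaseSchedule(
            zones=["I", "II", "III"], dwell_ms=[30, 40, 60],
            boundary_pct=[0, 0], drift_pct=[0, 0],
        )
        dp = ddm.solve_phase_params(sch, static)
        dyn = ddm.simulate_dynamic(dp, sch, static, 8000, seed=1)
        sta = ddm.simulate_static(static, 5000, seed=2)
        a = dyn["rt"][~np.isnan(dyn["rt"])][:5000]
        b = sta["rt"][~np.isnan(sta["rt"])]
        assert ks_2samp(a, b).pvalue > 0.01

    def test_collapse_decisions_occur_when_final_boundary_tiny(self):
        static = self._static()
        sch = ddm.PhaseSchedule(
            zones=["I", "II", "III"], dwell_ms=[200, 200, 200],
            boundary_pct=[10, 85], drift_pct=[0, 0],
        )
        dp = ddm.solve_phase_params(sch, static)
        sim = ddm.simulate_dynamic(dp, sch, static, 4000, seed=3)
        # sharply collapsed a3 harvests decisions right at the transition
        trans2 = static.tr + 0.4
        kept_rt = sim["rt"][sim["kept"]]
        near = np.abs(kept_rt - trans2) < 0.02
        assert near.mean() > 0.05

    def test_rts_exceed_onset_time(self):
        static = self._static()
        sch = ddm.PhaseSchedule(
            zones=["I", "II"], dwell_ms=[50, 100],
            boundary_pct=[20], drift_pct=[-20],
        )
        dp = ddm.solve_phase_params(sch, static)
        sim = ddm.simulate_dynamic(dp, sch, static, 2000, seed=4)
        assert np.all(sim["rt"][sim["kept"]] > static.tr)

    def test_discards_grow_with_earlier_transitions(self):
        """Scheduling more of the trajectory inside early phases leaves
        more room for premature crossings, so the discard rate rises."""
        static = ddm.DdmParams(a=0.8, v=1.5, tr=0.1, z=0.5)
        rates = []
        for first_ms in (50, 300, 900):
            sch = ddm.PhaseSchedule(
                zones=["I", "II"], dwell_ms=[first_ms, 50],
                boundary_pct=[0], drift_pct=[0],
            )
            dp = ddm.solve_phase_params(sch, static)
            sim = ddm.simulate_dynamic(dp, sch, static, 3000, seed=5)
            rates.append(sim["discard_rate"])
        assert rates[0] <= rates[1] <= rates[2]


@pytest.fixture(scope="module")
def cca():
    from cbgtclaw import ensembles as E

    rng = np.random.default_rng(0)
    X = rng.standard_normal((80, 18))
    B = rng.standard_normal((18, 4)) * 0.4
    Y = X @ B + 0.05 * rng.standard_normal((80, 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return E.ControlEnsembleCCA().fit(X, Y)


class TestDerivePercentChanges:

    def test_zero_activity_change_zero_percent(self, cca):
        static = ddm.DdmParams(a=1.0, v=1.0, tr=0.1, z=0.5)
        s = np.ones(18)
        b, v = ddm.derive_percent_changes([s, s.copy()], cca, static)
        assert b == pytest.approx([0.0])
        assert v == pytest.approx([0.0])

    def test_doubling_delta_doubles_percent(self, cca):
        static = ddm.DdmParams(a=1.0, v=1.0, tr=0.1, z=0.5)
        rng = np.random.default_rng(1)
        s0 = rng.random(18)
        d = rng.standard_normal(18) * 0.1
        b1, v1 = ddm.derive_percent_changes([s0, s0 + d], cca, static)
        b2, v2 = ddm.derive_percent_changes([s0, s0 + 2 * d], cca, static)
        assert b2[0] == pytest.approx(2 * b1[0], rel=1e-9)
        assert v2[0] == pytest.approx(2 * v1[0], rel=1e-9)

    def test_near_zero_static_parameter_rejected(self, cca):
        static = ddm.DdmParams(a=1.0, v=1e-14, tr=0.1, z=0.5)
        with pytest.raises(ParameterError):
            ddm.derive_percent_changes([np.zeros(18), np.ones(18)], cca, static)


class TestCompareModels:
    def test_generative_recovery_dynamic_wins(self):
        """Data generated by a strongly phase-changing model give the
        dynamic model the lower BIC."""
        true = ddm.DdmParams(a=1.2, v=0.8, tr=0.25, z=0.5)
        sch = ddm.PhaseSchedule(
            zones=["I", "II", "III"], dwell_ms=[150, 150, 200],
            boundary_pct=[20, 40], drift_pct=[-50, -80],
        )
        dp = ddm.solve_phase_params(sch, true)
        gen = ddm.simulate_dynamic(dp, sch, true, 15000, seed=7)
        ok = ~np.isnan(gen["rt"])
        rts = gen["rt"][ok][:1500]
        ch = np.where(gen["choice"][ok][:1500] > 0, "L", "R")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ddm.fit_static(ch, rts)
        res = ddm.compare_models(fit, dp, sch, ch, rts, n_sim=30000,
                                 dynamic_init=true)
        assert res["bic_dynamic"] < res["bic_static"]
        assert (abs(res["mean_rt_dynamic"] - res["mean_rt_data"])
                < abs(res["mean_rt_static"] - res["mean_rt_data"]))

    def test_static_data_favours_static_within_penalty(self):
        """On static-generated data the dynamic model cannot beat static
        by more than its extra-parameter penalty."""
        true = ddm.DdmParams(a=1.1, v=1.2, tr=0.2, z=0.5)
        sim = ddm.simulate_static(true, 3000, seed=8)
        ok = ~np.isnan(sim["rt"])
        rts = sim["rt"][ok][:1000]
        ch = np.where(sim["choice"][ok][:1000] > 0, "L", "R")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ddm.fit_static(ch, rts)
        sch = ddm.PhaseSchedule(
            zones=["I", "II"], dwell_ms=[50, 100],
            boundary_pct=[0], drift_pct=[0],
        )
        dp = ddm.solve_phase_params(sch, fit)
        res = ddm.compare_models(fit, dp, sch, ch, rts, n_sim=30000)
        # dynamic is the same process here; BIC differs by penalty plus
        # KDE approximation error only
        penalty_gap = (res["k_dynamic"] - res["k_static"]) * np.log(len(rts))
        assert res["bic_dynamic"] >= res["bic_static"] - 1.0
        assert res["bic_dynamic"] - res["bic_static"] < penalty_gap + 100.0

    def test_empty_data_rejected(self):
        fit = ddm.StaticFit(
            params=ddm.DdmParams(a=1, v=1, tr=0.1, z=0.5),
            loglike=0.0, n_trials=0,
        )
        sch = ddm.PhaseSchedule(zones=["I", "II"], dwell_ms=[50, 50],
                                boundary_pct=[0], drift_pct=[0])
        dp = ddm.solve_phase_params(sch, fit)
        with pytest.raises(Exception):
            ddm.compare_models(fit, dp, sch, [], [])
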