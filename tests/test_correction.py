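import numpy as np
import pytest

from mpcest import bmc, correction, synthetic, workflow
from mpcest.correction import CorrectionModel, DynamicT2
from mpcest.dge import mtr_asym_dge, single_offset_dge
from mpcest.presets import default_pulse, get_preset


@pytest.fixture(scope="module")
def tumor_p():
    return get_preset("tumor")


@pytest.fixture(scope="module")
def pulse_m():
    return default_pulse()


@pytest.fixture(scope="module")
def linear_model(tumor_p, pulse_m):
    return correction.calibrate_linear(
        tumor_p.background_pools(), pulse_m, t2_ref=tumor_p.t2_ref_ms
    )


@pytest.fixture(scope="module")
def quad_model(tumor_p, pulse_m):
    conc_ref = synthetic.conc_for_t2_drop(47.5, 44.0)
    return correction.calibrate_quadratic(
        tumor_p.pools(conc_ref), pulse_m, t2_ref=tumor_p.t2_ref_ms
    )


class TestCalibrateLinear:
    def test_degenerate_grid_rejected(self, tumor_p, pulse_m):
        with pytest.raises(ValueError, match="degenerate"):
            correction.calibrate_linear(
                tumor_p.background_pools(), pulse_m, np.array([47.5]), 47.5
            )

    def test_background_signal_rises_with_t2(self, linear_model):
        # spillover narrows as T2 grows, so k > 0
        assert linear_model.k > 0
        assert linear_model.linear_r2 > 0.99

    def test_water_only_background_positive_k(self, pulse_m):
        phantom = get_preset("phantom")
        model = correction.calibrate_linear(
            phantom.background_pools(), pulse_m, t2_ref=100.0
        )
        assert model.k > 0

    def test_doubling_b1_changes_k(self, tumor_p, pulse_m, linear_model):
        strong = bmc.SaturationPulse(2 * pulse_m.b1, pulse_m.t_sat)
        model2 = correction.calibrate_linear(
            tumor_p.background_pools(), strong, t2_ref=tumor_p.t2_ref_ms
        )
        assert model2.k != pytest.approx(linear_model.k, rel=0.01)

    def test_glucose_in_background_rejected(self, tumor_p, pulse_m):
        with pytest.raises(ValueError, match="glucose-free"):
            correction.calibrate_linear(tumor_p.pools(10.0), pulse_m, t2_ref=47.5)


class TestBackgroundMtrContribution:
    def test_zero_excursion_gives_zero(self, quad_model):
        assert correction.background_mtr_contribution(quad_model, 0.0) == 0.0

    def test_quadratic_fit_of_analytic_curve(self, quad_model):
        dt2 = np.linspace(-10, 10, 41)
        curve = correction.background_mtr_contribution(quad_model, dt2)
        coeffs = np.polyfit(dt2, curve, 2)
        resid = np.max(np.abs(np.polyval(coeffs, dt2) - curve))
        assert resid < 1e-3

    def test_monotone_over_physiological_branch(self, quad_model):
        dt2 = np.linspace(-10, 10, 81)
        curve = correction.background_mtr_contribution(quad_model, dt2)
        assert np.all(np.diff(curve) > 0)

    def test_uncalibrated_model_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            correction.background_mtr_contribution(CorrectionModel(t2_ref=47.5), 1.0)


class TestCalibrateQuadratic:
    def test_self_consistency_on_grid(self, tumor_p, pulse_m, quad_model):
        # fitted polynomial reproduces the simulated curve it was fit to
        assert quad_model.quad_residual < 1e-3

    def test_requires_glucose_pool(self, tumor_p, pulse_m):
        with pytest.raises(ValueError, match="glucose"):
            correction.calibrate_quadratic(
                tumor_p.background_pools(), pulse_m, t2_ref=47.5
            )

    def test_near_linear_curve_has_negligible_quadratic_term(self, quad_model):
        # analytic curve with a small k: a = scale * k^2 -> vanishes
        small = CorrectionModel(
            t2_ref=47.5, k=1e-6, s0_bg=quad_model.s0_bg, scale=quad_model.scale
        )
        dt2 = np.linspace(-10, 10, 21)
        a, b, c = np.polyfit(
            dt2, correction.background_mtr_contribution(small, dt2), 2
        )
        assert abs(a * 10.0**2) < 1e-4 * abs(b * 10.0)

    def test_t2_decrease_gives_negative_contribution(self, quad_model):
        # in vivo regime: T2 drop -> background term pulls MTR_asym down
        val = np.polyval([quad_model.a, quad_model.b, 0.0], -3.0)
        assert val < 0

    def test_analytic_source_matches_closed_form(self, tumor_p, pulse_m):
        conc_ref = synthetic.conc_for_t2_drop(47.5, 44.0)
        m = correction.calibrate_quadratic(
            tumor_p.pools(conc_ref), pulse_m, t2_ref=47.5, source="analytic"
        )
        assert m.a == pytest.approx(m.scale * m.k**2)
        assert m.b == pytest.approx(2 * m.scale * m.s0_bg * m.k)
        assert m.c == 0.0
        assert m.quad_residual == 0.0


def _truth_series(preset, conc_curve, t2_drift, nf, nb):
    proto = synthetic.DynamicProtocol(
        n_frames=nf, n_baseline=nb, t2_baseline=preset.t2_ref_ms,
        conc_curve=conc_curve, t2_drift=t2_drift,
    )
    tr = synthetic.simulate_dge_experiment(proto, tissue=preset, grid=None)["truth"]
    series = mtr_asym_dge(
        single_offset_dge(
            synthetic.dge_series_from_signals(
                tr["signal"], tr["offsets"], tr["time"], tr["baseline_idx"]
            )
        )
    )
    return series, DynamicT2(tr["time"], tr["t2"], tr["baseline_idx"])


class TestCorrections:
    def test_identity_under_zero_excursion(self, linear_model, quad_model, tumor_p):
        nf, nb = 12, 4
        series, t2 = _truth_series(tumor_p, np.zeros(nf), np.zeros(nf), nf, nb)
        cs = correction.correct_single_offset(series, t2, linear_model)
        cm = correction.correct_mtr_asym(series, t2, quad_model)
        np.testing.assert_array_equal(cs.dge, series.dge)
        np.testing.assert_array_equal(cm.dge_asym, series.dge_asym)

    def test_null_experiment_suppression(self, tumor_p, pulse_m):
        # glucose constant, T2 ramps 47.5 -> 44.0: corrected DGE ~ 0
        nf, nb = 40, 8
        t = np.arange(nf) * 45.0
        ramp = synthetic.make_uptake_curve(t, nb * 45.0, 1.0)
        series, t2 = _truth_series(tumor_p, np.zeros(nf), -3.5 * ramp, nf, nb)
        grid = np.linspace(43.0, 48.5, 21)
        lin = correction.calibrate_linear(tumor_p.background_pools(), pulse_m, grid, 47.5)
        conc_ref = synthetic.conc_for_t2_drop(47.5, 44.0)
        quad = correction.calibrate_quadratic(tumor_p.pools(conc_ref), pulse_m, grid, 47.5)
        cs = correction.correct_single_offset(series, t2, lin)
        cm = correction.correct_mtr_asym(series, t2, quad)
        assert np.max(np.abs(series.dge)) > 1.0  # sizeable artifact
        assert np.max(np.abs(cs.dge)) < 0.1 * np.max(np.abs(series.dge))
        assert abs(np.mean(cs.dge[nb:])) < 0.1
        assert abs(np.mean(cm.dge_asym[nb:])) < 0.1

    def test_time_misalignment_rejected(self, linear_model, tumor_p):
        nf, nb = 10, 3
        series, t2 = _truth_series(tumor_p, np.zeros(nf), np.zeros(nf), nf, nb)
        shifted = DynamicT2(t2.time + 30.0, t2.t2, t2.baseline_idx)
        with pytest.raises(ValueError, match="misaligned"):
            correction.correct_single_offset(series, shifted, linear_model)

    def test_missing_coefficients_rejected(self, tumor_p):
        nf, nb = 10, 3
        series, t2 = _truth_series(tumor_p, np.zeros(nf), np.zeros(nf), nf, nb)
        with pytest.raises(ValueError):
            correction.correct_single_offset(series, t2, CorrectionModel(t2_ref=47.5))
        with pytest.raises(ValueError):
            correction.correct_mtr_asym(series, t2, CorrectionModel(t2_ref=47.5))

    def test_combined_bias_directions_and_recovery(self, pulse_m):
        # brain-scale coupled experiment (T2 44.3 -> 43.0)
        brain = get_preset("brain")
        nf, nb = 40, 8
        t = np.arange(nf) * 45.0
        conc_ref = synthetic.conc_for_t2_drop(44.3, 43.0)
        conc = synthetic.make_uptake_curve(t, nb * 45.0, conc_ref, tau=300.0)
        proto = synthetic.DynamicProtocol(
            n_frames=nf, n_baseline=nb, t2_baseline=44.3, conc_curve=conc
        )
        series, t2 = _truth_series(brain, conc, np.zeros(nf), nf, nb)
        ref_series, _ = _truth_series(brain, conc, 44.3 - proto.t2_curve, nf, nb)
        grid = np.linspace(41.3, 47.3, 21)
        lin = correction.calibrate_linear(brain.background_pools(), pulse_m, grid, 44.3)
        quad = correction.calibrate_quadratic(brain.pools(conc_ref), pulse_m, grid, 44.3)
        cs = correction.correct_single_offset(series, t2, lin)
        cm = correction.correct_mtr_asym(series, t2, quad)
        pl = slice(30, nf)
        # T2 decrease inflates single-offset DGE and deflates MTR_asym DGE
        assert series.dge[pl].mean() > ref_series.dge[pl].mean()
        assert series.dge_asym[pl].mean() < ref_series.dge_asym[pl].mean()
        # correction moves both toward the glucose-only reference
        assert cs.dge[pl].mean() == pytest.approx(ref_series.dge[pl].mean(), rel=0.10)
        assert cm.dge_asym[pl].mean() == pytest.approx(
            ref_series.dge_asym[pl].mean(), rel=0.10
        )


class TestDecouplingReport:
    def _series_pair(self, dge_vals, corrected_vals, t2_vals):
        n = len(dge_vals)
        base = dict(
            time=np.arange(n) * 45.0, signal=np.full(n, 0.8),
            baseline_idx=np.arange(2),
        )
        from mpcest.dge import DgeSeries

        orig = DgeSeries(**base)
        orig.dge = np.asarray(dge_vals, dtype=float)
        corr = DgeSeries(**base)
        corr.dge = np.asarray(corrected_vals, dtype=float)
        t2 = DynamicT2(base["time"], np.asarray(t2_vals, dtype=float), np.arange(2))
        return orig, corr, t2

    def test_proportional_series_r_is_one(self):
        t2_vals = np.linspace(40, 50, 20)
        orig, corr, t2 = self._series_pair(2 * t2_vals, np.zeros(20), t2_vals)
        rep = correction.decoupling_report(orig, corr, t2)
        assert rep["single_offset"]["original"]["r"] == pytest.approx(1.0)

    def test_constant_series_flagged_not_crashed(self):
        orig, corr, t2 = self._series_pair(np.ones(10), np.ones(10), np.linspace(40, 50, 10))
        rep = correction.decoupling_report(orig, corr, t2)
        assert not rep["single_offset"]["original"]["defined"]
        assert np.isnan(rep["single_offset"]["original"]["r"])

    def test_independent_noise_null_distribution(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=100), rng.normal(size=100)
            orig, corr, t2 = self._series_pair(x, x, 45 + y)
            rep = correction.decoupling_report(orig, corr, t2)
            if abs(rep["single_offset"]["original"]["r"]) < 0.3:
                hits += 1
        assert hits >= 95

    def test_combined_simulation_decouples(self):
        # one seed of the default combined suite, end-to-end through imaging
        tumor = get_preset("tumor")
        pulse = default_pulse()
        nf, nb = 60, 10
        t = np.arange(nf) * 45.0
        conc = synthetic.make_uptake_curve(t, nb * 45.0, 10.0, tau=300.0)
        drift = synthetic.drift_curve(t, 6.0, seed=0, periods=(270.0, 450.0))
        proto = synthetic.DynamicProtocol(
            n_frames=nf, n_baseline=nb, t2_baseline=47.5, conc_curve=conc,
            t2_drift=drift, noise="rician", snr=50.0, seed=0,
        )
        res = synthetic.simulate_dge_experiment(proto, tissue=tumor, grid=(16, 16))
        series, dyn_t2 = workflow.quantify_dynamic(
            res["stack"], res["s0_stack"], proto.baseline_idx, roi=res["roi"]
        )
        grid = np.linspace(47.5 - 8, 47.5 + 8, 21)
        model = correction.calibrate_quadratic(tumor.pools(10.0), pulse, grid, 47.5)
        orig, corr = workflow.correct_series(series, dyn_t2, model)
        rep = correction.decoupling_report(orig, corr, dyn_t2)
        for mode in ("single_offset", "mtr_asym"):
            assert abs(rep[mode]["corrected"]["r"]) < abs(rep[mode]["original"]["r"])


class TestModelSerialization:
    def test_bit_exact_round_trip(self, quad_model, tmp_path):
        from mpcest import io

        path = tmp_path / "model.json"
        io.write_model(path, quad_model, seed=7)
        back = io.read_model(path)
        for name in ("t2_ref", "offset", "k", "s0_bg", "a", "b", "c", "scale"):
            assert getattr(back, name) == getattr(quad_model, name)
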