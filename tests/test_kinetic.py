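import numpy as np
import pytest
from scipy.integrate import fixed_quad, quad

from petkin.convolve import ConvolutionEngine
from petkin.core import FrameSchedule, TimeActivityCurve
from petkin.input_function import InputFunction
from petkin.kinetic import (FitOptions, Params1T, Params2T, SRTMParams,
                            fit_compartment, fit_srtm, model_1t, model_2t,
                            srtm_assumption_check)
from petkin.simulate import NoiseModel


def conv_oracle(inp, alpha, t):
    """Numerical-quadrature convolution, integrated piecewise between knots."""
    knots = inp.times[inp.times < t]
    edges = np.concatenate([knots, [t]])
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda s: np.exp(-alpha * (t - s)) * inp.evaluate(s),
                      a, b, limit=200)
        total += val
    return total


class TestForwardModels:
    def test_1t_step_input_closed_form(self, constant_input, sch60):
        # C_p = 1: C(t) = (K1/k2)(1 - e^(-k2 t)), asymptote VT = 1
        eng = ConvolutionEngine(constant_input, sch60)
        got = 0.5 * eng.basis_at_midpoints(0.5)
        t = sch60.midpoints
        np.testing.assert_allclose(got, 1.0 - np.exp(-0.5 * t), rtol=1e-12)

    def test_k1_zero_gives_blood_only(self, inp60, sch60):
        wb = TimeActivityCurve(sch60, np.linspace(5, 1, 42))
        out = model_1t(Params1T(0.0, 0.5, vB=0.1), inp60, sch60, wb)
        np.testing.assert_allclose(out.values, 0.1 * wb.values, rtol=1e-12)

    def test_instantaneous_matches_quadrature(self, inp60, sch60):
        eng = ConvolutionEngine(inp60, sch60)
        inst = 0.1 * eng.basis_at_midpoints(0.2)
        for i in (6, 28, 41):
            t = sch60.midpoints[i]
            expected = 0.1 * conv_oracle(inp60, 0.2, t)
            assert inst[i] == pytest.approx(expected, rel=1e-8)

    def test_frame_average_matches_quadrature(self, inp60, sch60):
        eng = ConvolutionEngine(inp60, sch60)
        avg = eng.basis_frame_avg(0.2)
        for i in (30, 41):
            a, b = sch60.starts[i], sch60.ends[i]
            val, _ = fixed_quad(
                lambda tt: np.array([conv_oracle(inp60, 0.2, t) for t in tt]),
                a, b, n=24)
            assert avg[i] == pytest.approx(val / (b - a), rel=1e-8)

    def test_2t_collapses_to_1t_when_k3_zero(self, inp60, sch60):
        for k4 in (0.0, 0.123, 0.4):
            c2 = model_2t(Params2T(0.3, 0.4, 0.0, k4), inp60, sch60).values
            c1 = model_1t(Params1T(0.3, 0.4), inp60, sch60).values
            np.testing.assert_allclose(c2, c1, rtol=1e-10)

    def test_repeated_root_continuity(self, inp60, sch60):
        # k3 = 0, k2 = k4 is the degenerate eigenvalue case; the analytic
        # t*exp kernel must join continuously with nearby distinct roots
        exact = model_2t(Params2T(0.3, 0.5, 0.0, 0.5), inp60, sch60).values
        near = model_2t(Params2T(0.3, 0.5, 0.0, 0.5 + 1e-5), inp60, sch60).values
        np.testing.assert_allclose(exact, near, rtol=1e-3)
        # and it still equals the 1TCM (k3 = 0 collapse)
        c1 = model_1t(Params1T(0.3, 0.5), inp60, sch60).values
        np.testing.assert_allclose(exact, c1, rtol=1e-9)

    def test_irreversible_late_slope_is_ki(self, constant_input):
        # k4 = 0 under constant input: dC/dt -> Ki * C_p
        p = Params2T(0.1, 0.2, 0.1, 0.0)
        sch = FrameSchedule.from_durations([1.0] * 240)
        out = model_2t(p, constant_input, sch).values
        t = sch.midpoints
        late = t > 120
        slope = np.polyfit(t[late], out[late], 1)[0]
        assert slope == pytest.approx(p.Ki, rel=1e-6)

    def test_tumor_truth_vt(self, tumor_rhpsma):
        assert tumor_rhpsma.VT == pytest.approx(0.24)
        assert tumor_rhpsma.K1 == 0.34 and tumor_rhpsma.k3 == 0.6

    def test_linearity_in_input(self, inp60, sch60, tumor_rhpsma):
        scaled = inp60.scaled(3.0)
        a = model_2t(tumor_rhpsma, inp60, sch60).values
        b = model_2t(tumor_rhpsma, scaled, sch60).values
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-12)

    def test_vt_monotone_in_k3(self):
        vts = [Params2T(0.3, 0.5, k3, 0.2).VT for k3 in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(vts) > 0)


class TestFitCompartment:
    def test_noiseless_1t_self_consistency(self, inp60, sch60):
        truth = Params1T(0.25, 0.35)
        tac = model_1t(truth, inp60, sch60)
        fit = fit_compartment(tac, inp60, model="1TCM",
                              options=FitOptions(multistart_count=5))
        assert fit.sswres < 1e-12
        assert fit.params["K1"] == pytest.approx(0.25, rel=1e-6)
        assert fit.params["k2"] == pytest.approx(0.35, rel=1e-6)

    def test_noiseless_2t_recovers_truth_3sig(self, inp90, sch90):
        truth = Params2T.from_vt(K1=0.16, k2=0.6, k3=0.09, VT=1.5)
        tac = model_2t(truth, inp90, sch90)
        fit = fit_compartment(tac, inp90, model="2TCM")
        for name in ("K1", "k2", "k3", "k4"):
            assert fit.params[name] == pytest.approx(getattr(truth, name), rel=1e-3)
        assert fit.derived["VT"] == pytest.approx(1.5, rel=1e-3)

    def test_noisy_recovery_median_bias(self, inp60, sch60, tumor_rhpsma):
        # scale-0.05 count noise: median relative bias of K1 and VT below 5%
        clean = model_2t(tumor_rhpsma, inp60, sch60)
        noise = NoiseModel(0.05)
        rng = np.random.default_rng(42)
        opts = FitOptions(multistart_count=5, seed=1)
        k1s, vts = [], []
        for _ in range(200):
            vals = noise.sample(clean.values, sch60.durations, rng)
            fit = fit_compartment(clean.with_values(vals), inp60,
                                  model="2TCM", options=opts)
            k1s.append(fit.params["K1"])
            vts.append(fit.derived["VT"])
        assert abs(np.median(k1s) / tumor_rhpsma.K1 - 1) < 0.05
        assert abs(np.median(vts) / tumor_rhpsma.VT - 1) < 0.05

    def test_weighting_modes_and_determinism(self, inp60, sch60, tumor_rhpsma):
        tac = model_2t(tumor_rhpsma, inp60, sch60)
        noisy = tac.with_values(tac.values * (1 + 0.02 * np.sin(np.arange(42))))
        for weighting in ("uniform", "frame_duration"):
            opts = FitOptions(weighting=weighting, multistart_count=5, seed=9)
            a = fit_compartment(noisy, inp60, model="2TCM", options=opts)
            b = fit_compartment(noisy, inp60, model="2TCM", options=opts)
            assert a.params == b.params  # same seed, bit-identical

    def test_stderr_reported(self, inp60, sch60, tumor_rhpsma):
        tac = model_2t(tumor_rhpsma, inp60, sch60)
        noisy = tac.with_values(np.clip(
            tac.values + np.random.default_rng(0).normal(0, 0.3, 42), 0, None))
        fit = fit_compartment(noisy, inp60, model="2TCM",
                              options=FitOptions(multistart_count=5))
        assert all(np.isfinite(fit.stderr[k]) for k in ("K1", "k2", "k3", "k4"))


def make_1tcm_pair(inp, sch, bp_true=0.5):
    """Target/reference 1TCM regions obeying the SRTM assumptions."""
    ref = Params1T(0.4, 0.4)                       # VT_ref = 1
    tgt = Params1T(0.44, 0.44 / (1.0 + bp_true))   # VT_tgt = (1+BP) VT_ref
    return (model_1t(tgt, inp, sch), model_1t(ref, inp, sch))


class TestSrtm:
    def test_identity(self, inp60, sch60):
        ref = model_1t(Params1T(0.4, 0.4), inp60, sch60)
        fit = fit_srtm(ref, ref)
        assert fit.params["R1"] == pytest.approx(1.0, abs=1e-4)
        assert fit.params["BPND"] == pytest.approx(0.0, abs=1e-3)

    def test_recovers_binding_potential(self, inp60, sch60):
        target, ref = make_1tcm_pair(inp60, sch60, bp_true=0.5)
        fit = fit_srtm(target, ref)
        assert fit.params["BPND"] == pytest.approx(0.5, abs=0.01)

    def test_assumption_diagnostic_flags_violation(self, inp60, sch60):
        # valid pair passes ...
        target, ref = make_1tcm_pair(inp60, sch60, bp_true=0.5)
        ok = srtm_assumption_check(target, ref, inp60,
                                   options=FitOptions(multistart_count=5))
        assert ok["assumptions_ok"]
        # ... a 3x distribution-volume mismatch is flagged
        bad_target = model_1t(Params1T(0.4, 0.4 / 3.0), inp60, sch60)
        bad = srtm_assumption_check(bad_target, ref, inp60,
                                    options=FitOptions(multistart_count=5))
        assert bad["vt_ratio"] == pytest.approx(3.0, rel=1e-3)
        assert not bad["assumptions_ok"]

    def test_degenerate_reference_rejected(self, sch60):
        zero = TimeActivityCurve(sch60, np.zeros(42))
        with pytest.raises(ValueError):
            fit_srtm(zero, zero)


class TestParamValidation:
    def test_srtm_params(self):
        with pytest.raises(ValueError):
            SRTMParams(R1=0.0, k2=0.1, BPND=0.0)
        assert SRTMParams(1.0, 0.2, 0.5).k2a == pytest.approx(0.2 / 1.5)

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            FitOptions(bounds={"K1": (1.0, 0.5)})
        with pytest.raises(ValueError):
            FitOptions(multistart_count=0)
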