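import numpy as np
import pytest

from petkin.core import FrameSchedule, RoiMask, TimeActivityCurve, VoxelGrid4D
from petkin.input_function import (InputFunction, ParentFraction,
                                   PlasmaBloodRatio, apply_parent_fraction,
                                   apply_pbr, build_input_function, derive_idif,
                                   evaluate_input, feng_input, fet_pbr_table)


def blood_tac(value=1.0, n=6):
    sch = FrameSchedule.from_durations([10.0] * n)
    return TimeActivityCurve(sch, np.full(n, float(value)), roi_label="vena_cava")


class TestPlasmaBloodRatio:
    def test_constant_166(self):
        plasma = apply_pbr(blood_tac(1.0), PlasmaBloodRatio("constant", 1.66))
        assert plasma.values == pytest.approx(np.full(6, 1.66))

    @pytest.mark.parametrize("t,expected", [(40.0, 1.3), (20.0, 1.1),
                                            (1.0, 1.1), (55.0, 1.4)])
    def test_fet_table(self, t, expected):
        assert fet_pbr_table().ratio_at(t) == pytest.approx(expected)

    def test_constant_extrapolation_beyond_ends(self):
        pbr = fet_pbr_table()
        assert pbr.ratio_at(0.1) == pytest.approx(1.1)
        assert pbr.ratio_at(90.0) == pytest.approx(1.4)

    def test_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            PlasmaBloodRatio("sampled", sample_times=[1, 2], sample_ratios=[1.0, -0.5])


class TestParentFraction:
    def test_constant_identity(self):
        pf = ParentFraction("constant", {"value": 1.0})
        plasma = blood_tac(2.0)
        inp = apply_parent_fraction(plasma, pf)
        assert inp.evaluate(plasma.midpoints) == pytest.approx(plasma.values)

    def test_one_exponential_limit(self):
        pf = ParentFraction("one_exponential", {"A": 1.0, "lam": 1e-9})
        assert pf.fraction_at(np.array([0.0, 60.0])) == pytest.approx([1.0, 1.0],
                                                                      abs=1e-6)

    def test_hill_value(self):
        pf = ParentFraction("hill", {"floor": 0.8, "t50": 30.0, "n": 2.0})
        assert pf.fraction_at(30.0) == pytest.approx(0.9)

    def test_rejects_fraction_above_one(self):
        with pytest.raises(ValueError):
            ParentFraction("one_exponential", {"A": -0.5, "lam": 0.01})


class TestInputFunctionEvaluation:
    def test_linear_between_samples(self):
        inp = InputFunction([1.0, 3.0], [2.0, 4.0])
        assert evaluate_input(inp, 2.0) == pytest.approx(3.0)

    def test_anchored_at_zero(self):
        inp = InputFunction([1.0, 3.0], [2.0, 4.0])
        assert inp.evaluate(0.0) == 0.0

    def test_samples_reproduced_exactly(self):
        t = np.array([0.5, 1.0, 7.0, 30.0])
        v = np.array([5.0, 3.0, 2.0, 1.0])
        inp = InputFunction(t, v)
        np.testing.assert_allclose(inp.evaluate(t), v, rtol=1e-15)

    def test_exponential_tail_extrapolation(self):
        t = np.linspace(1.0, 40.0, 20)
        inp = InputFunction(t, np.exp(-0.1 * t))
        got = inp.evaluate(50.0)
        assert got == pytest.approx(np.exp(-0.1 * 50.0), rel=1e-6)

    def test_negative_time_rejected(self):
        inp = InputFunction([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            inp.evaluate(-0.1)

    def test_continuity_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0.1, 60, 25))
        inp = InputFunction(t, rng.uniform(0, 10, 25))
        tt = np.linspace(0, 80, 4000)
        vals = inp.evaluate(tt)
        assert np.all(vals >= 0)
        assert np.max(np.abs(np.diff(vals))) < 1.0  # no jumps on a fine grid

    def test_integral_matches_trapezoid_on_dense_grid(self):
        inp = InputFunction([0.0, 1.0, 5.0, 20.0], [0.0, 8.0, 2.0, 1.0])
        tt = np.linspace(0, 20, 200001)
        num = np.trapezoid(inp.evaluate(tt), tt)
        assert inp.integral(20.0) == pytest.approx(num, rel=1e-8)


class TestFengInput:
    def test_zero_at_origin(self, sch60):
        inp = feng_input({"A1": 800, "A2": 20, "A3": 10,
                          "lam1": 4, "lam2": 0.5, "lam3": 0.008}, sch60)
        assert inp.evaluate(0.0) == 0.0

    def test_peak_then_monotone_decay(self, inp60):
        t = np.linspace(0, 60, 2001)
        v = inp60.evaluate(t)
        assert t[np.argmax(v)] < 2.0
        late = v[t > 5.0]
        assert np.all(np.diff(late) <= 1e-9)

    def test_small_lam3_late_tail_near_A3(self, sch90):
        inp = feng_input({"A1": 800, "A2": 20, "A3": 10,
                          "lam1": 4, "lam2": 0.5, "lam3": 1e-5}, sch90)
        assert inp.evaluate(85.0) == pytest.approx(10.0, rel=1e-3)

    def test_rejects_bad_eigenvalue_order(self, sch60):
        with pytest.raises(ValueError):
            feng_input({"A1": 800, "A2": 20, "A3": 10,
                        "lam1": 0.5, "lam2": 4, "lam3": 0.008}, sch60)


class TestDeriveIdif:
    def test_two_voxel_mean(self, sch60):
        vol = np.zeros((2, 1, 1, 42))
        vol[0, 0, 0, :] = 1.0
        vol[1, 0, 0, :] = 3.0
        grid = VoxelGrid4D(vol, (0.42,) * 3, sch60)
        mask = RoiMask(np.ones((2, 1, 1), bool))
        idif = derive_idif(grid, mask)
        assert idif.roi_label == "vena_cava"
        assert idif.values == pytest.approx(np.full(42, 2.0))

    def test_checkerboard_region_means(self, sch60):
        rng = np.random.default_rng(1)
        per_frame = rng.uniform(1, 5, 42)
        vol = np.zeros((4, 4, 1, 42))
        cb = (np.add.outer(np.arange(4), np.arange(4)) % 2 == 0)[..., None]
        vol[cb] = per_frame
        vol[~cb] = 2.0 * per_frame
        grid = VoxelGrid4D(vol, (0.42,) * 3, sch60)
        idif = derive_idif(grid, RoiMask(cb))
        np.testing.assert_allclose(idif.values, per_frame, rtol=1e-12)

    def test_empty_mask_rejected(self, sch60):
        grid = VoxelGrid4D(np.zeros((2, 2, 2, 42)), (0.42,) * 3, sch60)
        with pytest.raises(ValueError):
            derive_idif(grid, RoiMask(np.zeros((2, 2, 2), bool)))


class TestCorrectionChainProperties:
    def test_commutes_with_blood_scaling(self):
        pbr = fet_pbr_table()
        pf = ParentFraction("one_exponential", {"A": 0.2, "lam": 0.01})
        b = blood_tac(2.0)
        scaled_first = build_input_function(b.with_values(3.0 * b.values), pbr, pf)
        scaled_last = build_input_function(b, pbr, pf)
        np.testing.assert_allclose(scaled_first.values, 3.0 * scaled_last.values,
                                   rtol=1e-12)

    def test_constant_chain_is_scalar_multiplication(self):
        pbr = PlasmaBloodRatio("constant", 1.66)
        pf = ParentFraction("constant", {"value": 1.0})
        rng = np.random.default_rng(5)
        sch = FrameSchedule.from_durations([5.0] * 8)
        b = TimeActivityCurve(sch, rng.uniform(1, 10, 8), roi_label="vena_cava")
        inp = build_input_function(b, pbr, pf)
        np.testing.assert_allclose(inp.evaluate(b.midpoints), 1.66 * b.values,
                                   rtol=1e-12)
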