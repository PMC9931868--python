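import dataclasses

import numpy as np
import pytest

from petkin.core import to_suv
from petkin.imaging import fit_adc, roi_mean_tac, segment_mtv
from petkin.input_function import build_input_function
from petkin.kinetic import model_2t
from petkin.simulate import (NoiseModel, default_spec, generate_dwi,
                             generate_phantom, generate_study)


class TestDefaultSpec:
    def test_rhpsma_tumor_truth(self):
        spec = default_spec("rhPSMA73", 28)
        t = spec.regions["tumor"].truth
        assert (t.K1, t.k3, t.k4) == (0.34, 0.6, 0.47)
        # k2 solved from the reported VT
        assert t.k2 == pytest.approx(0.34 * (1 + 0.6 / 0.47) / 0.24, rel=1e-12)
        assert t.VT == pytest.approx(0.24)
        assert "k2" in spec.regions["tumor"].derived_fields

    def test_fluciclovine_tumor_k4_from_vt(self):
        t = default_spec("fluciclovine", 28).regions["tumor"].truth
        assert t.k4 == pytest.approx(0.09 / (1.5 * 0.6 / 0.16 - 1), rel=1e-12)
        assert t.k4 == pytest.approx(0.019459, abs=5e-7)
        assert t.VT == pytest.approx(1.5)

    def test_fet_tumor_truth(self):
        t = default_spec("FET", 28).regions["tumor"].truth
        assert (t.K1, t.k2, t.k3) == (0.19, 0.3, 0.03)
        assert t.VT == pytest.approx(1.38)
        assert t.k4 == pytest.approx(0.03 / (1.38 * 0.3 / 0.19 - 1), rel=1e-12)

    def test_schedules_by_tracer(self):
        assert default_spec("rhPSMA73", 28).schedule.total_duration == 60.0
        assert default_spec("FET", 28).schedule.total_duration == 90.0
        assert default_spec("fluciclovine", 21).schedule.total_duration == 90.0

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError):
            default_spec("rhPSMA73", 14)

    def test_vs_macroparameters_match_report_scale(self):
        # fluciclovine tumor/brain Vs ~ 1.3 / 0.3 as printed
        spec = default_spec("fluciclovine", 28)
        assert spec.regions["tumor"].truth.Vs == pytest.approx(1.3, abs=0.07)
        assert spec.regions["brain"].truth.Vs == pytest.approx(0.33, abs=0.04)


class TestGenerateStudy:
    def test_noiseless_equals_forward_model(self):
        spec = default_spec("rhPSMA73", 28)
        spec = dataclasses.replace(spec, n_animals=1)
        st = generate_study(spec, seed=0)
        a = st.animals[0]
        truth = spec.regions["tumor"].truth
        expected = model_2t(truth, st.input_function, spec.schedule,
                            st.whole_blood).values
        np.testing.assert_allclose(a["tumor"].values, expected, rtol=1e-12)

    def test_same_seed_byte_identical(self):
        spec = default_spec("FET", 28, noise_scale=0.05, jitter_sd=0.1)
        a = generate_study(spec, seed=3)
        b = generate_study(spec, seed=3)
        for ea, eb in zip(a.animals, b.animals):
            for roi in ("tumor", "brain", "vena_cava"):
                np.testing.assert_array_equal(ea[roi].values, eb[roi].values)
        assert a.truth.equals(b.truth)

    def test_noise_is_unbiased(self):
        # CLT check: mean of noisy replicates within 3 standard errors
        spec = default_spec("fluciclovine", 28)
        clean = generate_study(spec, seed=0).animals[0]["tumor"].values
        noise = NoiseModel(0.05)
        rng = np.random.default_rng(21)
        reps = np.stack([noise.sample(clean, spec.schedule.durations, rng)
                         for _ in range(200)])
        sd = noise.scale * np.sqrt(np.maximum(clean, noise.floor)
                                   / spec.schedule.durations)
        se = sd / np.sqrt(200)
        late = spec.schedule.midpoints > 1.0   # clipping at 0 can bias tiny frames
        dev = np.abs(reps.mean(axis=0) - clean)
        assert np.all(dev[late] <= 3.0 * se[late] + 1e-12)

    def test_zero_jitter_identical_animals(self):
        spec = default_spec("FET", 28)
        spec = dataclasses.replace(spec, n_animals=3)
        st = generate_study(spec, seed=5)
        for roi in ("tumor", "brain"):
            np.testing.assert_array_equal(st.animals[0][roi].values,
                                          st.animals[1][roi].values)

    def test_truth_table_contents(self):
        st = generate_study(default_spec("rhPSMA73", 28), seed=0)
        df = st.truth
        assert set(df.region) == {"tumor", "brain"}
        assert len(df) == 2 * 6       # 6 animals at 28 days
        assert (df[df.region == "tumor"].K1 == 0.34).all()

    def test_suv_magnitudes_match_reported_ranges(self):
        # PSMA tracer: early tumor SUV ~0.8 then washout; FET accumulates ~1.5
        st = generate_study(default_spec("rhPSMA73", 28), seed=0)
        a = st.animals[0]
        suv = to_suv(a["tumor"], a["meta"])
        i2 = np.argmin(np.abs(suv.midpoints - 2.0))
        assert suv.values[i2] == pytest.approx(0.8, abs=0.25)
        assert suv.values[-1] < 0.5 * suv.values[i2]
        st = generate_study(default_spec("FET", 28), seed=0)
        a = st.animals[0]
        suv = to_suv(a["tumor"], a["meta"])
        assert suv.values[-1] == pytest.approx(1.5, abs=0.4)


class TestInversionConsistency:
    @pytest.mark.parametrize("tracer,day", [("rhPSMA73", 28), ("FET", 21)])
    def test_pipeline_inverts_generator(self, tracer, day):
        from petkin.kinetic import fit_compartment
        spec = dataclasses.replace(default_spec(tracer, day), n_animals=1)
        st = generate_study(spec, seed=0)
        a = st.animals[0]
        inp = build_input_function(a["vena_cava"], spec.pbr, spec.parent_fraction)
        for region in ("tumor", "brain"):
            truth = spec.regions[region].truth
            fit = fit_compartment(a[region], inp, a["vena_cava"], "2TCM")
            for nm in ("K1", "k2", "k3", "k4"):
                assert fit.params[nm] == pytest.approx(getattr(truth, nm),
                                                       rel=1e-3)


class TestPhantom:
    def test_region_means_match_study_tacs(self):
        spec = default_spec("rhPSMA73", 28)
        grid, masks = generate_phantom(spec, seed=0)
        st = generate_study(dataclasses.replace(spec, n_animals=1), seed=0)
        for roi in ("tumor", "brain"):
            mean_tac = roi_mean_tac(grid, masks[roi])
            np.testing.assert_allclose(mean_tac.values,
                                       st.animals[0][roi].values, rtol=1e-10)

    def test_voxel_size_and_shape(self):
        grid, masks = generate_phantom(default_spec("rhPSMA73", 28), seed=0)
        assert grid.spatial_shape == (8, 8, 8)
        assert grid.voxel_size_mm == (0.42, 0.42, 0.42)
        labels = {m.label for m in masks.values()}
        assert labels == {"tumor", "brain", "vena_cava"}

    def test_mtv50_recovers_hot_core(self, sch60):
        # two-level tumor: core at 10, rim at 4; the 50% threshold keeps core
        import numpy as np
        from petkin.core import RoiMask, VoxelGrid4D
        vol = np.zeros((4, 1, 1, sch60.n_frames))
        vol[:2] = 10.0
        vol[2:] = 4.0
        grid = VoxelGrid4D(vol, (0.42,) * 3, sch60)
        roi = RoiMask(np.ones((4, 1, 1), bool))
        res = segment_mtv(grid, roi, (0.0, 60.0), 0.50)
        assert np.array_equal(np.argwhere(res.mask.membership)[:, 0], [0, 1])


class TestDwi:
    def test_noiseless_recovery_exact(self):
        df = generate_dwi(9.15e-4, 1000.0, [0.0, 500.0, 1000.0])
        res = fit_adc(df.signal.to_numpy(), df.b_s_per_mm2.to_numpy())
        assert res.adc == pytest.approx(9.15e-4, rel=1e-12)

    def test_single_bvalue_rejected_downstream(self):
        df = generate_dwi(9.15e-4, 1000.0, [0.0])
        with pytest.raises(ValueError):
            fit_adc(df.signal.to_numpy(), df.b_s_per_mm2.to_numpy())

    def test_noisy_median_within_2pct(self):
        adcs = []
        for seed in range(500):
            df = generate_dwi(9.15e-4, 1000.0, [0.0, 250.0, 500.0, 750.0, 1000.0],
                              noise_sd=10.0, seed=seed)
            adcs.append(fit_adc(df.signal.to_numpy(),
                                df.b_s_per_mm2.to_numpy()).adc)
        assert abs(np.median(adcs) / 9.15e-4 - 1.0) < 0.02
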