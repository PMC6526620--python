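"""Flow quantification, offset assessment, cardiac-output error, Qp/Qs."""

import dataclasses

import numpy as np
import pytest

from pcflow.datamodel import InvariantError, PolygonROI
from pcflow.flow import (
    assess_vessel_offsets,
    cardiac_output_error,
    qp_qs,
    roi_mean_velocity,
    volume_flow,
)
from pcflow.roi import rasterize_roi
from pcflow.surface import OffsetSurface, evaluate_surface
from pcflow.synth import NoiseConfig, SyntheticStudyConfig, generate_study

from conftest import constant_series, square_roi


class TestRoiMeanVelocity:
    def test_uniform_field(self):
        series = constant_series(10.0)
        assert roi_mean_velocity(series, square_roi("vessel", 2, 2, 8, 8)) == 10.0

    def test_antisymmetric_halves_average_to_zero(self):
        vel = np.zeros((4, 10, 10))
        vel[:, :, :5] = 2.0
        vel[:, :, 5:] = -2.0
        series = constant_series(0.0, shape=(4, 10, 10)).with_velocity(vel)
        # ROI spanning columns 1..8: 4 columns at +2, 4 at -2
        roi = square_roi("vessel", 1, 1, 8, 8)
        assert roi_mean_velocity(series, roi) == pytest.approx(0.0, abs=1e-14)

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(6)
        vel = rng.normal(0, 5, (7, 20, 20))
        series = constant_series(0.0, shape=(7, 20, 20)).with_velocity(vel)
        roi = square_roi("vessel", 3, 4, 12, 15)
        pixels = rasterize_roi(roi, (20, 20))
        oracle_all = vel[:, pixels].sum() / (7 * pixels.sum())
        assert roi_mean_velocity(series, roi) == pytest.approx(oracle_all, abs=1e-12)
        oracle_p3 = vel[3][pixels].sum() / pixels.sum()
        assert roi_mean_velocity(series, roi, 3) == pytest.approx(oracle_p3, abs=1e-12)

    def test_empty_roi_rejected(self):
        series = constant_series(1.0)
        roi = PolygonROI([(3.2, 3.2), (3.2, 3.6), (3.6, 3.4)], "vessel")
        with pytest.warns(UserWarning):
            with pytest.raises(InvariantError, match="empty"):
                roi_mean_velocity(series, roi)


class TestVolumeFlow:
    def test_constant_velocity_arithmetic(self):
        # 10 cm/s over exactly 5 cm^2 at 60 bpm -> CO 3.0 l/min
        # 1 mm pixels: 0.01 cm^2 each; 20x25 pixel centers = 500 pixels
        series = constant_series(10.0, shape=(8, 40, 40), spacing=1.0)
        roi = square_roi("vessel", 5, 5, 24, 29)  # spans 20 x 25 centers
        result = volume_flow(series, roi)
        assert result.roi_area[0] == pytest.approx(5.0, abs=1e-12)
        np.testing.assert_allclose(result.per_phase_flow, 50.0, atol=1e-10)
        assert result.stroke_volume == pytest.approx(50.0, abs=1e-9)
        assert result.cardiac_output == pytest.approx(3.0, abs=1e-10)

    def test_zero_velocity_gives_zero_flow(self):
        result = volume_flow(constant_series(0.0), square_roi("vessel", 2, 2, 10, 10))
        assert result.stroke_volume == 0.0
        assert result.cardiac_output == 0.0

    def test_flow_sign_flips_reported_flow(self):
        series = constant_series(10.0, flow_sign=-1)
        result = volume_flow(series, square_roi("vessel", 2, 2, 10, 10))
        assert result.per_phase_mean_velocity[0] == -10.0
        assert result.cardiac_output < 0

    def test_pulsatile_stroke_volume_matches_waveform_integral(self):
        cfg = SyntheticStudyConfig(
            noise=NoiseConfig(tissue=0.0, vessel=0.0, air=0.0), seed=0
        )
        study, truth = generate_study(cfg)
        result = volume_flow(study.in_vivo, study.roi("vessel"))
        assert result.stroke_volume == pytest.approx(
            truth.true_stroke_volume, rel=0.01
        )
        assert result.cardiac_output == pytest.approx(
            truth.true_cardiac_output, rel=0.01
        )

    def test_constant_offset_changes_output_linearly(self):
        rng = np.random.default_rng(15)
        vel = rng.normal(0, 3, (6, 30, 30))
        series = constant_series(0.0, shape=(6, 30, 30)).with_velocity(vel)
        roi = square_roi("vessel", 4, 4, 20, 20)
        base = volume_flow(series, roi)
        pixels = rasterize_roi(roi, (30, 30))
        c = 0.83
        shifted = vel.copy()
        shifted[:, pixels] += c
        bumped = volume_flow(series.with_velocity(shifted), roi)
        area = base.mean_roi_area
        rr = 60.0 / series.heart_rate
        expected_delta = c * area * rr * series.heart_rate / 1000.0
        assert bumped.cardiac_output - base.cardiac_output == pytest.approx(
            expected_delta, abs=1e-9
        )


def _uniform_phantom_study(phantom_value, flow_sign=1):
    from pcflow.datamodel import StudyRecord

    in_vivo = constant_series(5.0, flow_sign=flow_sign)
    phantom = constant_series(phantom_value, flow_sign=flow_sign, kind="phantom")
    rois = [square_roi("vessel", 4, 4, 12, 12), square_roi("thorax_wall", 1, 1, 3, 18)]
    return StudyRecord(in_vivo=in_vivo, phantom=phantom, rois=rois)


class TestOffsetAssessment:
    def test_surface_matching_phantom_gives_zero_residual(self):
        study = _uniform_phantom_study(1.3)
        surf = OffsetSurface(1, np.array([1.3, 0.0, 0.0]), study.in_vivo.shape, 0.0)
        a = assess_vessel_offsets(study, surf)
        assert a.v_post == pytest.approx(0.0, abs=1e-12)

    def test_positive_phantom_offset_is_positive_pre_offset(self):
        study = _uniform_phantom_study(1.0)
        surf = OffsetSurface(1, np.zeros(3), study.in_vivo.shape, 0.0)
        a = assess_vessel_offsets(study, surf)
        assert a.v_pre == pytest.approx(1.0, abs=1e-12)
        assert a.v_phantom == a.v_pre

    def test_negative_flow_sign_flips_reported_offset(self):
        study = _uniform_phantom_study(1.0, flow_sign=-1)
        surf = OffsetSurface(1, np.zeros(3), study.in_vivo.shape, 0.0)
        a = assess_vessel_offsets(study, surf)
        assert a.v_pre == pytest.approx(-1.0, abs=1e-12)

    def test_v_post_equals_independent_roi_means(self, compact_study):
        from pcflow.pipeline import analyze_study

        study, _ = compact_study
        an = analyze_study(study, orders=(1,))
        a = an.assessments[1]
        pixels = rasterize_roi(study.roi("vessel"), study.in_vivo.shape)
        field = evaluate_surface(an.surfaces[1], study.in_vivo.shape)
        sign = study.in_vivo.flow_sign
        v_ib = sign * field[pixels].mean()
        v_ph = sign * study.phantom.velocity.astype(np.float64)[:, pixels].mean()
        assert a.v_post == pytest.approx(v_ib - v_ph, abs=1e-12)


class TestCardiacOutputError:
    def test_worked_arithmetic_example(self):
        # offset 0.5 cm/s, 6 cm^2, RR = 1 s -> 3 ml extra of 60 ml -> +5%
        flow = dataclasses.replace(
            volume_flow(constant_series(10.0), square_roi("vessel", 2, 2, 8, 8)),
        )
        flow.roi_area = np.full(flow.roi_area.shape, 6.0)
        flow.stroke_volume = 60.0
        flow.heart_rate = 60.0
        assert cardiac_output_error(0.5, flow) == pytest.approx(5.0, abs=1e-12)
        assert cardiac_output_error(0.0, flow) == 0.0

    @pytest.mark.parametrize("flow_sign", [1, -1])
    def test_matches_end_to_end_recomputation_oracle(self, flow_sign):
        rng = np.random.default_rng(21)
        for _ in range(50):
            shape = (int(rng.integers(3, 10)), 24, 24)
            vel = rng.normal(1.0, 4.0, shape)
            hr = float(rng.uniform(50, 100))
            series = constant_series(
                0.0, shape=shape, heart_rate=hr, flow_sign=flow_sign
            ).with_velocity(vel)
            roi = square_roi("vessel", 4, 4, 18, 18)
            base = volume_flow(series, roi)
            offset = float(rng.normal(0, 2))  # flow-positive convention
            pixels = rasterize_roi(roi, shape[1:])
            shifted = vel.copy()
            shifted[:, pixels] += flow_sign * offset
            new = volume_flow(series.with_velocity(shifted), roi)
            oracle = 100.0 * (new.cardiac_output - base.cardiac_output) / base.cardiac_output
            assert cardiac_output_error(offset, base) == pytest.approx(oracle, abs=1e-9)

    def test_positive_offset_always_increases_output(self):
        for flow_sign in (1, -1):
            series = constant_series(8.0, flow_sign=flow_sign)
            roi = square_roi("vessel", 3, 3, 12, 12)
            flow = volume_flow(series, roi)
            assert flow_sign * flow.cardiac_output > 0
            err = cardiac_output_error(0.7, flow)
            # positive flow-convention offset inflates the reported output
            assert err * np.sign(flow.cardiac_output) > 0

    def test_zero_stroke_volume_rejected(self):
        flow = volume_flow(constant_series(0.0), square_roi("vessel", 2, 2, 8, 8))
        with pytest.raises(InvariantError, match="stroke volume"):
            cardiac_output_error(1.0, flow)


class TestQpQs:
    def test_equal_outputs_give_unity(self):
        roi = square_roi("vessel", 2, 2, 8, 8)
        f = volume_flow(constant_series(10.0), roi)
        assert qp_qs(f, f) == 1.0

    def test_ratio_arithmetic(self):
        roi = square_roi("vessel", 2, 2, 8, 8)
        f_ao = volume_flow(constant_series(10.0), roi)
        f_mpa = volume_flow(constant_series(11.0), roi)
        assert qp_qs(f_mpa, f_ao) == pytest.approx(1.1, abs=1e-12)

    def test_nonpositive_systemic_output_rejected(self):
        roi = square_roi("vessel", 2, 2, 8, 8)
        f = volume_flow(constant_series(10.0), roi)
        zero = volume_flow(constant_series(0.0), roi)
        with pytest.raises(InvariantError, match="aortic"):
            qp_qs(f, zero)

    def test_correction_pulls_shunt_free_ratio_toward_unity(self):
        """Planted offsets bias Qp/Qs away from 1; interpolation-based
        correction must bring it closer in >= 90% of seeded replicates."""
        import dataclasses as dc

        from pcflow.datamodel import CorrectionConfig
        from pcflow.mask import build_stationary_mask
        from pcflow.surface import correct_series, fit_offset_surface, time_averaged_velocity
        from pcflow.synth import VesselWaveform, compact_config

        rng = np.random.default_rng(314)
        config_cc = CorrectionConfig()
        improved = 0
        n_rep = 100
        for rep in range(n_rep):
            sv = float(rng.normal(80, 10))
            flows = {}
            for vessel, sysfrac in (("MPA", 0.48), ("aorta", 0.40)):
                coef = (float(rng.normal(0, 1.5)), float(rng.normal(0, 0.8)),
                        float(rng.normal(0, 0.8)))
                cfg = compact_config(
                    seed=int(rng.integers(0, 2**31 - 1)),
                    offset_order=1,
                    offset_coefficients=coef,
                    vessel_label=vessel,
                )
                area = np.pi * (cfg.layout.vessel_radius_cm**2)
                rr = 60.0 / cfg.heart_rate
                wf = VesselWaveform(systole_fraction=sysfrac).with_stroke_volume(
                    sv, area, rr
                )
                # shunt-free: match the *sampled* stroke volumes exactly, so
                # the clean series of both vessels carry identical flow
                sampled_sv = area * wf.sample(cfg.n_phases, rr).sum() * rr / cfg.n_phases
                k = sv / sampled_sv
                wf = dc.replace(wf, peak=wf.peak * k, diastolic=wf.diastolic * k)
                cfg = dc.replace(cfg, waveform=wf)
                study, _ = generate_study(cfg)
                roi = study.roi("vessel")
                pre = volume_flow(study.in_vivo, roi)
                mask = build_stationary_mask(study.in_vivo, [], config_cc)
                surf = fit_offset_surface(
                    time_averaged_velocity(study.in_vivo), mask, 1
                )
                post = volume_flow(correct_series(study.in_vivo, surf), roi)
                flows[vessel] = (pre, post)
            ratio_pre = qp_qs(flows["MPA"][0], flows["aorta"][0])
            ratio_post = qp_qs(flows["MPA"][1], flows["aorta"][1])
            if abs(ratio_post - 1.0) < abs(ratio_pre - 1.0):
                improved += 1
        assert improved >= 0.90 * n_rep
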