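"""Motion model and registration tests.

Parameter-recovery checks compare the estimated model against the
simulator's ground-truth traces after removing the single unobservable
global offset (the registration gauge).
"""

import numpy as np
import pytest

from octfuse import motion, simkit
from octfuse.motion import (CorrectedSamples, DisplacementModel,
                            MotionEstimationError, MotionOptions, correct,
                            estimate_motion, model_from_trace,
                            pairwise_disagreement)
from octfuse.simkit import MotionParams, MotionTrace

from conftest import small_protocol, textured_config

FAST_OPTS = MotionOptions(pyramid_factors=(4, 2), ctrl_bscans=(4, 2),
                          outer_passes=(3, 2), maxiter=(40, 20),
                          obj_stride=((1, 1), (1, 1)))


def gauge_aligned_errors(model, volumes, traces):
    """3D error between -model and the true traces, gauge offset removed."""
    est, tru = [], []
    for vol, tr in zip(volumes, traces):
        t = vol.timestamps().ravel()[::7]
        est.append(-model.evaluate(vol.volume_index, t))
        tru.append(tr.evaluate(t))
    est, tru = np.concatenate(est), np.concatenate(tru)
    off = (tru - est).mean(axis=0)
    return np.linalg.norm(est + off - tru, axis=1)


@pytest.fixture(scope="module")
def drifted_set():
    """Textured phantom, two orthogonal volumes with drift-only motion."""
    proto = small_protocol(96, 2, duration=0.6)
    phantom = simkit.make_phantom(textured_config(96, 200, 12, seed=42))
    traces = [simkit.simulate_motion(
        proto.volume_duration_s + 0.05,
        MotionParams(10.0, 5.0, 0.0, seed=10 + v),
        t0=proto.volume_start_s(v) - 0.02) for v in range(2)]
    vols = simkit.acquire(phantom, proto, traces, speckle_contrast=0.2,
                          detector_noise_sd=0.005, seed=5)
    return phantom, proto, traces, vols


class TestEvaluate:
    def test_zero_model_evaluates_to_zero(self, static_pair):
        model = DisplacementModel.zero(static_pair)
        t = static_pair[0].timestamps().ravel()
        assert np.all(model.evaluate(0, t) == 0.0)

    def test_linear_model_exact_at_nodes_and_midpoints(self, static_pair):
        t1 = float(static_pair[0].timestamps().max())
        tr = MotionTrace(np.array([0.0, 0.5, 1.0]) * t1,
                         np.array([[0, 0, 0], [10, -4, 2], [6, 8, -2]],
                                  float),
                         np.empty(0), np.empty((0, 3)))
        model = model_from_trace([tr, tr], static_pair)
        for tq, want in [(0.5 * t1, [10, -4, 2]),
                         (0.25 * t1, [5, -2, 1]),     # midpoint = mean
                         (0.75 * t1, [8, 2, 0])]:
            got = -model.evaluate(0, tq)
            assert got == pytest.approx(want, abs=1e-6)

    def test_time_outside_span_rejected(self, static_pair):
        model = DisplacementModel.zero(static_pair)
        with pytest.raises(ValueError, match="span"):
            model.evaluate(0, 1e6)

    def test_model_json_round_trip(self, static_pair, tmp_path):
        model = DisplacementModel.zero(static_pair)
        model.save(tmp_path / "m.json")
        back = DisplacementModel.load(tmp_path / "m.json")
        sp, sp2 = model.splines[0], back.splines[0]
        assert np.array_equal(sp.knots, sp2.knots)
        assert np.array_equal(sp.coeffs, sp2.coeffs)


class TestCorrect:
    def test_zero_model_keeps_nominal_positions(self, static_pair):
        vol = static_pair[0]
        cs = correct(vol, DisplacementModel.zero(static_pair))
        x, y = vol.ascan_xy_um()
        assert np.allclose(cs.xy_um[:, 0], x.ravel())
        assert np.allclose(cs.xy_um[:, 1], y.ravel())
        assert np.allclose(cs.dz_um, 0.0)

    def test_constant_model_shifts_by_minus_displacement(self, static_pair):
        vol = static_pair[0]
        t1 = vol.protocol.total_duration_s + 1.0
        tr = MotionTrace(np.array([-1.0, t1]),
                         np.array([[24.0, 0.0, 0.0]] * 2),
                         np.empty(0), np.empty((0, 3)))
        # a trace of +24 um means the model (eye displacement) is -24 um;
        # correct() shifts by -evaluate = +24 um back onto the content
        model = model_from_trace([tr, tr], static_pair)
        assert model.evaluate(0, 0.0) == pytest.approx([-24, 0, 0])
        cs = correct(vol, model)
        x, _ = vol.ascan_xy_um()
        assert np.allclose(cs.xy_um[:, 0] - x.ravel(), 24.0)

    def test_masked_bscans_marked_invalid(self, static_pair):
        vol = simkit.inject_blinks(static_pair[0], [(3, 6)])
        vol.valid_bscan[3:6] = False
        cs = correct(vol, DisplacementModel.zero(static_pair))
        assert not cs.valid.reshape(64, 64)[3:6].any()
        assert cs.valid.reshape(64, 64)[6:].all()

    def test_ground_truth_correction_restores_static_geometry(self):
        """Correcting with the true trace and re-gridding reproduces the
        static acquisition within interpolation tolerance."""
        from octfuse._gridops import bin_trilinear
        proto = small_protocol(64, 1)
        phantom = simkit.make_phantom(textured_config(64, 200, 6, seed=1))
        tr = simkit.simulate_motion(proto.volume_duration_s + 0.05,
                                    MotionParams(12.0, 6.0, 0.0, seed=2),
                                    t0=-0.02)
        moved = simkit.acquire(phantom, proto, [tr])[0]
        static = simkit.acquire(phantom, proto, None)[0]
        cs = correct(moved, model_from_trace([tr], [moved]))
        nz, n = moved.nz, 64
        cz = (np.arange(nz)[:, None] * 2.0 + cs.dz_um[None, :]) / 2.0
        cy = np.broadcast_to((cs.xy_um[:, 1] / 12.0)[None, :], cz.shape)
        cx = np.broadcast_to((cs.xy_um[:, 0] / 12.0)[None, :], cz.shape)
        W, WI = bin_trilinear(cz, cy, cx, cs.columns, (nz, n, n))
        I = np.divide(WI, W, out=np.zeros_like(WI), where=W > 0.2)
        I = I.reshape(nz, n, n)
        sel = (W.reshape(nz, n, n) > 0.2)
        err = np.abs(I - static.grid)[sel]
        raw_err = np.abs(moved.grid - static.grid)[sel]
        # double interpolation leaves a small residual at sharp layers,
        # but the bulk of the motion distortion must be gone
        assert err.mean() < 0.02
        assert np.quantile(err, 0.9) < 0.05
        assert err.mean() < 0.5 * raw_err.mean()


class TestEstimateMotion:
    def test_static_volumes_give_near_zero_displacement(self, textured_pair):
        model = estimate_motion(textured_pair, FAST_OPTS)
        for v in range(2):
            t = textured_pair[v].timestamps().ravel()[::31]
            d = model.evaluate(v, t)
            assert np.abs(d).max() <= 1.0   # um

    def test_drift_recovery_within_tolerance(self, drifted_set):
        _, _, traces, vols = drifted_set
        model = estimate_motion(vols, FAST_OPTS)
        err = gauge_aligned_errors(model, vols, traces)
        assert np.median(err) <= 6.0

    def test_objective_non_increasing_across_stages(self, drifted_set):
        _, _, _, vols = drifted_set
        model = estimate_motion(vols, FAST_OPTS)
        obj = model.diagnostics["stage_objectives"]
        assert all(b <= a * 1.02 + 1e-9 for a, b in zip(obj, obj[1:]))
        assert obj[-1] < obj[0]

    def test_gauge_mean_displacement_is_zero(self, drifted_set):
        _, _, _, vols = drifted_set
        model = estimate_motion(vols, FAST_OPTS)
        mean = np.mean([sp.coeffs.mean(axis=0)
                        for sp in model.splines.values()], axis=0)
        assert np.abs(mean).max() < 1e-9

    def test_fewer_than_two_volumes_rejected(self, textured_pair):
        with pytest.raises(MotionEstimationError):
            estimate_motion(textured_pair[:1], FAST_OPTS)

    def test_single_direction_rejected(self, textured_phantom):
        proto = small_protocol(96, 2, duration=0.6)
        vols = simkit.acquire(textured_phantom, proto, None, seed=1)
        vols[1].direction = vols[0].direction
        with pytest.raises(MotionEstimationError, match="direction"):
            estimate_motion(vols, FAST_OPTS)

    def test_error_degrades_gracefully_with_speckle(self):
        """Recovery error is monotonically non-decreasing (within noise)
        as speckle contrast grows."""
        proto = small_protocol(64, 2)
        phantom = simkit.make_phantom(textured_config(64, 200, 8, seed=7))
        traces = [simkit.simulate_motion(
            proto.volume_duration_s + 0.05,
            MotionParams(10.0, 5.0, 0.0, seed=20 + v),
            t0=proto.volume_start_s(v) - 0.02) for v in range(2)]
        meds = []
        for c in (0.0, 0.25, 0.5):
            vols = simkit.acquire(phantom, proto, traces,
                                  speckle_contrast=c, seed=5)
            model = estimate_motion(vols, FAST_OPTS)
            meds.append(np.median(gauge_aligned_errors(model, vols, traces)))
        assert meds[2] >= meds[0] - 1.0


class TestSaccadeCorrection:
    def test_saccade_discontinuity_removed(self):
        """A 60 um mid-volume saccade splits the en face image by 5 voxels;
        after estimation and correction the split-half offset is < 1."""
        from octfuse._gridops import bin_trilinear
        from skimage.registration import phase_cross_correlation as pcc
        n = 96
        proto = small_protocol(n, 4, duration=0.6)
        phantom = simkit.make_phantom(textured_config(n, 200, 16, seed=42,
                                                      undulation_amp_um=20.0))
        t_sac = proto.volume_start_s(0) + proto.volume_duration_s / 2
        traces = []
        for v in range(4):
            t0v = proto.volume_start_s(v) - 0.02
            t1v = t0v + proto.volume_duration_s + 0.05
            traces.append(MotionTrace(
                np.array([t0v, t1v]), np.zeros((2, 3)),
                np.array([t_sac]) if v == 0 else np.empty(0),
                np.array([[60.0, 0.0, 0.0]]) if v == 0 else np.empty((0, 3))))
        vols = simkit.acquire(phantom, proto, traces, speckle_contrast=0.2,
                              seed=5)
        static = simkit.acquire(phantom, proto, None, seed=5)[0]
        ref_ef = static.grid.mean(axis=0)

        def split_offset(ef):
            o1, _, _ = pcc(ref_ef[:n // 2], ef[:n // 2], upsample_factor=20,
                           normalization=None)
            o2, _, _ = pcc(ref_ef[n // 2:], ef[n // 2:], upsample_factor=20,
                           normalization=None)
            return float(np.hypot(*(o1 - o2)))

        before = split_offset(vols[0].grid.mean(axis=0))
        assert before >= 4.0
        model = estimate_motion(vols)
        cs = correct(vols[0], model)
        nz = vols[0].nz
        cz = (np.arange(nz)[:, None] * 2.0 + cs.dz_um[None, :]) / 2.0
        cy = np.broadcast_to((cs.xy_um[:, 1] / 12.0)[None, :], cz.shape)
        cx = np.broadcast_to((cs.xy_um[:, 0] / 12.0)[None, :], cz.shape)
        W, WI = bin_trilinear(cz, cy, cx, cs.columns, (nz, n, n))
        I = np.divide(WI, W, out=np.zeros_like(WI), where=W > 1e-3)
        after = split_offset(I.reshape(nz, n, n).mean(axis=0))
        assert after <= 1.0


class TestPairwiseDisagreement:
    def test_truth_model_minimizes_disagreement(self, drifted_set):
        _, _, traces, vols = drifted_set
        zero = DisplacementModel.zero(vols)
        truth = model_from_trace(traces, vols)
        assert pairwise_disagreement(vols, truth) < \
            pairwise_disagreement(vols, zero)

    def test_gauge_invariance_of_objective(self, drifted_set):
        """A constant 3D offset common to all volumes is unobservable: it
        changes the registration objective far less than the same offset
        applied to a single volume (residual variation comes only from
        grid-edge and re-binning discretization)."""
        import copy
        _, _, traces, vols = drifted_set
        truth = model_from_trace(traces, vols)
        base = pairwise_disagreement(vols, truth)
        offset = np.array([7.0, -4.0, 2.0])
        common = copy.deepcopy(truth)
        for sp in common.splines.values():
            sp.coeffs = sp.coeffs + offset
        single = copy.deepcopy(truth)
        single.splines[0].coeffs = single.splines[0].coeffs + offset
        d_common = abs(pairwise_disagreement(vols, common) - base)
        d_single = abs(pairwise_disagreement(vols, single) - base)
        assert d_common < 0.1 * base + 1e-6
        assert d_common < 0.2 * d_single
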