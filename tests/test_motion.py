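import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bevroi.apertures import Aperture, ImagingPlan, PlanEntry, open_field_aperture
from bevroi.motion import (
    DeliveryConfig,
    DeliveryRecord,
    CouchShift,
    couch_to_room,
    derive_couch_shift,
    evaluate_errors,
    make_motion_trace,
    simulate_delivery,
    simulate_epid_image,
)
from bevroi.projection import BeamGeometry, bev_displacement_of_offset, compute_drr, _rz


angles = st.floats(0.0, 360.0, allow_nan=False)
mm = st.floats(-5.0, 5.0, allow_nan=False)


class TestDeriveCouchShift:
    def test_zero_displacement(self):
        assert derive_couch_shift((0.0, 0.0), 123.0, 45.0).as_array().tolist() == [
            0.0,
            0.0,
            0.0,
        ]

    def test_hand_evaluated_cases(self):
        cs = derive_couch_shift((1.5, 1.5), 0.0, 0.0)
        assert np.allclose(cs.as_array(), [1.5, 1.5, 0.0])
        cs = derive_couch_shift((2.0, 1.0), 90.0, 0.0)
        assert np.allclose(cs.as_array(), [0.0, 1.0, 2.0], atol=1e-12)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(dx=mm, dy=mm, theta=angles, phi=angles)
    def test_norm_preservation(self, dx, dy, theta, phi):
        cs = derive_couch_shift((dx, dy), theta, phi)
        assert np.isclose(cs.norm, np.hypot(dx, dy), rtol=1e-12, atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        t=st.tuples(mm, mm, mm), theta=angles, phi=angles
    )
    def test_round_trip_is_projection(self, t, theta, phi):
        """Project a couch offset into the BEV and back: exactly the
        component of the offset perpendicular to the beam."""
        geo = BeamGeometry(theta, phi)
        t_room = couch_to_room(t, phi)
        d = bev_displacement_of_offset(geo, t_room)
        got = derive_couch_shift(d, theta, phi).as_array()
        _, _, _, b = geo.axes()
        expected = _rz(-geo.couch_iec_deg) @ (t_room - (t_room @ b) * b)
        assert np.all(np.abs(got - expected) < 1e-9)


class TestMotionTrace:
    def _cps(self, n=8, couch=0.0):
        return [BeamGeometry(g, couch) for g in np.linspace(0, 350, n)]

    def test_linear_drift_endpoints(self):
        tr = make_motion_trace("linear-drift", 1.5, self._cps(10))
        assert np.allclose(tr.offsets[0], 0.0)
        assert np.allclose(tr.offsets[-1], 1.5)

    def test_sudden_shift_step(self):
        tr = make_motion_trace("sudden-shift", 1.5, self._cps(72), onset=36)
        assert np.allclose(tr.offsets[35], 0.0)
        assert np.allclose(tr.offsets[36], 1.5)
        assert np.allclose(tr.offsets[-1], 1.5)

    def test_default_onset_is_mid_first_arc(self):
        cps = self._cps(10, couch=0.0) + self._cps(6, couch=45.0)
        tr = make_motion_trace("sudden-shift", 1.0, cps)
        assert tr.onset == 5

    def test_errors(self):
        with pytest.raises(ValueError):
            make_motion_trace("linear-drift", 1.0, [])
        with pytest.raises(ValueError):
            make_motion_trace("wiggle", 1.0, self._cps(4))


class TestSimulateEPID:
    def test_null_motion_equals_reference_crop(self, mini_volume, mini_geometry):
        ap = Aperture(0, 0, 40, 40)
        epid = simulate_epid_image(mini_volume, mini_geometry, (0, 0, 0), ap, (128, 128))
        full = compute_drr(mini_volume, mini_geometry, (128, 128))
        r0, c0 = epid.metadata["crop_origin"]
        h, w = epid.pixels.shape
        assert np.allclose(epid.pixels, full.pixels[r0 : r0 + h, c0 : c0 + w])

    def test_lateral_offset_moves_bb(self, mini_volume, mini_geometry):
        from bevroi.registration import detect_bb

        epid = simulate_epid_image(
            mini_volume, mini_geometry, (1.5, 0.0, 0.0), Aperture(0, 0, 25, 25), (128, 128)
        )
        d = detect_bb(epid.pixels, 2.0, epid.pitch_mm, epid.principal_point)
        assert abs(d[0] - 1.5) < 0.15
        assert abs(d[1]) < 0.15

    def test_noise_is_seeded(self, mini_volume, mini_geometry):
        kw = dict(noise_photons=5000.0, seed=11)
        a = simulate_epid_image(
            mini_volume, mini_geometry, (0, 0, 0), Aperture(0, 0, 30, 30), (128, 128), **kw
        )
        b = simulate_epid_image(
            mini_volume, mini_geometry, (0, 0, 0), Aperture(0, 0, 30, 30), (128, 128), **kw
        )
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.std() > 0


class TestSimulateDelivery:
    def _plan(self, n=4, field=90.0):
        cps = [BeamGeometry(g, 0.0, panel_pitch_mm=1.2) for g in np.linspace(0, 270, n)]
        return ImagingPlan(
            entries=[PlanEntry(g, open_field_aperture(field), "open") for g in cps]
        )

    def test_static_phantom_bb_tracking_is_tight(self, mini_volume):
        plan = self._plan()
        trace = make_motion_trace("none", 0.0, [e.geometry for e in plan.entries])
        recs = simulate_delivery(
            mini_volume, plan, trace, "bb", DeliveryConfig(detector_px=(128, 128))
        )
        ok = [r for r in recs if r.ok]
        assert len(ok) >= 3
        for r in ok:
            assert np.all(np.abs(r.bev_mm) < 0.02)

    def test_sudden_shift_consistent_with_projection(self, mini_volume):
        # finer pitch than the other delivery tests: the check compares the
        # detected BB position against the projected couch offset
        cps = [
            BeamGeometry(g, 0.0, panel_pitch_mm=0.6) for g in np.linspace(0, 270, 4)
        ]
        plan = ImagingPlan(
            entries=[PlanEntry(g, open_field_aperture(90.0), "open") for g in cps]
        )
        trace = make_motion_trace("sudden-shift", 1.5, cps, onset=2)
        recs = simulate_delivery(
            mini_volume, plan, trace, "bb", DeliveryConfig(detector_px=(256, 256))
        )
        for r in recs[2:]:
            if not r.ok:
                continue
            t_room = couch_to_room(trace.offsets[r.index], r.geometry.couch_deg)
            expected = bev_displacement_of_offset(r.geometry, t_room)
            assert np.all(np.abs(r.bev_mm - expected) < 0.25)

    def test_method_validation(self, mini_volume):
        plan = self._plan(2)
        trace = make_motion_trace("none", 0.0, [e.geometry for e in plan.entries])
        with pytest.raises(ValueError):
            simulate_delivery(mini_volume, plan, trace, "telepathy")
        with pytest.raises(ValueError, match="reference"):
            simulate_delivery(mini_volume, plan, trace, "anatomy")


class TestEvaluateErrors:
    def _rec(self, i, bev, shift, ok=True):
        return DeliveryRecord(
            i, BeamGeometry(0.0, 0.0), np.asarray(bev, float),
            CouchShift(*shift), ok=ok,
        )

    def test_identical_lists_zero_error(self):
        recs = [self._rec(i, (0.1, 0.2), (1, 2, 3)) for i in range(5)]
        es = evaluate_errors(recs, recs)
        assert es.median_3d_mm == 0.0
        assert es.frac_2d_lt_1mm == 1.0

    def test_unit_norm_difference(self):
        a = [self._rec(0, (0, 0), (1.0, 0.0, 0.0))]
        b = [self._rec(0, (0, 0), (0.0, 0.0, 0.0))]
        assert evaluate_errors(a, b).err3d_mm[0] == pytest.approx(1.0)

    def test_uniform_noise_median(self, rng):
        """Median 3D norm of U(-0.1, 0.1) per-axis noise stays below
        0.18 mm (Monte-Carlo bound on the norm of uniform triples)."""
        n = 10_000
        noise = rng.uniform(-0.1, 0.1, (n, 3))
        a = [self._rec(i, (0, 0), tuple(noise[i])) for i in range(n)]
        b = [self._rec(i, (0, 0), (0, 0, 0)) for i in range(n)]
        assert evaluate_errors(a, b).median_3d_mm < 0.18

    def test_flagged_points_excluded_and_counted(self):
        a = [self._rec(0, (0, 0), (0, 0, 0)), self._rec(1, (0, 0), (9, 9, 9), ok=False)]
        b = [self._rec(0, (0, 0), (0, 0, 0)), self._rec(1, (0, 0), (0, 0, 0))]
        es = evaluate_errors(a, b)
        assert es.n_points == 1
        assert es.n_flagged == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_errors([], [self._rec(0, (0, 0), (0, 0, 0))])
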