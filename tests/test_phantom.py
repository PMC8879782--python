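"""Phantom anatomy, breathing signal and acquisition-simulator tests."""

import numpy as np
import pytest

from fluorovol import (
    PhantomSpec,
    breathing_signal,
    forward_project,
    ground_truth_dvf,
    make_arc,
    make_phantom,
    signal_from_spec,
    simulate_acquisition,
    true_tumor_position,
    warp_volume,
)
from fluorovol.phantom import PhantomSpecError, _motion_weight_at



def fine_spec(tumor_radius=10.0):
    """1 mm grid around a lung-embedded tumor for voxelization checks."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        spacing_mm=(1.0, 1.0, 1.0),
        body_semiaxes_mm=(31.0, 31.0, 80.0),
        lung_semiaxes_mm=(16.0, 20.0, 40.0),
        lung_center_mm=(14.0, 0.0, 5.0),
        diaphragm_apex_z_mm=-12.0,
        diaphragm_curvature_mm=200.0,
        tumor_center_mm=(14.0, 0.0, 5.0),
        tumor_radius_mm=tumor_radius,
        spine_center_y_mm=26.0,
        spine_radius_mm=4.0,
    )


class TestAnatomy:
    def test_zero_radius_tumor_gives_empty_mask(self):
        spec = fine_spec(tumor_radius=0.0)
        _, mask = make_phantom(spec)
        assert mask.sum() == 0

    def test_tumor_voxel_count_matches_sphere_volume(self):
        """Voxelized 10 mm sphere on a 1 mm grid: count within 3% of 4/3 pi r^3."""
        _, mask = make_phantom(fine_spec(tumor_radius=10.0))
        expected = 4.0 / 3.0 * np.pi * 10.0**3
        assert mask.sum() == pytest.approx(expected, rel=0.03)

    def test_clinical_grid_configurable(self):
        spec = PhantomSpec(grid_shape=(176, 228, 256), spacing_mm=(1.1, 1.1, 1.1))
        assert spec.grid_shape == (176, 228, 256)
        assert np.allclose(spec.spacing_mm, 1.1)

    def test_tumor_outside_lung_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(tumor_center_mm=(0.0, 0.0, 0.0))  # mediastinum, not lung

    def test_attenuation_ordering(self, tiny_spec):
        vol, mask = make_phantom(tiny_spec)
        lung = (vol.voxels < 0.01) & (vol.voxels > 0) & ~mask
        assert vol.voxels[mask].mean() > vol.voxels[lung].mean()


class TestBreathingSignal:
    def test_raised_cosine_closed_form(self):
        """k=1, T=4 s, no jitter: s(0)=0, s(T/2)=1, exact raised cosine."""
        sig = breathing_signal(45, 5.5, period_s=4.0, shape_exponent=1.0)
        t = sig.times_s
        np.testing.assert_allclose(sig.samples, (1 - np.cos(2 * np.pi * t / 4.0)) / 2, atol=1e-12)
        assert sig.samples[0] == 0.0
        assert sig.samples[11] == pytest.approx(1.0)  # t = T/2 = 2 s at 5.5 fps

    def test_period_in_frames(self):
        sig = breathing_signal(100, 5.5, period_s=4.0, shape_exponent=2.0)
        peaks = np.nonzero(sig.samples > 1 - 1e-9)[0]
        assert np.all(np.diff(peaks) == 22)  # 4 s x 5.5 fps

    def test_four_minutes_gives_1320_samples(self):
        assert len(breathing_signal(1320, 5.5)) == 1320

    def test_jitter_deterministic_given_seed(self):
        a = breathing_signal(200, 5.5, amplitude_jitter=0.1, seed=5)
        b = breathing_signal(200, 5.5, amplitude_jitter=0.1, seed=5)
        c = breathing_signal(200, 5.5, amplitude_jitter=0.1, seed=6)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_drift_adds_linear_term(self):
        base = breathing_signal(100, 5.5, shape_exponent=2.0)
        drifted = breathing_signal(100, 5.5, shape_exponent=2.0,
                                   drift_mm_per_min=6.0, amplitude_si_mm=12.0)
        extra = drifted.samples - base.samples
        np.testing.assert_allclose(extra, 6.0 * (base.times_s / 60.0) / 12.0, atol=1e-12)


class TestGroundTruthMotion:
    def test_zero_signal_gives_zero_field(self, tiny_spec):
        dvf = ground_truth_dvf(tiny_spec, 0.0)
        assert np.all(dvf.field == 0.0)

    def test_diaphragm_apex_displacement_equals_amplitude(self, tiny_spec):
        """At s=1 the SI displacement of the motion field at the apex is A_SI."""
        apex = np.array([tiny_spec.lung_center_mm[0], tiny_spec.lung_center_mm[1],
                         tiny_spec.diaphragm_apex_z_mm])
        w = _motion_weight_at(tiny_spec, apex)
        assert w == pytest.approx(1.0, abs=1e-9)
        # the continuous field: A * s * w * direction
        assert w * tiny_spec.amplitude_si_mm == pytest.approx(
            tiny_spec.amplitude_si_mm, abs=1e-6
        )
        # and the gridded field interpolates it to within the cell size
        dvf = ground_truth_dvf(tiny_spec, 1.0)
        assert dvf.sample_at(apex)[2] == pytest.approx(tiny_spec.amplitude_si_mm, rel=0.01)

    def test_gridded_field_matches_analytic_formula_at_voxel_centers(self, tiny_spec):
        """Each stored vector equals A * s * w(p) * (lr, ap, 1) exactly."""
        ref, _ = make_phantom(tiny_spec)
        s = 0.7
        dvf = ground_truth_dvf(tiny_spec, s)
        X, Y, Z = ref.coordinate_grids()
        pts = np.stack([X, Y, Z], axis=-1)
        g = _motion_weight_at(tiny_spec, pts)
        direction = np.array([tiny_spec.lr_fraction, tiny_spec.ap_fraction, 1.0]) \
            * tiny_spec.amplitude_si_mm
        expected = s * g[..., None] * direction
        np.testing.assert_allclose(dvf.field, expected, atol=1e-12)

    def test_tumor_center_displacement_analytic(self, tiny_spec):
        c0 = np.array(tiny_spec.tumor_center_mm)
        s = 0.7
        dvf = ground_truth_dvf(tiny_spec, s)
        w = _motion_weight_at(tiny_spec, c0)
        expected = s * w * np.array([tiny_spec.lr_fraction, tiny_spec.ap_fraction, 1.0]) \
            * tiny_spec.amplitude_si_mm
        np.testing.assert_allclose(dvf.sample_at(c0), expected, rtol=0.01)

    def test_field_zero_outside_body(self, tiny_spec):
        ref, _ = make_phantom(tiny_spec)
        dvf = ground_truth_dvf(tiny_spec, 1.0)
        outside = ref.voxels == 0.0
        # strictly outside the body ellipsoid the taper has reached zero
        X, Y, Z = ref.coordinate_grids()
        ba, bb, bc = tiny_spec.body_semiaxes_mm
        far = (X / ba) ** 2 + (Y / bb) ** 2 + (Z / bc) ** 2 > 1.0
        assert np.all(dvf.field[outside & far] == 0.0)

    def test_mass_plausibility_under_warp(self, tiny_spec):
        """Total attenuation is nearly preserved by breathing warps.

        At mid-cycle the change is well under 2%; at peak inhale the
        diaphragm's descent genuinely moves dense tissue out of the lung
        window (field divergence, not interpolation error), so only a
        slightly looser bound is physical there.
        """
        ref, _ = make_phantom(tiny_spec)
        mid = warp_volume(ref, ground_truth_dvf(tiny_spec, 0.5))
        assert abs(mid.voxels.sum() - ref.voxels.sum()) / ref.voxels.sum() < 0.02
        peak = warp_volume(ref, ground_truth_dvf(tiny_spec, 1.0))
        assert abs(peak.voxels.sum() - ref.voxels.sum()) / ref.voxels.sum() < 0.03

    def test_warped_mask_centroid_matches_true_tumor_position(self, tiny_spec):
        """Apparent tumor position agrees with the warped mask's centroid."""
        ref, mask = make_phantom(tiny_spec)
        s = 1.0
        dvf = ground_truth_dvf(tiny_spec, s)
        warped_mask = warp_volume(ref.like(mask.astype(float)), dvf)
        w = warped_mask.voxels
        X, Y, Z = ref.coordinate_grids()
        centroid = np.array([np.sum(w * X), np.sum(w * Y), np.sum(w * Z)]) / w.sum()
        predicted = true_tumor_position(tiny_spec, s)
        assert np.linalg.norm(centroid - predicted) < 0.5 * np.max(ref.spacing_mm)


class TestAcquisition:
    def test_static_signal_reproduces_reference_projections(self, tiny_spec, tiny_geom):
        n = 5
        arc = make_arc(tiny_geom, n, 5.5)
        sig = breathing_signal(n, 5.5, shape_exponent=2.0)
        sig.samples[:] = 0.0
        stack, truth = simulate_acquisition(tiny_spec, sig, tiny_geom, arc)
        ref, _ = make_phantom(tiny_spec)
        for i in range(n):
            expected = forward_project(ref, tiny_geom.at_angle(arc[0][i]))
            np.testing.assert_array_equal(stack.pixels[i], expected.pixels)
        np.testing.assert_allclose(truth, np.tile(tiny_spec.tumor_center_mm, (n, 1)))

    def test_noiseless_frame_matches_independent_recomputation(self, tiny_spec, tiny_geom):
        """Bit-for-bit agreement with a freshly composed warp+project path."""
        n = 3
        arc = make_arc(tiny_geom, n, 5.5)
        sig = signal_from_spec(tiny_spec, n, 5.5, seed=1)
        stack, _ = simulate_acquisition(tiny_spec, sig, tiny_geom, arc)
        ref, _ = make_phantom(tiny_spec)
        i = 2
        warped = warp_volume(ref, ground_truth_dvf(tiny_spec, sig.samples[i]))
        expected = forward_project(warped, tiny_geom.at_angle(arc[0][i]))
        np.testing.assert_array_equal(stack.pixels[i], expected.pixels)

    def test_deterministic_given_seed(self, tiny_spec, tiny_geom):
        n = 4
        arc = make_arc(tiny_geom, n, 5.5)
        sig = signal_from_spec(tiny_spec, n, 5.5, seed=3)
        s1, t1 = simulate_acquisition(tiny_spec, sig, tiny_geom, arc, noise_sigma=0.5, seed=9)
        s2, t2 = simulate_acquisition(tiny_spec, sig, tiny_geom, arc, noise_sigma=0.5, seed=9)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        np.testing.assert_array_equal(t1, t2)

    def test_mismatched_lengths_rejected(self, tiny_spec, tiny_geom):
        arc = make_arc(tiny_geom, 4, 5.5)
        sig = breathing_signal(5, 5.5)
        with pytest.raises(ValueError):
            simulate_acquisition(tiny_spec, sig, tiny_geom, arc)
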