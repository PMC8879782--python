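"""Per-projection coefficient estimation tests (cost, gradient, recovery)."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fluorovol import (
    DVF,
    FluoroscopicModel,
    ProjectionStack,
    build_pca_model,
    cost_and_gradient,
    estimate_frame,
    estimate_lambda,
    estimate_sequence,
    forward_project,
    ground_truth_dvf,
    motion_basis,
    reconstruct_dvf,
    render_projection,
    roi_for_angle,
    tumor_position,
    warp_volume,
)
from fluorovol.estimator import DegenerateROIError

from oracles import brute_force_lambda


@pytest.fixture(scope="module")
def setting(tiny_sim):
    """Reference volume + full-rank motion model built from known fields."""
    spec = tiny_sim["spec"]
    ref = tiny_sim["reference"]
    basis = motion_basis(spec, ref)
    basis_ap = DVF(np.zeros_like(basis.field), basis.spacing_mm, basis.origin_mm)
    basis_ap.field[..., 1] = basis.field[..., 2] * 0.5  # independent AP pattern
    rng = np.random.default_rng(77)
    smooth = np.stack(
        [gaussian_filter(rng.standard_normal(ref.shape), 2.0) for _ in range(3)], axis=-1
    )
    basis_rand = DVF(2.0 * smooth, basis.spacing_mm, basis.origin_mm)
    s_vals = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    e_vals = [0.0, 0.5, -0.3, 0.8, -0.6, 0.2]
    r_vals = [0.0, -0.2, 0.3, -0.1, 0.2, -0.3]
    dvfs = [
        DVF(s * basis.field + e * basis_ap.field + r * basis_rand.field,
            basis.spacing_mm, basis.origin_mm)
        for s, e, r in zip(s_vals, e_vals, r_vals)
    ]
    model = build_pca_model(dvfs, n_modes=3)
    return {
        "spec": spec,
        "ref": ref,
        "model": model,
        "geom": tiny_sim["geom"],
        "c0": np.array(spec.tumor_center_mm),
        "apex": np.array([spec.lung_center_mm[0], spec.lung_center_mm[1],
                          spec.diaphragm_apex_z_mm]),
    }


def _roi(setting, angle):
    geom = setting["geom"].at_angle(angle)
    return geom, roi_for_angle(geom, [setting["c0"], setting["apex"]])


class TestRender:
    def test_equals_independent_composition(self, setting):
        """render = P(warp(f0, D(u))) by two separately composed paths."""
        u = setting["model"].scores[3]
        geom = setting["geom"].at_angle(25.0)
        a = render_projection(u, setting["ref"], setting["model"], geom)
        warped = warp_volume(setting["ref"], reconstruct_dvf(setting["model"], u))
        b = forward_project(warped, geom)
        np.testing.assert_allclose(a.pixels, b.pixels, rtol=1e-6, atol=1e-12)

    def test_zero_coefficients_zero_mean_equals_reference_projection(self, setting):
        model = setting["model"]
        zero_mean_model = type(model)(
            mean=DVF(np.zeros_like(model.mean.field), model.mean.spacing_mm,
                     model.mean.origin_mm),
            modes=model.modes, eigenvalues=model.eigenvalues,
            scores=model.scores, spectrum=model.spectrum,
        )
        geom = setting["geom"].at_angle(0.0)
        a = render_projection(np.zeros(3), setting["ref"], zero_mean_model, geom)
        b = forward_project(setting["ref"], geom)
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)

    def test_rendered_correlates_with_measured(self, setting, tiny_sim):
        """On noiseless phantom data the model projection matches closely."""
        i = 40
        stack = tiny_sim["stack"]
        geom = setting["geom"].at_angle(stack.angles_deg[i])
        s = tiny_sim["signal"].samples[i]
        dvf_true = ground_truth_dvf(setting["spec"], s)
        u = setting["model"].modes.reshape(3, -1) @ (
            dvf_true.field.ravel() - setting["model"].mean.field.ravel()
        )
        rendered = render_projection(u, setting["ref"], setting["model"], geom)
        r = np.corrcoef(rendered.pixels.ravel(), stack.pixels[i].ravel())[0, 1]
        assert r >= 0.99


class TestLambda:
    def test_identical_images_give_unity(self, setting, tiny_sim):
        x = tiny_sim["stack"].frame(0)
        assert estimate_lambda(x, x) == 1.0

    def test_exact_ratio(self, setting, tiny_sim):
        x = tiny_sim["stack"].frame(0)
        scaled = 2.5 * x.pixels
        assert estimate_lambda(scaled, x.pixels) == pytest.approx(2.5, abs=1e-12)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        r = rng.standard_normal(300)
        x = rng.standard_normal(300)
        assert estimate_lambda(r, x) == pytest.approx(brute_force_lambda(r, x), abs=1e-6)

    def test_zero_measurement_rejected(self):
        with pytest.raises(DegenerateROIError):
            estimate_lambda(np.ones(10), np.zeros(10))


class TestCostGradient:
    def test_perfect_fit_has_zero_cost_and_gradient(self, setting):
        u = setting["model"].scores[2]
        geom, roi = _roi(setting, 30.0)
        x = render_projection(u, setting["ref"], setting["model"], geom)
        J, g, lam = cost_and_gradient(u, setting["ref"], setting["model"], geom, x, roi)
        scale = float(np.sum(roi.take(x.pixels) ** 2))
        assert J < 1e-12 * scale
        assert lam == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(g) < 1e-8 * scale

    def test_gradient_matches_finite_differences(self, setting, tiny_sim):
        """Analytic gradient vs central differences at random coefficients."""
        stack = tiny_sim["stack"]
        model = setting["model"]
        rng = np.random.default_rng(5)
        scale = model.score_scale()
        i = 17
        geom, roi = _roi(setting, stack.angles_deg[i])
        x = stack.frame(i)
        for _ in range(4):
            u = rng.uniform(-1, 1, 3) * scale
            J, g, _ = cost_and_gradient(u, setting["ref"], model, geom, x, roi)
            for k in range(3):
                h = 1e-5 * max(scale[k], 1.0)
                up = u.copy(); up[k] += h
                dn = u.copy(); dn[k] -= h
                Jp, _, _ = cost_and_gradient(up, setting["ref"], model, geom, x, roi)
                Jm, _, _ = cost_and_gradient(dn, setting["ref"], model, geom, x, roi)
                fd = (Jp - Jm) / (2 * h)
                assert abs(g[k] - fd) / max(abs(fd), 1e-12) < 1e-3

    def test_joint_scale_invariance(self, setting, tiny_sim):
        """Scaling x is absorbed by the closed-form lambda: J unchanged."""
        stack = tiny_sim["stack"]
        u = 0.3 * setting["model"].scores[4]
        geom, roi = _roi(setting, stack.angles_deg[8])
        x = stack.pixels[8]
        J1, g1, lam1 = cost_and_gradient(u, setting["ref"], setting["model"], geom, x, roi)
        J2, g2, lam2 = cost_and_gradient(u, setting["ref"], setting["model"], geom, 4.0 * x, roi)
        assert J2 == pytest.approx(J1, rel=1e-12)
        np.testing.assert_allclose(g2, g1, rtol=1e-9)
        assert lam2 == pytest.approx(lam1 / 4.0, rel=1e-12)


class TestEstimateFrame:
    def test_reference_frame_recovers_zero(self, setting):
        geom, roi = _roi(setting, 10.0)
        x = render_projection(np.zeros(3), setting["ref"], setting["model"], geom)
        u, vol, state = estimate_frame(x, setting["ref"], setting["model"], geom, roi,
                                       u_init=np.zeros(3))
        scale = setting["model"].score_scale()
        assert np.all(np.abs(u) < 1e-2 * scale)

    def test_inverse_crime_recovery_within_one_voxel(self, setting):
        """Frames rendered from in-span coefficients are recovered."""
        model = setting["model"]
        rng = np.random.default_rng(21)
        vox = np.max(setting["ref"].spacing_mm)
        for trial in range(3):
            u_true = rng.uniform(-0.8, 0.8, 3) * model.score_scale()
            angle = rng.uniform(-100, 100)
            geom, roi = _roi(setting, angle)
            x = render_projection(u_true, setting["ref"], model, geom)
            u, _, state = estimate_frame(x, setting["ref"], model, geom, roi,
                                         u_init=np.zeros(3), return_volume=False)
            p_est = tumor_position(reconstruct_dvf(model, u), setting["c0"])
            p_true = tumor_position(reconstruct_dvf(model, u_true), setting["c0"])
            assert abs(p_est[2] - p_true[2]) < vox

    def test_monotone_descent(self, setting, tiny_sim):
        stack = tiny_sim["stack"]
        geom, roi = _roi(setting, stack.angles_deg[50])
        _, _, state = estimate_frame(stack.frame(50), setting["ref"], setting["model"],
                                     geom, roi, return_volume=False)
        hist = np.array(state.cost_history)
        assert np.all(np.diff(hist) <= 0.0)


class TestSequence:
    def test_identical_reference_frames_give_zero_coefficients(self, setting):
        model = setting["model"]
        zero_mean_model = type(model)(
            mean=DVF(np.zeros_like(model.mean.field), model.mean.spacing_mm,
                     model.mean.origin_mm),
            modes=model.modes, eigenvalues=model.eigenvalues,
            scores=model.scores, spectrum=model.spectrum,
        )
        geom = setting["geom"]
        n = 4
        frames = np.stack(
            [forward_project(setting["ref"], geom.at_angle(a)).pixels for a in [0.0] * n]
        )
        stack = ProjectionStack(frames, geom, np.zeros(n), np.arange(n) / 5.5)
        out, _ = estimate_sequence(stack, setting["ref"], zero_mean_model,
                                   roi_landmarks_mm=[setting["c0"], setting["apex"]])
        scale = zero_mean_model.score_scale()
        assert np.all(np.abs(out["coefficients"]) < 2e-2 * scale[None, :])

    def test_output_count_matches_input(self, setting, tiny_sim):
        stack = tiny_sim["stack"].subset(np.arange(6))
        out, vols = estimate_sequence(stack, setting["ref"], setting["model"],
                                      roi_landmarks_mm=[setting["c0"], setting["apex"]],
                                      store_volumes=True)
        assert out["coefficients"].shape == (6, 3)
        assert len(vols) == 6

    def test_noise_robustness(self, setting):
        """2% Gaussian projection noise degrades SI MAE by < 1 voxel."""
        model = setting["model"]
        rng = np.random.default_rng(31)
        angles = np.linspace(-60, 60, 8)
        u_true = np.outer(np.sin(np.linspace(0, 2 * np.pi, 8)), [0.7, 0.0, 0.0]) \
            * model.score_scale()
        clean, noisy, truth_si = [], [], []
        for a, u in zip(angles, u_true):
            geom = setting["geom"].at_angle(a)
            x = render_projection(u, setting["ref"], model, geom)
            clean.append(x.pixels)
            noisy.append(x.pixels + 0.02 * x.pixels.max() * rng.standard_normal(x.pixels.shape))
            truth_si.append(tumor_position(reconstruct_dvf(model, u), setting["c0"])[2])
        maes = []
        for frames in (clean, noisy):
            stack = ProjectionStack(np.stack(frames), setting["geom"], angles,
                                    np.arange(8) / 5.5)
            out, _ = estimate_sequence(stack, setting["ref"], model,
                                       roi_landmarks_mm=[setting["c0"], setting["apex"]])
            si = [tumor_position(reconstruct_dvf(model, u), setting["c0"])[2]
                  for u in out["coefficients"]]
            maes.append(np.mean(np.abs(np.array(si) - np.array(truth_si))))
        assert maes[1] - maes[0] < np.max(setting["ref"].spacing_mm)


class TestModelSurface:
    def test_fit_returns_results_with_summary(self, setting, tiny_sim):
        stack = tiny_sim["stack"].subset(np.arange(5))
        fm = FluoroscopicModel(stack, setting["ref"], setting["model"],
                               tumor_centroid_mm=setting["c0"],
                               diaphragm_apex_mm=setting["apex"])
        res = fm.fit()
        assert res.n_frames == 5
        text = res.summary()
        assert "frames" in text and "u1" in text
        df = res.to_frame()
        assert {"u1", "u2", "u3", "lambda", "cost"} <= set(df.columns)

    def test_grid_mismatch_rejected(self, setting, tiny_sim):
        from fluorovol import Volume3D

        small = Volume3D.centered(np.zeros((8, 8, 8)), 8.0)
        with pytest.raises(ValueError):
            FluoroscopicModel(tiny_sim["stack"], small, setting["model"])
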