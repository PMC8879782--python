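"""Per-projection estimation of fluoroscopic 3D volumes.

Given a reference volume ``f0``, a PCA motion model and one measured
cone-beam projection ``x`` per time point, the estimator solves, frame by
frame,

    min_u  J(u) = || M . ( P f(D(u), f0) - lambda x ) ||^2

where ``D(u)`` is the model field at coefficients ``u``, ``f`` the
reference warped by it, ``P`` the forward projector, ``M`` a detector ROI
mask surrounding the tumor and diaphragm apex, and ``lambda`` a relative
intensity scale re-estimated in closed form at every cost evaluation
(block-coordinate treatment of the joint problem in (u, lambda); by the
envelope theorem the gradient of the lambda-minimized cost equals the
fixed-lambda gradient).  The analytic gradient is the exact derivative of
the discrete computation: the projector's matched adjoint composed with
the exact trilinear-interpolation derivative of the warp.

Optimization is plain gradient descent with Armijo backtracking, warm
started across frames; the result is a sequence of coefficient vectors
and (optionally materialized) fluoroscopic volumes.

The statsmodels-style surface is :class:`FluoroscopicModel` (construct
from data) / :class:`FluoroscopicResults` (estimates, diagnostics,
``summary()``, plotting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DVF,
    Projection2D,
    ProjectionStack,
    Volume3D,
    trilinear_gather,
    trilinear_gradient,
)
from .geometry import ConeBeamGeometry, Projector, project_point
from .motion import PCAMotionModel, reconstruct_dvf
from .registration import warp_volume

__all__ = [
    "ROIMask",
    "OptimizerState",
    "roi_for_angle",
    "render_projection",
    "estimate_lambda",
    "cost_and_gradient",
    "estimate_frame",
    "estimate_sequence",
    "FluoroscopicModel",
    "FluoroscopicResults",
]

log = logging.getLogger(__name__)


class DegenerateROIError(ValueError):
    """The measured projection vanishes inside the ROI."""


@dataclass
class ROIMask:
    """A binary detector-pixel mask, stored as flat (rows, cols) index arrays."""

    rows: np.ndarray
    cols: np.ndarray
    detector_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int).ravel()
        self.cols = np.asarray(self.cols, dtype=int).ravel()
        if self.rows.size == 0:
            raise ValueError("ROI mask is empty")
        if self.rows.size != self.cols.size:
            raise ValueError("rows/cols length mismatch")

    @classmethod
    def full(cls, geom: ConeBeamGeometry) -> "ROIMask":
        rr, cc = np.meshgrid(
            np.arange(geom.detector_rows), np.arange(geom.detector_cols), indexing="ij"
        )
        return cls(rr.ravel(), cc.ravel(), (geom.detector_rows, geom.detector_cols))

    @classmethod
    def from_bool(cls, mask: np.ndarray) -> "ROIMask":
        rr, cc = np.nonzero(mask)
        return cls(rr, cc, mask.shape)

    def as_bool(self) -> np.ndarray:
        m = np.zeros(self.detector_shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m

    def take(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.rows, self.cols]


def roi_for_angle(
    geom: ConeBeamGeometry,
    landmarks_mm,
    margin_mm: float = 30.0,
) -> ROIMask:
    """Detector rectangle around projected landmarks (tumor, diaphragm apex).

    ``margin_mm`` is at isocenter scale and is magnified onto the panel.
    The rectangle is the bounding box of all projected landmarks, padded,
    clipped to the detector.
    """
    pts = np.atleast_2d(np.asarray(landmarks_mm, dtype=np.float64))
    uv = np.atleast_2d(project_point(pts, geom))
    pad = margin_mm * geom.magnification
    u_lo, v_lo = uv.min(axis=0) - pad
    u_hi, v_hi = uv.max(axis=0) + pad
    v_mm, u_mm = geom.detector_axes_mm()
    rows = np.nonzero((v_mm >= v_lo) & (v_mm <= v_hi))[0]
    cols = np.nonzero((u_mm >= u_lo) & (u_mm <= u_hi))[0]
    if rows.size == 0 or cols.size == 0:
        raise ValueError("ROI falls outside the detector")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ROIMask(rr.ravel(), cc.ravel(), (geom.detector_rows, geom.detector_cols))


@dataclass
class OptimizerState:
    """Diagnostics of one frame's gradient-descent run."""

    u: np.ndarray
    lam: float
    cost_history: list[float] = field(default_factory=list)
    n_iterations: int = 0
    step_size: float = 0.0
    converged: bool = False


class _FrameWorkspace:
    """Cached per-frame operators: ROI projector + voxel index grid.

    The projection geometry is fixed while one frame is optimized, so the
    ray sample coordinates are computed once and reused by every cost and
    gradient evaluation.
    """

    def __init__(self, f0: Volume3D, model: PCAMotionModel, geom: ConeBeamGeometry, roi: ROIMask):
        self.f0 = f0
        self.model = model
        self.geom = geom
        self.roi = roi
        self.projector = Projector(f0, geom, pixel_index=(roi.rows, roi.cols))

        # voxels whose values the ROI rays can interpolate: only these need
        # to be warped at each cost evaluation
        shape = f0.shape
        rc = self.projector._coords
        i0 = np.floor(rc).astype(np.int64)
        corners = []
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    ci = i0[0] + di
                    cj = i0[1] + dj
                    ck = i0[2] + dk
                    ok = (
                        (ci >= 0) & (ci < shape[0])
                        & (cj >= 0) & (cj < shape[1])
                        & (ck >= 0) & (ck < shape[2])
                    )
                    corners.append(((ci * shape[1] + cj) * shape[2] + ck)[ok])
        self.needed = np.unique(np.concatenate(corners)) if corners else np.arange(0)

        base_idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
        self.base_idx = base_idx[:, self.needed]
        mean_flat = model.mean.field.reshape(-1, 3)
        modes_flat = model.modes.reshape(model.n_modes, -1, 3)
        self.mean_flat = mean_flat[self.needed]
        self.modes_flat = modes_flat[:, self.needed, :]
        self._warped_buffer = np.zeros(int(np.prod(shape)))

    def displacement(self, u: np.ndarray) -> np.ndarray:
        """Model displacement (mm) on the needed-voxel subset, (k, 3)."""
        return self.mean_flat + np.tensordot(u, self.modes_flat, axes=(0, 0))

    def warp_coords(self, u: np.ndarray) -> np.ndarray:
        d = self.displacement(u) / self.f0.spacing_mm
        return self.base_idx + d.T

    def rendered(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        coords = self.warp_coords(u)
        warped = trilinear_gather(self.f0.voxels, coords, mode="clamp")
        buf = self._warped_buffer
        buf[self.needed] = warped
        return self.projector.forward(buf.reshape(self.f0.shape)), coords


def render_projection(
    u, f0: Volume3D, model: PCAMotionModel, geom: ConeBeamGeometry
) -> Projection2D:
    """P(warp(f0, D(u))): the model-predicted projection at coefficients u."""
    warped = warp_volume(f0, reconstruct_dvf(model, u))
    proj = Projector(f0, geom)
    return proj.to_projection(proj.forward(warped.voxels))


def estimate_lambda(rendered, x, roi: ROIMask | None = None) -> float:
    """Closed-form least-squares intensity scale: argmin_l ||rendered - l x||^2_ROI."""
    r = rendered.pixels if isinstance(rendered, Projection2D) else np.asarray(rendered)
    xx = x.pixels if isinstance(x, Projection2D) else np.asarray(x)
    if roi is not None and r.ndim == 2:
        r = roi.take(r)
        xx = roi.take(xx)
    denom = float(np.dot(xx.ravel(), xx.ravel()))
    if denom == 0.0:
        raise DegenerateROIError("measured projection is zero inside the ROI")
    return float(np.dot(r.ravel(), xx.ravel())) / denom


def _cost_and_gradient_ws(ws: _FrameWorkspace, u: np.ndarray, x_roi: np.ndarray):
    rendered, coords = ws.rendered(u)
    denom = float(x_roi @ x_roi)
    if denom == 0.0:
        raise DegenerateROIError("measured projection is zero inside the ROI")
    lam = float(rendered @ x_roi) / denom
    resid = rendered - lam * x_roi
    J = float(resid @ resid)
    if not np.isfinite(J):
        raise ValueError("non-finite residual in cost evaluation")

    # exact chain rule: dJ/du_i = < P^T (2 resid), grad_f0(.)|_warp . v_i >;
    # the adjoint image is nonzero only on the needed-voxel subset, so the
    # warp derivative is evaluated only there
    back = ws.projector.adjoint(2.0 * resid).ravel()[ws.needed]
    nz = np.nonzero(back)[0]
    g_vox = trilinear_gradient(ws.f0.voxels, coords[:, nz], mode="clamp")
    g_mm = g_vox / ws.f0.spacing_mm[:, None]
    weighted = (back[nz][None, :] * g_mm).T  # (k, 3)
    grad = np.array(
        [np.sum(weighted * ws.modes_flat[i][nz]) for i in range(ws.model.n_modes)]
    )
    return J, grad, lam


def cost_and_gradient(u, f0, model, geom, x, roi: ROIMask | None = None):
    """Cost J(u) with lambda minimized in closed form, and its exact gradient.

    Returns (J, grad, lambda).  ``x`` may be a Projection2D or pixel array.
    """
    roi = roi if roi is not None else ROIMask.full(geom)
    ws = _FrameWorkspace(f0, model, geom, roi)
    xx = x.pixels if isinstance(x, Projection2D) else np.asarray(x)
    u = np.asarray(u, dtype=np.float64).ravel()
    return _cost_and_gradient_ws(ws, u, roi.take(xx))


def _descend(ws, x_roi, u0, max_iterations, tol, step0=None, armijo_c=1e-4, shrink=0.5):
    u = np.asarray(u0, dtype=np.float64).copy()
    J, g, lam = _cost_and_gradient_ws(ws, u, x_roi)
    state = OptimizerState(u=u, lam=lam, cost_history=[J])
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0.0 or J == 0.0:
        state.converged = True
        return state
    if step0 is None:
        # first step moves by ~half the first mode's training score std
        scale = ws.model.score_scale()
        ref = float(scale[0]) if scale.size and scale[0] > 0 else 1.0
        step0 = 0.5 * ref / gnorm
    step = step0
    for it in range(max_iterations):
        accepted = False
        g2 = float(g @ g)
        while step * g2 > 0:
            u_try = u - step * g
            try:
                J_try, g_try, lam_try = _cost_and_gradient_ws(ws, u_try, x_roi)
            except ValueError:
                J_try = np.inf
            if J_try <= J - armijo_c * step * g2:
                accepted = True
                break
            step *= shrink
            if step * np.sqrt(g2) < 1e-12 * (1.0 + np.linalg.norm(u)):
                break
        if not accepted:
            break
        rel_drop = (J - J_try) / max(J, 1e-300)
        u, J, g, lam = u_try, J_try, g_try, lam_try
        state.cost_history.append(J)
        state.n_iterations = it + 1
        if rel_drop < tol:
            state.converged = True
            break
        step *= 2.0  # re-expand after success; backtracking will shrink again
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            state.converged = True
            break
    else:
        log.debug("gradient descent hit the iteration cap (%d)", max_iterations)
    state.u = u
    state.lam = lam
    state.step_size = step
    return state


def estimate_frame(
    x,
    f0: Volume3D,
    model: PCAMotionModel,
    geom: ConeBeamGeometry,
    roi: ROIMask | None = None,
    u_init=None,
    max_iterations: int = 50,
    tol: float = 1e-4,
    return_volume: bool = True,
):
    """Optimize the motion-model coefficients against one measured projection.

    Returns ``(u_star, fluoroscopic_volume_or_None, OptimizerState)``.
    Deterministic given inputs; non-convergence at the iteration cap
    returns the best-so-far coefficients with ``converged=False``.
    """
    roi = roi if roi is not None else ROIMask.full(geom)
    ws = _FrameWorkspace(f0, model, geom, roi)
    xx = x.pixels if isinstance(x, Projection2D) else np.asarray(x)
    u0 = np.zeros(model.n_modes) if u_init is None else np.asarray(u_init, dtype=np.float64)
    state = _descend(ws, roi.take(xx), u0, max_iterations, tol)
    vol = warp_volume(f0, reconstruct_dvf(model, state.u)) if return_volume else None
    return state.u, vol, state


def estimate_sequence(
    stack: ProjectionStack,
    f0: Volume3D,
    model: PCAMotionModel,
    roi_landmarks_mm=None,
    roi_margin_mm: float = 30.0,
    max_iterations: int = 50,
    tol: float = 1e-4,
    store_volumes: bool = False,
):
    """Frame-by-frame estimation over a projection stack with warm starts.

    ``roi_landmarks_mm``: world points (e.g. reference tumor centroid and
    diaphragm apex) whose per-angle projections define the ROI rectangle;
    ``None`` uses the whole detector.  Returns a dict of per-frame arrays
    (coefficients, lambda, cost, iterations, converged) and, optionally,
    the list of fluoroscopic volumes.
    """
    n = len(stack)
    coeffs = np.zeros((n, model.n_modes))
    lams = np.zeros(n)
    costs = np.zeros(n)
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    failed = np.zeros(n, dtype=bool)
    volumes = [] if store_volumes else None

    u_prev = np.zeros(model.n_modes)
    for i in range(n):
        geom_i = stack.geometry.at_angle(stack.angles_deg[i])
        if roi_landmarks_mm is None:
            roi = ROIMask.full(geom_i)
        else:
            roi = roi_for_angle(geom_i, roi_landmarks_mm, roi_margin_mm)
        try:
            ws = _FrameWorkspace(f0, model, geom_i, roi)
            state = _descend(ws, roi.take(stack.pixels[i]), u_prev, max_iterations, tol)
        except (ValueError, DegenerateROIError) as exc:  # mark and continue
            log.warning("frame %d failed: %s", i, exc)
            failed[i] = True
            coeffs[i] = u_prev
            continue
        coeffs[i] = state.u
        lams[i] = state.lam
        costs[i] = state.cost_history[-1]
        iters[i] = state.n_iterations
        converged[i] = state.converged
        u_prev = state.u
        if store_volumes:
            volumes.append(warp_volume(f0, reconstruct_dvf(model, state.u)))
    out = {
        "coefficients": coeffs,
        "lambda": lams,
        "cost": costs,
        "iterations": iters,
        "converged": converged,
        "failed": failed,
    }
    return (out, volumes) if store_volumes else (out, None)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class FluoroscopicModel:
    """Fluoroscopic 3D estimation model bound to one dataset.

    Parameters
    ----------
    stack : ProjectionStack
        Measured projections with per-frame gantry angles.
    reference : Volume3D
        The 4D-CBCT reference phase f0 (typically peak-exhale).
    motion_model : PCAMotionModel
        Eigenmode model built from the registered phase DVFs.
    tumor_centroid_mm : 3-vector, optional
        Reference tumor centroid; enables the per-frame tumor trace.
    diaphragm_apex_mm : 3-vector, optional
        Second ROI landmark.
    roi_margin_mm : float
        ROI padding at isocenter scale (default 30 mm); ``use_roi=False``
        fits against the whole detector.
    """

    def __init__(
        self,
        stack: ProjectionStack,
        reference: Volume3D,
        motion_model: PCAMotionModel,
        tumor_centroid_mm=None,
        diaphragm_apex_mm=None,
        roi_margin_mm: float = 30.0,
        use_roi: bool = True,
        max_iterations: int = 50,
        tol: float = 1e-4,
    ):
        if motion_model.grid_shape != reference.shape:
            raise ValueError("motion model grid does not match the reference volume")
        self.stack = stack
        self.reference = reference
        self.motion_model = motion_model
        self.tumor_centroid_mm = (
            None if tumor_centroid_mm is None else np.asarray(tumor_centroid_mm, float)
        )
        self.diaphragm_apex_mm = (
            None if diaphragm_apex_mm is None else np.asarray(diaphragm_apex_mm, float)
        )
        self.roi_margin_mm = roi_margin_mm
        self.use_roi = use_roi
        self.max_iterations = max_iterations
        self.tol = tol

    def _landmarks(self):
        if not self.use_roi:
            return None
        pts = [p for p in (self.tumor_centroid_mm, self.diaphragm_apex_mm) if p is not None]
        return np.array(pts) if pts else None

    def fit(self, store_volumes: bool = False) -> "FluoroscopicResults":
        per_frame, volumes = estimate_sequence(
            self.stack,
            self.reference,
            self.motion_model,
            roi_landmarks_mm=self._landmarks(),
            roi_margin_mm=self.roi_margin_mm,
            max_iterations=self.max_iterations,
            tol=self.tol,
            store_volumes=store_volumes,
        )
        return FluoroscopicResults(self, per_frame, volumes)


class FluoroscopicResults:
    """Per-frame coefficient estimates and diagnostics of a fitted model."""

    def __init__(self, model: FluoroscopicModel, per_frame: dict, volumes=None):
        self.model = model
        self.coefficients = per_frame["coefficients"]
        self.lambdas = per_frame["lambda"]
        self.costs = per_frame["cost"]
        self.iterations = per_frame["iterations"]
        self.converged = per_frame["converged"]
        self.failed = per_frame["failed"]
        self.volumes = volumes

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[0]

    def dvf(self, i: int) -> DVF:
        return reconstruct_dvf(self.model.motion_model, self.coefficients[i])

    def fluoroscopic_volume(self, i: int) -> Volume3D:
        if self.volumes is not None:
            return self.volumes[i]
        return warp_volume(self.model.reference, self.dvf(i))

    def tumor_positions(self) -> np.ndarray:
        """Per-frame tumor centroid (mm), via the motion model's field."""
        from .evaluation import tumor_position

        c0 = self.model.tumor_centroid_mm
        if c0 is None:
            raise ValueError("model was built without a tumor centroid")
        mm = self.model.motion_model
        return np.array(
            [tumor_position(reconstruct_dvf(mm, u), c0) for u in self.coefficients]
        )

    def to_frame(self):
        """Per-frame results as a pandas DataFrame."""
        import pandas as pd

        data = {"frame": np.arange(self.n_frames)}
        data["angle_deg"] = self.model.stack.angles_deg
        data["time_s"] = self.model.stack.times_s
        for i in range(self.coefficients.shape[1]):
            data[f"u{i + 1}"] = self.coefficients[:, i]
        data["lambda"] = self.lambdas
        data["cost"] = self.costs
        data["iterations"] = self.iterations
        data["converged"] = self.converged
        data["failed"] = self.failed
        return pd.DataFrame(data)

    def evaluate(self, truth_positions_mm) -> "object":
        """SI tumor-localization errors vs ground truth (mm at isocenter)."""
        from .evaluation import detector_error_at_isocenter, mae_and_p95

        truth = np.asarray(truth_positions_mm, dtype=np.float64)
        est = self.tumor_positions()
        errors = np.empty(self.n_frames)
        for i in range(self.n_frames):
            geom_i = self.model.stack.geometry.at_angle(self.model.stack.angles_deg[i])
            truth_uv = project_point(truth[i], geom_i)
            errors[i] = detector_error_at_isocenter(est[i], truth_uv, geom_i)
        return mae_and_p95(errors)

    def summary(self) -> str:
        lines = [
            "Fluoroscopic 3D estimation results",
            "==================================",
            f"frames:            {self.n_frames}",
            f"modes:             {self.model.motion_model.n_modes}",
            f"converged frames:  {int(self.converged.sum())}",
            f"failed frames:     {int(self.failed.sum())}",
            f"mean iterations:   {self.iterations.mean():.2f}",
            f"mean lambda:       {self.lambdas.mean():.4f}",
            f"final cost (median): {np.median(self.costs):.6g}",
        ]
        scale = self.model.motion_model.score_scale()
        for i in range(self.coefficients.shape[1]):
            c = self.coefficients[:, i]
            lines.append(
                f"u{i + 1}: mean {c.mean():+.3g}  std {c.std():.3g}"
                f"  (training score std {scale[i]:.3g})"
            )
        return "\n".join(lines)

    def plot_trace(self, truth_positions_mm=None, ax=None):
        """SI tumor trace over time (optionally with ground truth)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.stack.times_s
        ax.plot(t, self.tumor_positions()[:, 2], label="estimated")
        if truth_positions_mm is not None:
            ax.plot(t, np.asarray(truth_positions_mm)[:, 2], "--", label="ground truth")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("tumor SI position (mm)")
        ax.legend()
        return ax
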