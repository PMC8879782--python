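"""Cone-beam acquisition geometry and the matched forward/back projector.

Angle convention: gantry angle 0 deg places the X-ray source on the
anterior side of the patient (world -y), rotating counter-clockwise when
viewed from superior (+z).  Detector coordinates are in mm with (0, 0) at
the principal point; the detector v axis is parallel to world +z (SI) and
u is the lateral in-plane axis.

The forward projector is ray-driven: each detector pixel's ray is sampled
at a fixed step (default ``min(spacing)/2``) and the trilinearly
interpolated attenuation is summed (midpoint rule).  The back projector is
the exact matched transpose of that discretization, so the adjoint
identity <P v, q> = <v, P^T q> holds to rounding error — a property the
cost-function gradient in :mod:`fluorovol.estimator` relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import Projection2D, Volume3D, trilinear_gather, trilinear_scatter

__all__ = [
    "ConeBeamGeometry",
    "Projector",
    "forward_project",
    "back_project",
    "project_point",
    "make_arc",
    "n_frames_for",
]

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Invalid cone-beam geometry (e.g. detector not beyond the isocenter)."""


class ProjectionUndefinedError(ValueError):
    """Point projection undefined (point at or behind the source plane)."""


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Source/flat-panel layout of a circular cone-beam scan.

    ``source_to_axis_mm`` (SAD) and ``source_to_detector_mm`` (SDD) define
    the magnification SDD/SAD > 1.  ``arc_start_deg``/``arc_span_deg``
    describe the sweep; ``gantry_angle_deg`` is this snapshot's angle.
    """

    source_to_axis_mm: float = 1000.0
    source_to_detector_mm: float = 1536.0
    detector_rows: int = 512
    detector_cols: int = 512
    detector_pixel_mm: float = 0.8
    gantry_angle_deg: float = 0.0
    arc_start_deg: float = 0.0
    arc_span_deg: float = 200.0

    def __post_init__(self) -> None:
        if self.source_to_axis_mm <= 0:
            raise GeometryError("SAD must be positive")
        if self.source_to_detector_mm <= self.source_to_axis_mm:
            raise GeometryError("SDD must exceed SAD")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise GeometryError("detector dimensions must be >= 1")
        if self.detector_pixel_mm <= 0:
            raise GeometryError("detector pixel pitch must be positive")

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_axis_mm

    def at_angle(self, angle_deg: float) -> "ConeBeamGeometry":
        return replace(self, gantry_angle_deg=float(angle_deg))

    # -- orthonormal frame -------------------------------------------------
    def source_position(self) -> np.ndarray:
        th = np.deg2rad(self.gantry_angle_deg)
        return self.source_to_axis_mm * np.array([np.sin(th), -np.cos(th), 0.0])

    def unit_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(e_d, e_u, e_v): ray direction source->isocenter, lateral, SI."""
        th = np.deg2rad(self.gantry_angle_deg)
        e_d = np.array([-np.sin(th), np.cos(th), 0.0])
        e_u = np.array([-np.cos(th), -np.sin(th), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        return e_d, e_u, e_v

    def detector_axes_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel detector coordinates (v per row, u per col) in mm."""
        v = (np.arange(self.detector_rows) - (self.detector_rows - 1) / 2.0) * self.detector_pixel_mm
        u = (np.arange(self.detector_cols) - (self.detector_cols - 1) / 2.0) * self.detector_pixel_mm
        return v, u


def project_point(p_world_mm, geom: ConeBeamGeometry) -> np.ndarray:
    """Perspective projection of world points onto the detector (u, v) in mm.

    At the isocenter plane the magnification is exactly SDD/SAD.  Raises
    :class:`ProjectionUndefinedError` for points at or behind the source.
    """
    p = np.asarray(p_world_mm, dtype=np.float64)
    src = geom.source_position()
    e_d, e_u, e_v = geom.unit_vectors()
    w = p - src
    depth = w @ e_d
    if np.any(np.asarray(depth) <= 1e-9):
        raise ProjectionUndefinedError("point at or behind the source plane")
    scale = geom.source_to_detector_mm / depth
    return np.stack([scale * (w @ e_u), scale * (w @ e_v)], axis=-1)


def n_frames_for(duration_s: float, frame_rate_hz: float) -> int:
    """Frame count of an acquisition of given duration (e.g. 240 s at 5.5 fps -> 1320)."""
    return int(round(duration_s * frame_rate_hz))


def make_arc(
    geom0: ConeBeamGeometry, n_frames: int, frame_rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced (angle_deg, time_s) pairs over the geometry's arc.

    Angles span [arc_start, arc_start + arc_span] inclusive; times are
    frame_index / frame_rate.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if geom0.arc_span_deg <= 0:
        raise ValueError("arc_span_deg must be positive")
    idx = np.arange(n_frames)
    if n_frames == 1:
        angles = np.array([geom0.arc_start_deg])
    else:
        angles = geom0.arc_start_deg + geom0.arc_span_deg * idx / (n_frames - 1)
    return angles, idx / float(frame_rate_hz)


class Projector:
    """Ray-driven projector for one (grid, geometry) pair, with cached rays.

    Caching the per-pixel sample coordinates matters in the per-frame
    optimization, where the same geometry is re-projected many times.

    Parameters
    ----------
    template : Volume3D
        Defines grid shape/spacing/origin (voxel values ignored).
    geom : ConeBeamGeometry
    pixel_index : optional (rows, cols) integer arrays
        Restrict the projector to a flat list of detector pixels (used for
        ROI-limited cost evaluation).  Default: every pixel.
    step_mm : float, optional
        Ray sampling step; default min(spacing)/2.
    """

    def __init__(self, template: Volume3D, geom: ConeBeamGeometry, pixel_index=None, step_mm=None):
        self.geom = geom
        self.grid_shape = template.shape
        self.spacing = template.spacing_mm
        self.origin = template.origin_mm
        self.step_mm = float(step_mm) if step_mm else float(np.min(self.spacing) / 2.0)

        v_mm, u_mm = geom.detector_axes_mm()
        if pixel_index is None:
            rr, cc = np.meshgrid(
                np.arange(geom.detector_rows), np.arange(geom.detector_cols), indexing="ij"
            )
            rows, cols = rr.ravel(), cc.ravel()
        else:
            rows = np.asarray(pixel_index[0], dtype=int).ravel()
            cols = np.asarray(pixel_index[1], dtype=int).ravel()
        self.rows, self.cols = rows, cols
        self.n_pixels = rows.size

        src = geom.source_position()
        e_d, e_u, e_v = geom.unit_vectors()
        targets = (
            src[None, :]
            + geom.source_to_detector_mm * e_d[None, :]
            + u_mm[cols, None] * e_u[None, :]
            + v_mm[rows, None] * e_v[None, :]
        )
        dirs = targets - src[None, :]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

        # slab intersection with the grid support (one-voxel margin for the
        # interpolation ramp beyond edge voxel centers)
        lo = self.origin - self.spacing
        hi = self.origin + self.grid_shape * self.spacing
        with np.errstate(divide="ignore"):
            inv = 1.0 / dirs
        t_lo = (lo[None, :] - src[None, :]) * inv
        t_hi = (hi[None, :] - src[None, :]) * inv
        t_near = np.nanmax(np.minimum(t_lo, t_hi), axis=1)
        t_far = np.nanmin(np.maximum(t_lo, t_hi), axis=1)
        hit = t_far > t_near
        if not np.any(hit):
            log.warning("volume entirely outside the projector field of view")
        t_near = np.where(hit, np.maximum(t_near, 0.0), 0.0)
        t_far = np.where(hit, t_far, 0.0)

        n_steps = int(np.ceil(np.max(t_far - t_near) / self.step_mm)) if np.any(hit) else 1
        n_steps = max(n_steps, 1)
        t = t_near[:, None] + (np.arange(n_steps)[None, :] + 0.5) * self.step_mm
        coords = np.empty((3, self.n_pixels * n_steps))
        for a in range(3):  # per-axis to avoid a (n_pixels, n_steps, 3) temp
            coords[a] = ((src[a] + t * dirs[:, a : a + 1] - self.origin[a]) / self.spacing[a]).ravel()
        self._coords = coords
        self._n_steps = n_steps

    def forward(self, voxels: np.ndarray) -> np.ndarray:
        """Line integrals for the selected pixels (flat array)."""
        samples = trilinear_gather(voxels, self._coords, mode="zero")
        return samples.reshape(self.n_pixels, self._n_steps).sum(axis=1) * self.step_mm

    def adjoint(self, pixel_values: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward` applied to flat pixel values."""
        vals = np.repeat(np.asarray(pixel_values, dtype=np.float64).ravel(), self._n_steps)
        return trilinear_scatter(self.grid_shape, self._coords, vals, mode="zero") * self.step_mm

    def to_projection(self, flat: np.ndarray, frame_index: int = 0, time_s: float = 0.0) -> Projection2D:
        img = np.zeros((self.geom.detector_rows, self.geom.detector_cols))
        img[self.rows, self.cols] = flat
        return Projection2D(img, self.geom, frame_index=frame_index, time_s=time_s)


def forward_project(volume: Volume3D, geom: ConeBeamGeometry, step_mm=None) -> Projection2D:
    """Project ``volume`` through ``geom``: each pixel holds the ray line integral."""
    proj = Projector(volume, geom, step_mm=step_mm)
    return proj.to_projection(proj.forward(volume.voxels))


def back_project(proj: Projection2D, grid_template: Volume3D, step_mm=None) -> Volume3D:
    """Apply the exact adjoint of :func:`forward_project` to a projection."""
    geom = proj.geometry
    if proj.pixels.shape != (geom.detector_rows, geom.detector_cols):
        raise ValueError("projection shape does not match its geometry")
    p = Projector(grid_template, geom, step_mm=step_mm)
    return grid_template.like(p.adjoint(proj.pixels.ravel()))
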