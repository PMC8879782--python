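"""Deformable digital thorax phantom and CBCT acquisition simulator.

The phantom is the package's synthetic stand-in for patient data: an
attenuation volume containing a body ellipsoid, two lungs truncated from
below by diaphragm domes, an optional vertebral column, and a spherical
tumor inside one lung.  Breathing is a single spatial displacement pattern
(SI-dominant, decaying from the diaphragm toward the lung apices) scaled
by a quasi-periodic respiratory signal, optionally with baseline drift and
cycle-to-cycle amplitude jitter.

All ground-truth displacement fields are produced directly in the
reference-sampling (pull-back) convention used by
:func:`fluorovol.registration.warp_volume`, so they are directly
comparable to registration outputs.  The recorded ground-truth tumor
positions are the *apparent* centroid locations in the warped volumes
(fixed-point inversion of the pull-back field), which is what a reader of
the simulated images would measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import DVF, ProjectionStack, Volume3D
from .geometry import ConeBeamGeometry, Projector

__all__ = [
    "PhantomSpec",
    "RespiratorySignal",
    "make_phantom",
    "breathing_signal",
    "signal_from_spec",
    "true_tumor_position",
    "motion_basis",
    "ground_truth_dvf",
    "simulate_acquisition",
    "desk_spec",
    "desk_geometry",
    "clinical_scale_spec",
    "clinical_scale_geometry",
]

log = logging.getLogger(__name__)


class PhantomSpecError(ValueError):
    """Inconsistent phantom specification (e.g. tumor outside a lung)."""


@dataclass
class PhantomSpec:
    """Geometry, tissue and motion parameters of the digital thorax.

    Lengths in mm, attenuations in relative mm^-1.  ``amplitude_si_mm`` is
    the peak-inhale SI displacement at the diaphragm apex;
    ``ap_fraction``/``lr_fraction`` scale the AP/LR components as fixed
    fractions of the SI component.  ``drift_mm_per_min`` adds a linear
    baseline shift of the whole motion pattern.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_semiaxes_mm: tuple[float, float, float] = (110.0, 85.0, 140.0)
    lung_semiaxes_mm: tuple[float, float, float] = (34.0, 55.0, 85.0)
    lung_center_mm: tuple[float, float, float] = (48.0, -5.0, 15.0)  # right lung; left mirrored
    diaphragm_apex_z_mm: float = -35.0
    diaphragm_curvature_mm: float = 60.0
    tumor_center_mm: tuple[float, float, float] = (48.0, -5.0, -10.0)
    tumor_radius_mm: float = 12.0
    mu_body: float = 0.020
    mu_lung: float = 0.004
    mu_tumor: float = 0.024
    mu_bone: float = 0.040
    include_spine: bool = True
    spine_center_y_mm: float = 58.0
    spine_radius_mm: float = 13.0
    lung_texture_amp: float = 0.0015  # vessel-like parenchymal texture (std of mu)
    body_texture_amp: float = 0.0012  # soft-tissue heterogeneity outside the lungs
    lung_texture_sigma_mm: float = 7.0
    texture_seed: int = 12345
    # motion
    amplitude_si_mm: float = 12.0
    ap_fraction: float = 0.3
    lr_fraction: float = 0.1
    decay_apex_z_mm: float | None = None  # default: superior end of the lungs
    body_taper_start: float = 0.85  # normalized body-ellipsoid radius where motion tapers
    drift_mm_per_min: float = 0.5  # slow inferior baseline shift, typical intra-fraction
    # breathing signal
    period_s: float = 4.0
    shape_exponent: float = 2.0
    amplitude_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.tumor_radius_mm < 0 or self.amplitude_si_mm < 0:
            raise PhantomSpecError("radii and amplitudes must be >= 0")
        for mu in (self.mu_body, self.mu_lung, self.mu_tumor, self.mu_bone):
            if mu < 0:
                raise PhantomSpecError("attenuations must be >= 0")
        if self.tumor_radius_mm > 0 and not self._tumor_in_lung():
            raise PhantomSpecError("tumor center must lie inside a lung, above the diaphragm")

    # -- derived geometry --------------------------------------------------
    @property
    def lung_apex_z_mm(self) -> float:
        if self.decay_apex_z_mm is not None:
            return self.decay_apex_z_mm
        return self.lung_center_mm[2] + self.lung_semiaxes_mm[2]

    def _lung_centers(self):
        cx, cy, cz = self.lung_center_mm
        return [(cx, cy, cz), (-cx, cy, cz)]

    def _dome_z(self, x, y, cx, cy):
        return self.diaphragm_apex_z_mm - ((x - cx) ** 2 + (y - cy) ** 2) / (
            2.0 * self.diaphragm_curvature_mm
        )

    def _tumor_in_lung(self) -> bool:
        tx, ty, tz = self.tumor_center_mm
        a, b, c = self.lung_semiaxes_mm
        for cx, cy, cz in self._lung_centers():
            in_ell = ((tx - cx) / a) ** 2 + ((ty - cy) / b) ** 2 + ((tz - cz) / c) ** 2 < 1.0
            if in_ell and tz > self._dome_z(tx, ty, cx, cy):
                return True
        return False


@dataclass
class RespiratorySignal:
    """A sampled breathing surrogate.

    ``samples`` are in normalized amplitude units (0 = peak-exhale,
    1 = peak-inhale before drift/jitter are added; drift can push values
    outside [0, 1]).
    """

    samples: np.ndarray
    times_s: np.ndarray
    frame_rate_hz: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.samples.shape != self.times_s.shape:
            raise ValueError("samples/times length mismatch")

    def __len__(self) -> int:
        return self.samples.size


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, np.ndarray]:
    """Build the reference (peak-exhale) attenuation volume and tumor mask.

    Voxels take the attenuation of the last structure painted over them
    (body -> lungs clipped by the diaphragm domes -> spine -> tumor); a
    voxel belongs to a structure when its *center* lies strictly inside.
    """
    shape = tuple(spec.grid_shape)
    vol = Volume3D.centered(np.zeros(shape), spec.spacing_mm)
    X, Y, Z = vol.coordinate_grids()

    ba, bb, bc = spec.body_semiaxes_mm
    body = (X / ba) ** 2 + (Y / bb) ** 2 + (Z / bc) ** 2 < 1.0
    vox = np.where(body, spec.mu_body, 0.0)

    la, lb, lc = spec.lung_semiaxes_mm
    lung_mask = np.zeros(shape, dtype=bool)
    for cx, cy, cz in spec._lung_centers():
        ell = ((X - cx) / la) ** 2 + ((Y - cy) / lb) ** 2 + ((Z - cz) / lc) ** 2 < 1.0
        above_dome = Z > spec._dome_z(X, Y, cx, cy)
        lung_mask |= ell & above_dome & body
    vox[lung_mask] = spec.mu_lung

    if spec.lung_texture_amp > 0 or spec.body_texture_amp > 0:
        # smooth random heterogeneity: vessel-like structure in the lungs,
        # mild soft-tissue variation elsewhere; it moves with the anatomy
        # (the reference is warped) and gives DIR signal inside otherwise
        # uniform regions, as real parenchyma does
        rng = np.random.default_rng(spec.texture_seed)
        noise = rng.standard_normal(shape)
        sig_vox = spec.lung_texture_sigma_mm / np.asarray(spec.spacing_mm)
        tex = gaussian_filter(noise, sigma=sig_vox)
        tex_std = tex.std()
        if tex_std > 0:
            tex /= tex_std
        vox[lung_mask] = np.maximum(vox[lung_mask] + spec.lung_texture_amp * tex[lung_mask], 0.0)
        soft = body & ~lung_mask
        vox[soft] = np.maximum(vox[soft] + spec.body_texture_amp * tex[soft], 0.0)

    if spec.include_spine and spec.mu_bone > 0:
        spine = (X**2 + (Y - spec.spine_center_y_mm) ** 2 < spec.spine_radius_mm**2) & body
        vox[spine] = spec.mu_bone

    tx, ty, tz = spec.tumor_center_mm
    tumor_mask = (X - tx) ** 2 + (Y - ty) ** 2 + (Z - tz) ** 2 < spec.tumor_radius_mm**2
    vox[tumor_mask] = spec.mu_tumor

    return vol.like(vox), tumor_mask


def breathing_signal(
    n_frames: int,
    frame_rate_hz: float,
    period_s: float = 4.0,
    shape_exponent: float = 2.0,
    amplitude_jitter: float = 0.0,
    drift_mm_per_min: float = 0.0,
    amplitude_si_mm: float = 12.0,
    seed: int | None = None,
) -> RespiratorySignal:
    """Quasi-periodic breathing surrogate s(t) = ((1 - cos 2 pi t/T)/2)^k.

    ``shape_exponent`` k > 1 lengthens the exhale plateau (typical of free
    breathing).  ``amplitude_jitter`` draws one multiplicative factor
    ~N(1, jitter) per breathing cycle (seeded); drift is expressed in mm
    per minute at the diaphragm and converted to signal units via
    ``amplitude_si_mm``.
    """
    if period_s <= 0:
        raise ValueError("period must be positive")
    t = np.arange(n_frames) / float(frame_rate_hz)
    raw = ((1.0 - np.cos(2.0 * np.pi * t / period_s)) / 2.0) ** shape_exponent
    if amplitude_jitter > 0:
        rng = np.random.default_rng(seed)
        n_cycles = int(np.floor(t[-1] / period_s)) + 1 if n_frames else 1
        factors = 1.0 + amplitude_jitter * rng.standard_normal(n_cycles)
        factors = np.clip(factors, 0.2, None)
        raw = raw * factors[np.floor(t / period_s).astype(int)]
    if drift_mm_per_min != 0.0:
        if amplitude_si_mm <= 0:
            raise ValueError("drift requires a positive SI amplitude for normalization")
        raw = raw + drift_mm_per_min * (t / 60.0) / amplitude_si_mm
    return RespiratorySignal(
        raw,
        t,
        frame_rate_hz,
        params={
            "period_s": period_s,
            "shape_exponent": shape_exponent,
            "amplitude_jitter": amplitude_jitter,
            "drift_mm_per_min": drift_mm_per_min,
            "seed": seed,
        },
    )


def signal_from_spec(spec: PhantomSpec, n_frames: int, frame_rate_hz: float, seed=None):
    """Breathing signal with the spec's period/shape/jitter/drift settings."""
    return breathing_signal(
        n_frames,
        frame_rate_hz,
        period_s=spec.period_s,
        shape_exponent=spec.shape_exponent,
        amplitude_jitter=spec.amplitude_jitter,
        drift_mm_per_min=spec.drift_mm_per_min,
        amplitude_si_mm=spec.amplitude_si_mm,
        seed=seed,
    )


def _motion_weight_at(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Scalar motion envelope g(p) at world points (..., 3): g = w(z) * taper."""
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    z_top = spec.lung_apex_z_mm
    z_dia = spec.diaphragm_apex_z_mm
    w = _smoothstep((z_top - z) / (z_top - z_dia))
    ba, bb, bc = spec.body_semiaxes_mm
    rho = np.sqrt((x / ba) ** 2 + (y / bb) ** 2 + (z / bc) ** 2)
    taper = 1.0 - _smoothstep((rho - spec.body_taper_start) / (1.0 - spec.body_taper_start))
    return w * taper


def _direction(spec: PhantomSpec) -> np.ndarray:
    # pull-back convention: +z samples superior content, i.e. anatomy
    # descends toward inferior at inhale (diaphragm contraction)
    return np.array([spec.lr_fraction, spec.ap_fraction, 1.0]) * spec.amplitude_si_mm


def motion_basis(spec: PhantomSpec, grid: Volume3D | None = None) -> DVF:
    """Unit-signal (s = 1) ground-truth displacement field on the grid."""
    if grid is None:
        grid = Volume3D.centered(np.zeros(spec.grid_shape), spec.spacing_mm)
    X, Y, Z = grid.coordinate_grids()
    pts = np.stack([X, Y, Z], axis=-1)
    g = _motion_weight_at(spec, pts)
    field = g[..., None] * _direction(spec)[None, None, None, :]
    return DVF(field, grid.spacing_mm.copy(), grid.origin_mm.copy(), provenance="ground-truth basis")


def ground_truth_dvf(spec: PhantomSpec, s: float, basis: DVF | None = None) -> DVF:
    """Pull-back displacement field at signal value ``s``."""
    if not np.isfinite(s):
        raise ValueError("signal value must be finite")
    if basis is None:
        basis = motion_basis(spec)
    return DVF(
        basis.field * float(s),
        basis.spacing_mm.copy(),
        basis.origin_mm.copy(),
        provenance=f"ground-truth s={s:g}",
    )


def true_tumor_position(spec: PhantomSpec, s: float, n_iter: int = 8) -> np.ndarray:
    """Apparent tumor-center location in the warped volume at signal ``s``.

    Solves p + d(p) = c0 for the pull-back field d by fixed-point
    iteration; for our smooth fields this converges in a few steps.
    """
    c0 = np.array(spec.tumor_center_mm, dtype=np.float64)
    direction = _direction(spec)
    p = c0.copy()
    for _ in range(n_iter):
        d = float(s) * _motion_weight_at(spec, p) * direction
        p = c0 - d
    return p


def simulate_acquisition(
    spec: PhantomSpec,
    signal: RespiratorySignal,
    geometry: ConeBeamGeometry,
    arc: tuple[np.ndarray, np.ndarray],
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[ProjectionStack, np.ndarray]:
    """Simulate the rotational CBCT acquisition of the breathing phantom.

    Frame i is the forward projection, at gantry angle ``arc[0][i]``, of
    the reference volume warped by the ground-truth field at signal value
    ``signal.samples[i]``; optional additive Gaussian noise (std
    ``noise_sigma`` in line-integral units) is seeded and reproducible.

    Returns the projection stack and the per-frame true tumor positions
    (n_frames, 3) in mm.
    """
    from .registration import warp_volume  # local import to avoid a cycle

    angles, times = arc
    angles = np.asarray(angles, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if len(signal) != angles.size or angles.size != times.size:
        raise ValueError("arc length must equal signal length")

    reference, _ = make_phantom(spec)
    basis = motion_basis(spec, reference)
    rng = np.random.default_rng(seed) if noise_sigma > 0 else None

    frames = np.empty((angles.size, geometry.detector_rows, geometry.detector_cols))
    truth = np.empty((angles.size, 3))
    for i, (ang, s) in enumerate(zip(angles, signal.samples)):
        dvf = DVF(basis.field * float(s), basis.spacing_mm, basis.origin_mm)
        warped = warp_volume(reference, dvf)
        proj = Projector(reference, geometry.at_angle(ang))
        img = proj.forward(warped.voxels).reshape(geometry.detector_rows, geometry.detector_cols)
        if rng is not None:
            img = img + noise_sigma * rng.standard_normal(img.shape)
        frames[i] = img
        truth[i] = true_tumor_position(spec, s)
    stack = ProjectionStack(frames, geometry, angles, times)
    return stack, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def desk_spec(**overrides) -> PhantomSpec:
    """Desk-scale phantom: 64^3 voxels at 4 mm (full pipeline in minutes)."""
    return PhantomSpec(**overrides)


def desk_geometry() -> ConeBeamGeometry:
    """96x96 detector at 4 mm pitch over a 200 degree arc."""
    return ConeBeamGeometry(
        detector_rows=96, detector_cols=96, detector_pixel_mm=4.0,
        arc_start_deg=-100.0, arc_span_deg=200.0,
    )


def clinical_scale_spec(**overrides) -> PhantomSpec:
    """Clinical-scale grid: 176 x 228 x 256 voxels at 1.1 mm."""
    kw = dict(grid_shape=(176, 228, 256), spacing_mm=(1.1, 1.1, 1.1))
    kw.update(overrides)
    return PhantomSpec(**kw)


def clinical_scale_geometry() -> ConeBeamGeometry:
    """512x512 detector at 0.8 mm pitch (typical kV on-board imager)."""
    return ConeBeamGeometry(
        detector_rows=512, detector_cols=512, detector_pixel_mm=0.8,
        arc_start_deg=-100.0, arc_span_deg=200.0,
    )
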