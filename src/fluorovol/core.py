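"""Core data containers and sampling primitives.

Conventions used throughout the package:

* World axes are ``x`` = left-right (LR), ``y`` = anterior-posterior (AP,
  +y posterior), ``z`` = superior-inferior (SI, +z superior).  All world
  coordinates and spacings are in millimetres.
* :class:`Volume3D` voxel arrays are indexed ``[ix, iy, iz]`` matching the
  world axis order; the world position of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing``.
* Displacement vector fields (:class:`DVF`) live on the reference grid and
  are stored in the *reference-sampling* (pull-back) convention: warping a
  volume with field ``d`` produces ``out(p) = vol(p + d(p))``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Volume3D",
    "Projection2D",
    "ProjectionStack",
    "DVF",
    "trilinear_gather",
    "trilinear_scatter",
    "trilinear_gradient",
    "read_volume",
    "write_volume",
    "read_dvf",
    "write_dvf",
    "read_projection_stack",
    "write_projection_stack",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D scalar attenuation raster with voxel spacing and world origin.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation values (relative mm^-1 units).
    spacing_mm : ndarray, shape (3,)
        Voxel pitch per world axis; strictly positive.
    origin_mm : ndarray, shape (3,)
        World coordinate of the *center* of voxel index (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(self.spacing_mm > 0):
            raise ValueError("spacing must be positive on all axes")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @classmethod
    def centered(cls, voxels: np.ndarray, spacing_mm) -> "Volume3D":
        """Build a volume whose center coincides with the world isocenter."""
        voxels = np.asarray(voxels, dtype=np.float64)
        spacing = np.asarray(spacing_mm, dtype=np.float64) * np.ones(3)
        origin = -(np.array(voxels.shape) - 1) / 2.0 * spacing
        return cls(voxels, spacing, origin)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert world coordinates (..., 3) to fractional voxel indices."""
        return (np.asarray(points_mm, dtype=np.float64) - self.origin_mm) / self.spacing_mm

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=np.float64) * self.spacing_mm

    def coordinate_grids(self):
        """World coordinate arrays (x, y, z), each of the volume's shape."""
        axes = [
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    def like(self, voxels: np.ndarray) -> "Volume3D":
        """New volume sharing this grid (spacing and origin)."""
        return Volume3D(voxels, self.spacing_mm.copy(), self.origin_mm.copy())

    def copy(self) -> "Volume3D":
        return Volume3D(self.voxels.copy(), self.spacing_mm.copy(), self.origin_mm.copy())


@dataclass
class Projection2D:
    """A flat-panel line-integral image with its acquisition geometry.

    ``pixels[row, col]``: row indexes the detector SI axis (v), col the
    lateral axis (u).  Detector coordinates are in mm with (0, 0) at the
    principal point (see :mod:`fluorovol.geometry`).
    """

    pixels: np.ndarray
    geometry: "object"  # ConeBeamGeometry; typed loosely to avoid a cycle
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection pixels must be 2D")
        g = self.geometry
        if g is not None and self.pixels.shape != (g.detector_rows, g.detector_cols):
            raise ValueError(
                f"projection shape {self.pixels.shape} does not match detector "
                f"({g.detector_rows}, {g.detector_cols})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("projection contains non-finite values")


@dataclass
class ProjectionStack:
    """A sequence of projections sharing one geometry family.

    ``pixels`` is frame-major, shape (n_frames, rows, cols); ``angles_deg``
    and ``times_s`` give the per-frame gantry angle and timestamp.
    """

    pixels: np.ndarray
    geometry: "object"
    angles_deg: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("stack pixels must be (n_frames, rows, cols)")
        n = self.pixels.shape[0]
        if self.angles_deg.shape != (n,) or self.times_s.shape != (n,):
            raise ValueError("angles/times must have one entry per frame")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    def frame(self, i: int) -> Projection2D:
        geom = dataclasses.replace(self.geometry, gantry_angle_deg=float(self.angles_deg[i]))
        return Projection2D(self.pixels[i], geom, frame_index=i, time_s=float(self.times_s[i]))

    def subset(self, indices) -> "ProjectionStack":
        indices = np.asarray(indices, dtype=int)
        return ProjectionStack(
            self.pixels[indices], self.geometry, self.angles_deg[indices], self.times_s[indices]
        )


@dataclass
class DVF:
    """A per-voxel 3-component displacement field (mm, world axes).

    ``field`` has shape (nx, ny, nz, 3) on the reference grid described by
    ``spacing_mm``/``origin_mm``.  Stored in the pull-back convention (see
    module docstring).
    """

    field: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.field.ndim != 4 or self.field.shape[-1] != 3:
            raise ValueError("DVF field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.field)):
            raise ValueError("DVF contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.field.shape[:3]  # type: ignore[return-value]

    @classmethod
    def zeros_like_volume(cls, vol: Volume3D, provenance: str = "zero") -> "DVF":
        return cls(
            np.zeros(vol.shape + (3,)), vol.spacing_mm.copy(), vol.origin_mm.copy(), provenance
        )

    def matches_grid(self, vol: Volume3D) -> bool:
        return (
            self.grid_shape == vol.shape
            and np.allclose(self.spacing_mm, vol.spacing_mm)
            and np.allclose(self.origin_mm, vol.origin_mm)
        )

    def sample_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate the field at world points (..., 3) -> (..., 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
        coords = ((pts - self.origin_mm) / self.spacing_mm).T  # (3, M)
        out = np.stack(
            [trilinear_gather(self.field[..., c], coords, mode="clamp") for c in range(3)],
            axis=-1,
        )
        return out.reshape(np.shape(points_mm))


# ---------------------------------------------------------------------------
# trilinear sampling with exact adjoint and exact derivative
#
# The three kernels below (gather / scatter / gradient) share one corner
# enumeration, so scatter is the exact transpose of gather and gradient is
# the exact derivative of the value gather computes.  A numba fast path is
# used when available (the projector samples millions of ray points per
# frame); the pure-numpy fallback is semantically identical.
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_CORNERS = [(di, dj, dk) for di in (0, 1) for dj in (0, 1) for dk in (0, 1)]


def _corner_terms(shape, coords, mode):
    """Yield (flat_index, weight, frac, base) per corner.

    ``coords``: (3, M) fractional voxel coordinates.  ``mode`` is "zero"
    (out-of-grid corners contribute nothing) or "clamp" (indices clipped to
    the boundary, weights untouched — equals nearest-edge extension).
    """
    nx, ny, nz = shape
    i0 = np.floor(coords).astype(np.int64)  # (3, M)
    f = coords - i0
    for di, dj, dk in _CORNERS:
        ci = i0[0] + di
        cj = i0[1] + dj
        ck = i0[2] + dk
        wx = f[0] if di else 1.0 - f[0]
        wy = f[1] if dj else 1.0 - f[1]
        wz = f[2] if dk else 1.0 - f[2]
        w = wx * wy * wz
        if mode == "zero":
            valid = (
                (ci >= 0) & (ci < nx) & (cj >= 0) & (cj < ny) & (ck >= 0) & (ck < nz)
            )
            w = np.where(valid, w, 0.0)
            ci = np.clip(ci, 0, nx - 1)
            cj = np.clip(cj, 0, ny - 1)
            ck = np.clip(ck, 0, nz - 1)
        elif mode == "clamp":
            ci = np.clip(ci, 0, nx - 1)
            cj = np.clip(cj, 0, ny - 1)
            ck = np.clip(ck, 0, nz - 1)
        else:  # pragma: no cover
            raise ValueError(f"unknown boundary mode {mode!r}")
        flat = (ci * ny + cj) * nz + ck
        yield flat, w, (wx, wy, wz), (di, dj, dk)


def _gather_np(vol: np.ndarray, coords: np.ndarray, mode: str) -> np.ndarray:
    flat_vol = np.ascontiguousarray(vol, dtype=np.float64).ravel()
    out = np.zeros(coords.shape[1], dtype=np.float64)
    for flat, w, _, _ in _corner_terms(vol.shape, coords, mode):
        out += w * flat_vol[flat]
    return out


def _scatter_np(shape, coords: np.ndarray, values: np.ndarray, mode: str) -> np.ndarray:
    nvox = int(np.prod(shape))
    acc = np.zeros(nvox, dtype=np.float64)
    for flat, w, _, _ in _corner_terms(shape, coords, mode):
        acc += np.bincount(flat, weights=w * values, minlength=nvox)
    return acc.reshape(shape)


def _gradient_np(vol: np.ndarray, coords: np.ndarray, mode: str) -> np.ndarray:
    flat_vol = np.ascontiguousarray(vol, dtype=np.float64).ravel()
    out = np.zeros((3,) + (coords.shape[1],), dtype=np.float64)
    for flat, w, (wx, wy, wz), (di, dj, dk) in _corner_terms(vol.shape, coords, mode):
        v = flat_vol[flat]
        sx = 1.0 if di else -1.0
        sy = 1.0 if dj else -1.0
        sz = 1.0 if dk else -1.0
        out[0] += sx * wy * wz * v
        out[1] += wx * sy * wz * v
        out[2] += wx * wy * sz * v
    return out


if _HAVE_NUMBA:

    @_njit(fastmath=False)
    def _gather_nb(vol, coords, zero_mode):  # pragma: no cover - numba
        nx, ny, nz = vol.shape
        m = coords.shape[1]
        out = np.zeros(m)
        for s in range(m):
            x, y, z = coords[0, s], coords[1, s], coords[2, s]
            i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
            fx, fy, fz = x - i0, y - j0, z - k0
            acc = 0.0
            for di in range(2):
                ii = i0 + di
                wx = fx if di else 1.0 - fx
                for dj in range(2):
                    jj = j0 + dj
                    wy = fy if dj else 1.0 - fy
                    for dk in range(2):
                        kk = k0 + dk
                        wz = fz if dk else 1.0 - fz
                        if zero_mode:
                            if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                                acc += wx * wy * wz * vol[ii, jj, kk]
                        else:
                            ic = min(max(ii, 0), nx - 1)
                            jc = min(max(jj, 0), ny - 1)
                            kc = min(max(kk, 0), nz - 1)
                            acc += wx * wy * wz * vol[ic, jc, kc]
            out[s] = acc
        return out

    @_njit(fastmath=False)
    def _scatter_nb(nx, ny, nz, coords, values, zero_mode):  # pragma: no cover
        out = np.zeros((nx, ny, nz))
        m = coords.shape[1]
        for s in range(m):
            x, y, z = coords[0, s], coords[1, s], coords[2, s]
            i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
            fx, fy, fz = x - i0, y - j0, z - k0
            v = values[s]
            for di in range(2):
                ii = i0 + di
                wx = fx if di else 1.0 - fx
                for dj in range(2):
                    jj = j0 + dj
                    wy = fy if dj else 1.0 - fy
                    for dk in range(2):
                        kk = k0 + dk
                        wz = fz if dk else 1.0 - fz
                        if zero_mode:
                            if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                                out[ii, jj, kk] += wx * wy * wz * v
                        else:
                            ic = min(max(ii, 0), nx - 1)
                            jc = min(max(jj, 0), ny - 1)
                            kc = min(max(kk, 0), nz - 1)
                            out[ic, jc, kc] += wx * wy * wz * v
        return out

    @_njit(fastmath=False)
    def _gradient_nb(vol, coords, zero_mode):  # pragma: no cover - numba
        nx, ny, nz = vol.shape
        m = coords.shape[1]
        out = np.zeros((3, m))
        for s in range(m):
            x, y, z = coords[0, s], coords[1, s], coords[2, s]
            i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
            fx, fy, fz = x - i0, y - j0, z - k0
            gx = gy = gz = 0.0
            for di in range(2):
                ii = i0 + di
                wx = fx if di else 1.0 - fx
                sx = 1.0 if di else -1.0
                for dj in range(2):
                    jj = j0 + dj
                    wy = fy if dj else 1.0 - fy
                    sy = 1.0 if dj else -1.0
                    for dk in range(2):
                        kk = k0 + dk
                        wz = fz if dk else 1.0 - fz
                        sz = 1.0 if dk else -1.0
                        if zero_mode:
                            if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                                continue
                            v = vol[ii, jj, kk]
                        else:
                            v = vol[
                                min(max(ii, 0), nx - 1),
                                min(max(jj, 0), ny - 1),
                                min(max(kk, 0), nz - 1),
                            ]
                        gx += sx * wy * wz * v
                        gy += wx * sy * wz * v
                        gz += wx * wy * sz * v
            out[0, s] = gx
            out[1, s] = gy
            out[2, s] = gz
        return out


def trilinear_gather(vol: np.ndarray, coords: np.ndarray, mode: str = "zero") -> np.ndarray:
    """Trilinear interpolation of ``vol`` at fractional voxel ``coords`` (3, M).

    ``mode="zero"``: corners outside the grid contribute nothing (the
    interpolant ramps to zero within one voxel beyond the edge centers);
    ``mode="clamp"``: indices are clipped to the boundary (nearest-edge
    extension).
    """
    if _HAVE_NUMBA:
        return _gather_nb(
            np.ascontiguousarray(vol, dtype=np.float64),
            np.ascontiguousarray(coords, dtype=np.float64),
            mode == "zero",
        )
    return _gather_np(vol, coords, mode)


def trilinear_scatter(
    shape, coords: np.ndarray, values: np.ndarray, mode: str = "zero"
) -> np.ndarray:
    """Exact adjoint of :func:`trilinear_gather`: spread ``values`` onto a grid."""
    if _HAVE_NUMBA:
        return _scatter_nb(
            int(shape[0]),
            int(shape[1]),
            int(shape[2]),
            np.ascontiguousarray(coords, dtype=np.float64),
            np.ascontiguousarray(values, dtype=np.float64).ravel(),
            mode == "zero",
        )
    return _scatter_np(shape, coords, values, mode)


def trilinear_gradient(vol: np.ndarray, coords: np.ndarray, mode: str = "clamp") -> np.ndarray:
    """Exact derivative of the trilinear interpolant w.r.t. voxel coordinates.

    Returns (3, M): d(interp)/d(coord_axis).  Piecewise constant per cell
    along the differentiated axis; this is the true derivative of the value
    :func:`trilinear_gather` computes, not a smoothed estimate.
    """
    if _HAVE_NUMBA:
        return _gradient_nb(
            np.ascontiguousarray(vol, dtype=np.float64),
            np.ascontiguousarray(coords, dtype=np.float64),
            mode == "zero",
        )
    return _gradient_np(vol, coords, mode)


# ---------------------------------------------------------------------------
# file I/O (MetaImage via SimpleITK, NIfTI via nibabel)
# ---------------------------------------------------------------------------


def _is_nifti(path: Path) -> bool:
    s = str(path)
    return s.endswith(".nii") or s.endswith(".nii.gz")


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag(np.append(vol.spacing_mm, 1.0))
        affine[:3, 3] = vol.origin_mm
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.T, dtype=np.float32))
        img.SetSpacing(tuple(float(s) for s in vol.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in vol.origin_mm))
        sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume3D:
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3]
        return Volume3D(np.asanyarray(img.dataobj, dtype=np.float64), spacing, origin)
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return Volume3D(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def write_dvf(dvf: DVF, path) -> None:
    """Write a DVF as a 3-component MetaImage vector image (mm, world axes)."""
    import SimpleITK as sitk

    arr = np.ascontiguousarray(np.transpose(dvf.field, (2, 1, 0, 3)), dtype=np.float64)
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in dvf.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in dvf.origin_mm))
    sitk.WriteImage(img, str(path))


def write_projection_stack(stack: ProjectionStack, mha_path, csv_path) -> None:
    """Write a stack as one frame-major 3D MetaImage + a CSV angle sidecar."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(stack.pixels, dtype=np.float32))
    px = stack.geometry.detector_pixel_mm
    img.SetSpacing((float(px), float(px), 1.0))
    sitk.WriteImage(img, str(mha_path))
    arr = np.column_stack([np.arange(len(stack)), stack.angles_deg, stack.times_s])
    np.savetxt(csv_path, arr, delimiter=",", header="frame_index,angle_deg,time_s", comments="")


def read_projection_stack(mha_path, csv_path, geometry) -> ProjectionStack:
    """Read a stack written by :func:`write_projection_stack`."""
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(sitk.ReadImage(str(mha_path))).astype(np.float64)
    side = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    return ProjectionStack(arr, geometry, side[:, 1], side[:, 2])


def read_dvf(path) -> DVF:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    return DVF(
        np.transpose(arr, (2, 1, 0, 3)),
        np.array(img.GetSpacing()),
        np.array(img.GetOrigin()),
        provenance=str(path),
    )
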