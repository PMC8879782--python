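"""Volume warping and Demons deformable image registration.

DVF convention.  Every stored field is in the reference-sampling
(pull-back) convention: ``warp_volume(vol, d)(p) = vol(p + d(p))``.
:func:`demons_register` is therefore called with ``fixed = phase`` and
``moving = reference`` when building a motion model, so each stored field
deforms the reference phase toward that breathing phase — the form needed
by the per-projection optimization, where the reference is repeatedly
deformed into candidate states.  This choice is recorded in each DVF's
provenance string.

The Demons solver itself is SimpleITK's symmetric-forces Demons filter,
run coarse-to-fine inside a hand-rolled multiresolution loop (Gaussian
pre-smoothing + shrinking, previous level's field upsampled as the next
initial field).  It is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DVF, Volume3D, trilinear_gather

__all__ = [
    "DemonsParams",
    "warp_volume",
    "demons_register",
    "register_all_phases",
    "body_mask",
    "mask_dvf",
]

log = logging.getLogger(__name__)


@dataclass
class DemonsParams:
    """Multiresolution Demons settings.

    ``shrink_factors``/``iterations`` are per level, coarse to fine.
    Smoothing sigmas are in *voxels of the current level* (the native
    units of the ITK Demons field smoother; sub-voxel sigmas destabilize
    the solver, so voxel units keep the regularization meaningful at every
    pyramid level): ``update_sigma_vox`` regularizes each force update
    (fluid-like), ``field_sigma_vox`` the accumulated field
    (diffusion-like).  Both images are linearly rescaled to
    [0, ``normalize_range``] before the solver runs — the Demons force
    normalization is not intensity-scale invariant, so a fixed working
    range keeps the defaults meaningful for any input units.
    ``intensity_difference_threshold`` (in rescaled units) freezes voxels
    whose fixed/moving difference is below it.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (100, 60, 40)
    update_sigma_vox: float = 1.0
    field_sigma_vox: float = 1.0
    intensity_difference_threshold: float = 0.01
    max_rms_error: float = 1e-3
    normalize_range: float = 100.0

    def __post_init__(self) -> None:
        if len(self.shrink_factors) != len(self.iterations):
            raise ValueError("one iteration count per level required")
        if self.update_sigma_vox < 0 or self.field_sigma_vox < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if any(n < 1 for n in self.iterations):
            raise ValueError("iterations must be >= 1")


def warp_volume(vol: Volume3D, dvf: DVF) -> Volume3D:
    """Pull-back warp: ``out(p) = vol(p + dvf(p))`` with trilinear interpolation.

    Out-of-bounds samples take the boundary-clamped value.  A zero field
    reproduces the input bit-for-bit.
    """
    if not dvf.matches_grid(vol):
        raise ValueError("DVF grid does not match the volume grid")
    nx, ny, nz = vol.shape
    idx = np.indices(vol.shape, dtype=np.float64)  # (3, nx, ny, nz)
    coords = idx.reshape(3, -1) + (dvf.field.reshape(-1, 3) / vol.spacing_mm).T
    out = trilinear_gather(vol.voxels, coords, mode="clamp")
    return vol.like(out.reshape(vol.shape))


# ---------------------------------------------------------------------------
# Demons via SimpleITK
# ---------------------------------------------------------------------------


def _to_sitk(vol: Volume3D):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.T, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in vol.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in vol.origin_mm))
    return img


def _shrink(img, factor: int, sigma_mm: float):
    import SimpleITK as sitk

    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(img, sigma_mm)
    return sitk.Shrink(smoothed, [factor] * 3)


def demons_register(fixed: Volume3D, moving: Volume3D, params: DemonsParams | None = None) -> DVF:
    """Register ``moving`` to ``fixed``; returns d with warp(moving, d) ~ fixed.

    Symmetric-forces Demons with Gaussian regularization, coarse to fine.
    Emits a convergence warning (and returns the field anyway) if the
    registration failed to reduce the intensity residual.
    """
    import SimpleITK as sitk

    if params is None:
        params = DemonsParams()
    if fixed.shape != moving.shape or not np.allclose(fixed.spacing_mm, moving.spacing_mm):
        raise ValueError("fixed and moving must share one grid")
    if not (np.all(np.isfinite(fixed.voxels)) and np.all(np.isfinite(moving.voxels))):
        raise ValueError("non-finite voxel data")

    lo = min(fixed.voxels.min(), moving.voxels.min())
    hi = max(fixed.voxels.max(), moving.voxels.max())
    scale = params.normalize_range / (hi - lo) if hi > lo else 1.0
    f_img = _to_sitk(fixed.like((fixed.voxels - lo) * scale))
    m_img = _to_sitk(moving.like((moving.voxels - lo) * scale))

    field = None
    for factor, iters in zip(params.shrink_factors, params.iterations):
        presmooth_mm = float(np.mean(fixed.spacing_mm)) * max(factor - 1, 0) / 2.0
        f_lvl = _shrink(f_img, factor, presmooth_mm) if factor > 1 else f_img
        m_lvl = _shrink(m_img, factor, presmooth_mm) if factor > 1 else m_img

        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        if params.field_sigma_vox > 0:
            demons.SetSmoothDisplacementField(True)
            demons.SetStandardDeviations(params.field_sigma_vox)
        else:
            demons.SetSmoothDisplacementField(False)
        if params.update_sigma_vox > 0:
            demons.SetSmoothUpdateField(True)
            demons.SetUpdateFieldStandardDeviations(params.update_sigma_vox)
        else:
            demons.SetSmoothUpdateField(False)
        demons.SetIntensityDifferenceThreshold(params.intensity_difference_threshold)
        demons.SetMaximumRMSError(params.max_rms_error)

        if field is None:
            field = demons.Execute(f_lvl, m_lvl)
        else:
            init = sitk.Resample(
                field, f_lvl, sitk.Transform(), sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64
            )
            field = demons.Execute(f_lvl, m_lvl, init)

    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3), components in world mm
    dvf = DVF(
        np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)), dtype=np.float64),
        fixed.spacing_mm.copy(),
        fixed.origin_mm.copy(),
        provenance="demons: pull-back field deforming `moving` toward `fixed`",
    )

    before = float(np.linalg.norm(moving.voxels - fixed.voxels))
    after = float(np.linalg.norm(warp_volume(moving, dvf).voxels - fixed.voxels))
    if after > before and before > 0:
        log.warning("demons did not reduce the residual (%.3g -> %.3g)", before, after)
    return dvf


def body_mask(vol: Volume3D, threshold: float | None = None) -> np.ndarray:
    """Binary patient-outline mask from an (FDK) attenuation volume.

    Threshold at half the median-above-median intensity (robust against
    streak spikes), keep the largest connected component (drops isolated
    streak blobs in the air), fill holes (recovers the lungs inside the
    body shell), then close.  Used to suppress the spurious displacements
    Demons produces on streak artifacts in the air around the patient
    before the fields enter the motion model.
    """
    from scipy.ndimage import binary_closing, binary_fill_holes, label

    v = vol.voxels
    if threshold is None:
        upper = v[v > np.percentile(v, 50)]
        threshold = 0.5 * upper.mean() if upper.size else 0.0
    m = v > threshold
    lab, n = label(m)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        m = lab == int(np.argmax(sizes))
    m = binary_fill_holes(m)
    m = binary_closing(m, iterations=1)
    return m


def mask_dvf(dvf: DVF, mask: np.ndarray, feather_vox: float = 1.0) -> DVF:
    """Zero a DVF outside a mask, with a Gaussian-feathered edge (C^1-ish)."""
    from scipy.ndimage import gaussian_filter

    w = gaussian_filter(mask.astype(np.float64), feather_vox) if feather_vox > 0 else mask
    return DVF(dvf.field * w[..., None], dvf.spacing_mm.copy(), dvf.origin_mm.copy(),
               provenance=dvf.provenance + " (body-masked)")


def register_all_phases(
    phases: list[Volume3D], reference_index: int, params: DemonsParams | None = None
) -> list[DVF]:
    """One pull-back DVF per phase, deforming the reference toward each phase.

    The reference's own entry is the exact zero field.
    """
    if len(phases) < 2:
        raise ValueError("need at least two phases")
    reference = phases[reference_index]
    out: list[DVF] = []
    for k, phase in enumerate(phases):
        if k == reference_index:
            d = DVF.zeros_like_volume(reference, provenance="reference self-registration")
        else:
            d = demons_register(fixed=phase, moving=reference, params=params)
            d.provenance = f"demons: reference -> phase {k}"
        out.append(d)
    return out
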