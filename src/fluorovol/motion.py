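"""PCA eigenmode decomposition of a DVF set — the respiratory motion model.

A set of displacement fields (one per breathing phase, registered to a
common reference) is flattened into sample vectors and decomposed as

    D(t) = D_mean + sum_i  u_i(t) * v_i,      i = 1..N

with orthonormal spatial eigenmodes v_i (descending eigenvalue order) and
per-phase scores u_i(t).  A handful of modes (default N = 3) captures the
organ motion; the per-projection estimator then searches over u.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import DVF

__all__ = ["PCAMotionModel", "build_pca_model", "reconstruct_dvf", "explained_variance"]

log = logging.getLogger(__name__)


@dataclass
class PCAMotionModel:
    """Mean field + retained eigenmodes + eigenvalues + training scores.

    ``modes`` has shape (N, nx, ny, nz, 3); each mode is unit-norm under
    the flattened (unweighted) inner product and mutually orthonormal.
    ``eigenvalues`` are score variances (mm^2 units, descending);
    ``spectrum`` keeps the full nonzero eigenvalue spectrum so explained
    variance can be reported beyond the retained modes.  ``scores`` is
    (n_training_samples, N).
    """

    mean: DVF
    modes: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    spectrum: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def grid_shape(self):
        return self.mean.grid_shape

    def mode_dvf(self, i: int) -> DVF:
        return DVF(self.modes[i], self.mean.spacing_mm.copy(), self.mean.origin_mm.copy(),
                   provenance=f"eigenmode {i + 1}")

    def score_scale(self) -> np.ndarray:
        """Per-mode score standard deviation (sqrt of eigenvalue)."""
        return np.sqrt(np.maximum(self.eigenvalues, 0.0))

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        """Serialize as a directory: vector images + CSV + YAML metadata."""
        import yaml

        from .core import write_dvf

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_dvf(self.mean, directory / "mean_dvf.mha")
        for i in range(self.n_modes):
            write_dvf(self.mode_dvf(i), directory / f"mode_{i + 1}.mha")
        np.savetxt(directory / "eigenvalues.csv", self.eigenvalues, delimiter=",",
                   header="eigenvalue_mm2", comments="")
        np.savetxt(directory / "spectrum.csv", self.spectrum, delimiter=",",
                   header="eigenvalue_mm2", comments="")
        np.savetxt(directory / "scores.csv", self.scores, delimiter=",",
                   header=",".join(f"u{i + 1}" for i in range(self.n_modes)), comments="")
        meta = dict(self.metadata)
        meta["n_modes"] = int(self.n_modes)
        (directory / "metadata.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, directory) -> "PCAMotionModel":
        import yaml

        from .core import read_dvf

        directory = Path(directory)
        meta = yaml.safe_load((directory / "metadata.yaml").read_text())
        mean = read_dvf(directory / "mean_dvf.mha")
        n = int(meta["n_modes"])
        modes = np.stack([read_dvf(directory / f"mode_{i + 1}.mha").field for i in range(n)])
        eig = np.loadtxt(directory / "eigenvalues.csv", delimiter=",", skiprows=1, ndmin=1)
        spectrum = np.loadtxt(directory / "spectrum.csv", delimiter=",", skiprows=1, ndmin=1)
        scores = np.loadtxt(directory / "scores.csv", delimiter=",", skiprows=1, ndmin=2)
        return cls(mean, modes, eig, scores, spectrum, meta)


def build_pca_model(dvfs: list[DVF], n_modes: int = 3) -> PCAMotionModel:
    """PCA of a DVF set via SVD of the centered, flattened sample matrix.

    Each DVF becomes one sample vector; the mean field is subtracted;
    modes are the right singular vectors sorted by descending singular
    value.  Each mode's sign is fixed so that its largest-magnitude SI
    component is positive, for reproducible output.  ``n_modes`` larger
    than the available rank is truncated with a warning.
    """
    if len(dvfs) < 2:
        raise ValueError("need at least two DVFs")
    g0 = dvfs[0]
    for d in dvfs[1:]:
        if d.grid_shape != g0.grid_shape or not np.allclose(d.spacing_mm, g0.spacing_mm):
            raise ValueError("all DVFs must share one grid")

    n = len(dvfs)
    X = np.stack([d.field.ravel() for d in dvfs])  # (n, 3*nvox)
    mean_vec = X.mean(axis=0)
    Xc = X - mean_vec

    max_rank = n - 1
    if n_modes > max_rank:
        warnings.warn(
            f"n_modes={n_modes} exceeds sample rank {max_rank}; truncating", RuntimeWarning
        )
        n_modes = max_rank

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals_all = S**2 / (n - 1)
    spectrum = eigvals_all[:max_rank]

    keep = min(n_modes, max_rank)
    modes_flat = Vt[:keep]
    scores = Xc @ modes_flat.T  # (n, keep)

    # sign convention: largest-|.| SI component of each mode positive
    shp = g0.grid_shape + (3,)
    for i in range(keep):
        si = modes_flat[i].reshape(shp)[..., 2]
        j = np.argmax(np.abs(si))
        if si.ravel()[j] < 0:
            modes_flat[i] = -modes_flat[i]
            scores[:, i] = -scores[:, i]

    mean = DVF(mean_vec.reshape(shp), g0.spacing_mm.copy(), g0.origin_mm.copy(),
               provenance="PCA mean DVF")
    return PCAMotionModel(
        mean=mean,
        modes=modes_flat.reshape((keep,) + shp),
        eigenvalues=eigvals_all[:keep],
        scores=scores,
        spectrum=spectrum,
        metadata={"n_samples": n},
    )


def reconstruct_dvf(model: PCAMotionModel, coefficients) -> DVF:
    """D_mean + sum_i u_i v_i for an N-vector of coefficients; linear in u."""
    u = np.asarray(coefficients, dtype=np.float64).ravel()
    if u.size != model.n_modes:
        raise ValueError(f"expected {model.n_modes} coefficients, got {u.size}")
    f = model.mean.field + np.tensordot(u, model.modes, axes=(0, 0))
    return DVF(f, model.mean.spacing_mm.copy(), model.mean.origin_mm.copy(),
               provenance="PCA reconstruction")


def explained_variance(model: PCAMotionModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode and cumulative explained-variance ratios over the full spectrum."""
    total = model.spectrum.sum()
    if total <= 0:
        raise ValueError("explained variance undefined: zero total variance")
    ratios = model.spectrum / total
    return ratios, np.cumsum(ratios)
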