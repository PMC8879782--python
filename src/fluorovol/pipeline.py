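"""End-to-end orchestration: phantom/load -> sort -> FDK -> DIR -> PCA -> estimate -> evaluate.

The two-step workflow: (1) build the patient-specific PCA motion model
from phase-sorted, FDK-reconstructed 4D-CBCT and Demons registration;
(2) optimize the model coefficients against every projection to produce
the fluoroscopic 3D sequence, then evaluate tumor localization.

``run_pipeline`` consumes a :class:`RunConfig` (loadable from YAML),
writes every stage's outputs plus a frozen copy of the resolved
configuration into the run directory, and returns the in-memory results.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .core import Volume3D, write_dvf, write_volume
from .estimator import FluoroscopicModel
from .geometry import ConeBeamGeometry, make_arc, n_frames_for
from .motion import build_pca_model, explained_variance
from .phantom import (
    PhantomSpec,
    desk_geometry,
    make_phantom,
    signal_from_spec,
    simulate_acquisition,
)
from .reconstruction import FDKParams, reconstruct_4dcbct
from .registration import DemonsParams, body_mask, mask_dvf, register_all_phases
from .respiratory import amsterdam_shroud, bin_projections, extract_phase

__all__ = ["RunConfig", "run_pipeline", "select_reference_phase", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``source`` is "phantom" (synthesize the acquisition; the default) or
    "load" (read a projection stack written by this package).  The random
    seed drives every stochastic option (breathing jitter, noise).
    """

    output_dir: str = "fluorovol_run"
    source: str = "phantom"
    # phantom mode
    phantom: dict = dc_field(default_factory=dict)  # PhantomSpec overrides
    n_frames: int | None = None
    duration_s: float = 60.0
    frame_rate_hz: float = 5.5
    noise_sigma: float = 0.0
    seed: int = 0
    # load mode
    projections_mha: str | None = None
    projections_csv: str | None = None
    tumor_centroid_mm: tuple[float, float, float] | None = None
    diaphragm_apex_mm: tuple[float, float, float] | None = None
    # geometry (None fields fall back to the desk geometry)
    geometry: dict = dc_field(default_factory=dict)
    # stages
    n_bins: int = 6
    reference_bin: int | None = None  # None: automatic peak-exhale selection
    demons: dict = dc_field(default_factory=dict)
    n_modes: int = 3
    mask_dvfs_to_body: bool = True
    roi_margin_mm: float = 30.0
    use_roi: bool = True
    optimizer_max_iterations: int = 50
    optimizer_tol: float = 1e-4
    store_volumes: bool = False
    apodization: str = "none"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class PipelineResult:
    """In-memory products of a pipeline run."""

    config: RunConfig
    reference_bin: int
    phases: list
    motion_model: object
    results: object
    report: object | None
    truth_positions_mm: np.ndarray | None
    signal: object
    assignment: object


def select_reference_phase(assignment, signal, n_bins: int | None = None) -> int:
    """Peak-exhale bin: the bin whose frames have the lowest mean amplitude.

    The trace is oriented inhale-high (see the shroud extractor), so the
    minimum-mean bin is end-expiration.
    """
    if n_bins is None:
        n_bins = assignment.n_bins
    means = []
    for b in range(n_bins):
        sel = assignment.bin_index == b
        if not np.any(sel):
            means.append(np.inf)
        else:
            means.append(float(np.mean(signal.samples[sel])))
    return int(np.argmin(means))


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full two-step workflow described in the module docstring."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    geom = ConeBeamGeometry(**{**dataclasses.asdict(desk_geometry()), **config.geometry})

    truth = None
    tumor_centroid = config.tumor_centroid_mm
    diaphragm_apex = config.diaphragm_apex_mm
    if config.source == "phantom":
        t0 = _stage("phantom + acquisition simulation")
        spec = PhantomSpec(**config.phantom)
        n = config.n_frames or n_frames_for(config.duration_s, config.frame_rate_hz)
        arc = make_arc(geom, n, config.frame_rate_hz)
        signal_true = signal_from_spec(spec, n, config.frame_rate_hz, seed=config.seed)
        stack, truth = simulate_acquisition(
            spec, signal_true, geom, arc, noise_sigma=config.noise_sigma, seed=config.seed + 1
        )
        reference_truth, _ = make_phantom(spec)
        write_volume(reference_truth, out / "phantom_reference.mha")
        if tumor_centroid is None:
            tumor_centroid = spec.tumor_center_mm
        if diaphragm_apex is None:
            diaphragm_apex = (
                spec.lung_center_mm[0],
                spec.lung_center_mm[1],
                spec.diaphragm_apex_z_mm,
            )
        grid_template = reference_truth
        np.savetxt(
            out / "tumor_truth.csv",
            np.column_stack([np.arange(n), truth]),
            delimiter=",",
            header="frame,x_mm,y_mm,z_mm",
            comments="",
        )
        log.info("simulated %d frames in %.1f s", n, time.time() - t0)
    elif config.source == "load":
        from .core import read_projection_stack

        if config.projections_mha is None or config.projections_csv is None:
            raise ValueError("load mode requires projections_mha and projections_csv")
        stack = read_projection_stack(config.projections_mha, config.projections_csv, geom)
        spec = PhantomSpec(**config.phantom)  # grid defaults for the output volume
        grid_template = Volume3D.centered(np.zeros(spec.grid_shape), spec.spacing_mm)
        if tumor_centroid is None:
            raise ValueError("load mode requires tumor_centroid_mm")
    else:
        raise ValueError(f"unknown source {config.source!r}")

    t0 = _stage("respiratory signal + phase sorting")
    trace = amsterdam_shroud(stack)
    assignment = extract_phase(trace, n_bins=config.n_bins)
    assignment.to_frame().to_csv(out / "phase_assignment.csv", index=False)
    np.savetxt(out / "breathing_trace.csv",
               np.column_stack([trace.times_s, trace.samples]),
               delimiter=",", header="time_s,amplitude", comments="")
    bins = bin_projections(stack, assignment)
    log.info("sorted %d frames into %d bins in %.1f s",
             len(stack), config.n_bins, time.time() - t0)

    t0 = _stage("FDK reconstruction per bin")
    params = FDKParams(grid=grid_template, apodization=config.apodization)
    phases = reconstruct_4dcbct(stack, assignment, params)
    log.info("reconstructed %d phases in %.1f s", len(phases), time.time() - t0)

    ref_bin = (
        config.reference_bin
        if config.reference_bin is not None
        else select_reference_phase(assignment, trace)
    )
    log.info("reference phase bin: %d", ref_bin)
    for b, vol in enumerate(phases):
        write_volume(vol, out / f"phase_{b}.mha")

    t0 = _stage("Demons registration")
    dvfs = register_all_phases(phases, ref_bin, DemonsParams(**config.demons))
    if config.mask_dvfs_to_body:
        mask = body_mask(phases[ref_bin])
        dvfs = [mask_dvf(d, mask) for d in dvfs]
    for b, d in enumerate(dvfs):
        write_dvf(d, out / f"dvf_{b}.mha")
    log.info("registered %d phases in %.1f s", len(dvfs), time.time() - t0)

    t0 = _stage("PCA motion model")
    model = build_pca_model(dvfs, n_modes=config.n_modes)
    model.metadata.update({"reference_bin": ref_bin,
                           "dvf_convention": "pull-back (reference-sampling)"})
    model.save(out / "motion_model")
    ratios, cum = explained_variance(model)
    log.info("explained variance (first %d modes): %.1f%%",
             config.n_modes, 100 * cum[min(config.n_modes, cum.size) - 1])

    t0 = _stage("per-projection estimation")
    fmodel = FluoroscopicModel(
        stack,
        phases[ref_bin],
        model,
        tumor_centroid_mm=tumor_centroid,
        diaphragm_apex_mm=diaphragm_apex,
        roi_margin_mm=config.roi_margin_mm,
        use_roi=config.use_roi,
        max_iterations=config.optimizer_max_iterations,
        tol=config.optimizer_tol,
    )
    results = fmodel.fit(store_volumes=config.store_volumes)
    results.to_frame().to_csv(out / "per_frame.csv", index=False)
    if config.store_volumes:
        vol_dir = out / "fluoroscopic_volumes"
        vol_dir.mkdir(exist_ok=True)
        for i, vol in enumerate(results.volumes):
            write_volume(vol, vol_dir / f"frame_{i:05d}.mha")
    log.info("estimated %d frames in %.1f s", results.n_frames, time.time() - t0)

    report = None
    if tumor_centroid is not None:
        est = results.tumor_positions()
        np.savetxt(out / "tumor_estimated.csv",
                   np.column_stack([np.arange(len(est)), est]),
                   delimiter=",", header="frame,x_mm,y_mm,z_mm", comments="")
    if truth is not None:
        report = results.evaluate(truth)
        summary = results.summary() + "\n\n" + str(report) + "\n"
        (out / "report.txt").write_text(summary)
        log.info("%s", report)
    else:
        (out / "report.txt").write_text(results.summary() + "\n")

    return PipelineResult(
        config=config,
        reference_bin=ref_bin,
        phases=phases,
        motion_model=model,
        results=results,
        report=report,
        truth_positions_mm=truth,
        signal=trace,
        assignment=assignment,
    )
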