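"""Shared fixtures: a miniature phantom study and one full desk-scale run.

The miniature setting (32^3 grid at 8 mm, 48^2 panel) keeps unit tests
fast; the desk-scale run (64^3 at 4 mm, 96^2 panel, 330 frames over a
200-degree arc, 6 phase bins, 3 modes) is executed once per session and
shared by the end-to-end tests.
"""

from __future__ import annotations

import pytest

from fluorovol import (
    ConeBeamGeometry,
    PhantomSpec,
    RunConfig,
    make_arc,
    make_phantom,
    run_pipeline,
    signal_from_spec,
    simulate_acquisition,
)

SEED = 20260920


def tiny_phantom_spec(**overrides) -> PhantomSpec:
    kw = dict(grid_shape=(32, 32, 32), spacing_mm=(8.0, 8.0, 8.0))
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return tiny_phantom_spec()


@pytest.fixture(scope="session")
def tiny_geom() -> ConeBeamGeometry:
    return ConeBeamGeometry(
        detector_rows=48, detector_cols=48, detector_pixel_mm=8.0,
        arc_start_deg=-100.0, arc_span_deg=200.0,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_spec, tiny_geom):
    """A 180-frame (8-cycle) miniature acquisition with ground truth."""
    n = 180
    arc = make_arc(tiny_geom, n, 5.5)
    signal = signal_from_spec(tiny_spec, n, 5.5, seed=SEED)
    stack, truth = simulate_acquisition(tiny_spec, signal, tiny_geom, arc)
    reference, tumor_mask = make_phantom(tiny_spec)
    return {
        "spec": tiny_spec,
        "geom": tiny_geom,
        "arc": arc,
        "signal": signal,
        "stack": stack,
        "truth": truth,
        "reference": reference,
        "tumor_mask": tumor_mask,
    }


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale pipeline run (the package's standard preset)."""
    outdir = tmp_path_factory.mktemp("desk_run")
    config = RunConfig(output_dir=str(outdir), seed=SEED)
    return run_pipeline(config)
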