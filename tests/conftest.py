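"""Shared fixtures: calibrated phantoms and their analyzed renders.

The expensive noise-free renders and full analyses are session-scoped so
the oracle-equivalence, recovery and bookkeeping tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cinedense import phantom, pipeline

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: healthy-subject strain-table means the phantom is calibrated to
HEALTHY_ECC = -0.18
HEALTHY_ERR = 0.35
HEALTHY_ELL = -0.15
HEALTHY_TORSION = 2.79

SAX_VIEWS = ("SAX-base", "SAX-mid", "SAX-apex")


@pytest.fixture(scope="session")
def healthy_spec() -> phantom.PhantomSpec:
    return phantom.calibrate_deformation(
        HEALTHY_ECC,
        HEALTHY_ERR,
        HEALTHY_ELL,
        phantom.twists_for_torsion((0.0, 25.0, 50.0), HEALTHY_TORSION),
    )


@pytest.fixture(scope="session")
def sax_renders_17(healthy_spec):
    """Noise-free SAX renders at 1.7 mm, one per level."""
    return {
        view: phantom.render_dense_series(healthy_spec, view, 1.7, seed=0)
        for view in SAX_VIEWS
    }


@pytest.fixture(scope="session")
def sax_summaries_17(sax_renders_17):
    return {
        view: pipeline.analyze_series(series, roi)
        for view, (series, roi) in sax_renders_17.items()
    }


@pytest.fixture(scope="session")
def lax_summary_17(healthy_spec):
    series, roi = phantom.render_dense_series(healthy_spec, "LAX-4CH", 1.7, seed=0)
    return pipeline.analyze_series(series, roi)


@pytest.fixture(scope="session")
def base_render_1mm(healthy_spec):
    """Noise-free basal-slice render at 1 mm for per-point oracle checks."""
    return phantom.render_dense_series(healthy_spec, "SAX-base", 1.0, seed=0)


@pytest.fixture(scope="session")
def base_analysis_1mm(base_render_1mm):
    from cinedense import phase, strain

    series, roi = base_render_1mm
    unwrapped = phase.unwrap_phase(series, roi)
    disp = phase.to_displacement(
        unwrapped, series.encoding_frequency, series.pixel_spacing
    )
    traj = phase.track_trajectories(
        disp, roi.reference_mask, times_ms=series.trigger_times
    )
    s = series.pixel_spacing
    center_mm = np.array([roi.center[1] * s, roi.center[0] * s])
    fieldd = strain.compute_strain_field(
        traj, series.view, series.landmarks, center_mm=center_mm,
        neighborhood_radius=2.5 * s,
    )
    summary = strain.strain_summary(fieldd, traj, slice_location=series.slice_location)
    return {
        "series": series,
        "roi": roi,
        "traj": traj,
        "field": fieldd,
        "summary": summary,
        "center_mm": center_mm,
    }


def eulerian_truth(spec, series, roi, frame):
    """Ground-truth Eulerian displacement at the masked pixels of a frame.

    Inverts the analytic deformation map on the pixel grid exactly (the
    twist is spatially uniform, so the reference angle is known in closed
    form), independently of what the renderer stored.
    """
    s = series.pixel_spacing
    n = series.grid_shape[0]
    c = (n - 1) / 2.0 * s
    idx = np.arange(n) * s - c
    xg, yg = np.meshgrid(idx, idx, indexing="xy")
    t = series.trigger_times[frame]
    z = series.slice_location
    r = np.hypot(xg, yg)
    th = np.arctan2(yg, xg)
    _, _, psi = spec.coefficients(0.0, z, t)
    theta_ref = th - psi
    A, B, _ = spec.coefficients(theta_ref, z, t)
    R = (r - B) / A
    ux = xg - R * np.cos(theta_ref)
    uy = yg - R * np.sin(theta_ref)
    m = roi.mask[frame]
    return ux, uy, m
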