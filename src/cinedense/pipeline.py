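"""Configuration-driven study orchestration.

Emulates the two-scan, multi-analyst reproducibility design end-to-end on
synthetic data: generate a cohort of deforming-LV phantoms (each subject
scanned twice, with repositioning emulated by a slice-position offset),
run phase unwrapping -> tracking -> strain for several emulated "users"
(perturbed analysis inputs: eroded/dilated masks, jittered RV-insertion
landmark, altered temporal smoothing), pair the resulting strain tables
per comparison type, and emit agreement statistics, bullseye tables, and a
machine-readable run manifest.  Everything derives deterministically from
one master seed.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import ndimage

from . import core, phantom, phase, strain, stats


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input id."""

    def __init__(self, stage: str, input_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id


class UserParams(BaseModel):
    """Perturbations emulating one analyst's conventions."""

    mask_erode: int = 0               # pixels; negative dilates
    landmark_jitter_deg: float = 0.0  # RV-insertion rotation about the center
    smooth_degree_offset: int = 0     # added to the smoothing polynomial degree

    @property
    def is_reference(self) -> bool:
        return (
            self.mask_erode == 0
            and self.landmark_jitter_deg == 0.0
            and self.smooth_degree_offset == 0
        )


DEFAULT_USERS = {
    "user1": UserParams(),
    "user1-session2": UserParams(landmark_jitter_deg=1.0, smooth_degree_offset=1),
    "user2": UserParams(mask_erode=-1, landmark_jitter_deg=3.0, smooth_degree_offset=-1),
    "user-uva": UserParams(mask_erode=-1, landmark_jitter_deg=5.0, smooth_degree_offset=-2),
    "dl": UserParams(mask_erode=-1, landmark_jitter_deg=2.0, smooth_degree_offset=2),
}

#: comparison type -> ((user, scan), (user, scan))
DEFAULT_COMPARISONS = {
    "intra-user": (("user1", "A"), ("user1-session2", "A")),
    "inter-user-same-site": (("user1", "A"), ("user2", "A")),
    "inter-user-different-site": (("user1", "A"), ("user-uva", "A")),
    "inter-user-human-DL": (("user1", "A"), ("dl", "A")),
    "inter-scan": (("user1", "A"), ("user1", "B")),
}

ALL_ENDPOINTS = (
    "whole-slice-Ecc",
    "whole-slice-Err",
    "global-Ell",
    "torsion",
    "segmental-Ecc",
)


class StudyConfig(BaseModel):
    """Every knob of one emulated reproducibility study."""

    n_healthy: int = 6
    n_patient: int = 2
    pixel_spacing: float = 3.4
    noise_sd: float = 4.0
    scanb_z_offset: float = 2.0
    n_frames: int = 40
    views: list[str] = Field(default_factory=lambda: list(phantom._ALL_VIEWS))
    smooth_degree: int = 6
    neighborhood_radius_px: float = 2.5
    cv_mean_floor: float = stats.CV_MEAN_FLOOR
    septal_reduction_patient: float = 0.5
    snr_threshold: float = core.PHASE_SNR_THRESHOLD
    users: dict[str, UserParams] = Field(default_factory=lambda: dict(DEFAULT_USERS))
    comparisons: dict[str, tuple[tuple[str, str], tuple[str, str]]] = Field(
        default_factory=lambda: dict(DEFAULT_COMPARISONS)
    )
    endpoints: list[str] = Field(default_factory=lambda: list(ALL_ENDPOINTS))
    seed: int = 0
    outdir: str = "study-output"

    @field_validator("views")
    @classmethod
    def _known_views(cls, v):
        for view in v:
            if view not in core.VIEWS:
                raise ValueError(f"unknown view {view!r}")
        return v

    def validated_comparisons(self):
        for name, ((u1, s1), (u2, s2)) in self.comparisons.items():
            for u in (u1, u2):
                if u not in self.users:
                    raise ValueError(
                        f"comparison {name!r} references unknown user {u!r}"
                    )
            for s in (s1, s2):
                if s not in ("A", "B"):
                    raise ValueError(f"comparison {name!r}: scan must be A or B")
        return self.comparisons


# ---------------------------------------------------------------------------
# single-series analysis

@dataclass
class AnalysisParams:
    smooth_degree: int = 6
    neighborhood_radius_px: float = 2.5
    #: masked pixels whose magnitude falls below this fraction of the median
    #: myocardial magnitude carry no stimulated-echo signal (e.g. background
    #: swept in by a generous contour) and are excluded before unwrapping
    magnitude_gate_frac: float = 0.25


def _gate_mask(series: core.DenseSeries, roi: core.RoiMask, frac: float) -> core.RoiMask:
    if frac <= 0:
        return roi
    med = np.median(series.magnitude[roi.mask])
    gated = roi.mask & (series.magnitude >= frac * med)
    # never gate away a whole frame; fall back to the drawn mask
    for k in range(gated.shape[0]):
        if not gated[k].any():
            gated[k] = roi.mask[k]
    return core.RoiMask(
        mask=gated,
        endo_contour=roi.endo_contour,
        epi_contour=roi.epi_contour,
        center=roi.center,
    )


def analyze_series(
    series: core.DenseSeries,
    roi: core.RoiMask,
    params: AnalysisParams | None = None,
) -> strain.StrainSummary:
    """Run unwrap -> displacement -> tracking -> strain for one slice."""
    params = params or AnalysisParams()
    roi = _gate_mask(series, roi, params.magnitude_gate_frac)
    unwrapped = phase.unwrap_phase(series, roi)
    disp = phase.to_displacement(
        unwrapped, series.encoding_frequency, series.pixel_spacing
    )
    traj = phase.track_trajectories(
        disp,
        roi.reference_mask,
        times_ms=series.trigger_times,
        smooth_degree=params.smooth_degree if params.smooth_degree > 0 else None,
    )
    s = series.pixel_spacing
    center_mm = np.array([roi.center[1] * s, roi.center[0] * s])
    fieldd = strain.compute_strain_field(
        traj,
        series.view,
        series.landmarks,
        center_mm=center_mm,
        neighborhood_radius=params.neighborhood_radius_px * s,
    )
    return strain.strain_summary(fieldd, traj, slice_location=series.slice_location)


def emulate_users(
    series: core.DenseSeries,
    roi: core.RoiMask,
    user: UserParams,
    seed: int,
    base_smooth_degree: int = 6,
) -> tuple[core.DenseSeries, core.RoiMask, AnalysisParams]:
    """Produce the analysis-input variant one emulated analyst would use.

    Mask erosion/dilation is applied per frame; the RV-insertion landmark is
    rotated about the LV center by a seeded draw within +/- the jitter
    range; the smoothing degree is offset.  A zero-perturbation user
    reproduces the reference analysis input exactly.
    """
    params = AnalysisParams(smooth_degree=base_smooth_degree + user.smooth_degree_offset)
    if user.is_reference:
        return series, roi, params
    mask = roi.mask
    if user.mask_erode > 0:
        mask = np.stack(
            [ndimage.binary_erosion(m, iterations=user.mask_erode) for m in roi.mask]
        )
    elif user.mask_erode < 0:
        mask = np.stack(
            [ndimage.binary_dilation(m, iterations=-user.mask_erode) for m in roi.mask]
        )
    landmarks = dict(series.landmarks)
    if user.landmark_jitter_deg and "rv_insertion" in landmarks:
        rng = np.random.default_rng(seed)
        ang = np.deg2rad(user.landmark_jitter_deg) * rng.uniform(-1.0, 1.0)
        rv = np.asarray(landmarks["rv_insertion"], dtype=float) - roi.center
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        # (row, col) rotation: rotating the (x, y)=(col, row) vector by +ang
        xy = np.array([rv[1], rv[0]])
        xy = rot @ xy
        landmarks["rv_insertion"] = roi.center + np.array([xy[1], xy[0]])
    new_series = core.DenseSeries(
        magnitude=series.magnitude,
        phase_x=series.phase_x,
        phase_y=series.phase_y,
        trigger_times=series.trigger_times,
        pixel_spacing=series.pixel_spacing,
        encoding_frequency=series.encoding_frequency,
        view=series.view,
        slice_location=series.slice_location,
        landmarks=landmarks,
        noise_sd=series.noise_sd,
    )
    new_roi = core.RoiMask(
        mask=mask,
        endo_contour=roi.endo_contour,
        epi_contour=roi.epi_contour,
        center=roi.center,
    )
    return new_series, new_roi, params


# ---------------------------------------------------------------------------
# study orchestration

def _subject_scan_analysis(
    datadir: str,
    manifest: pd.DataFrame,
    subject: str,
    scan: str,
    user: UserParams,
    user_seed: int,
    config: StudyConfig,
) -> dict:
    """Analyze every view of one (subject, scan) with one emulated user."""
    rows = manifest[(manifest.subject == subject) & (manifest.scan == scan)]
    out = {"slices": {}, "points": {}}
    sax = []
    for _, row in rows.iterrows():
        series, roi = core.read_series(os.path.join(datadir, row["path"]))
        if core.phase_snr(series, roi) < config.snr_threshold and series.noise_sd:
            continue
        s2, r2, params = emulate_users(
            series, roi, user, user_seed, base_smooth_degree=config.smooth_degree
        )
        params.neighborhood_radius_px = config.neighborhood_radius_px
        try:
            summary = analyze_series(s2, r2, params)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError("analyze", f"{subject}/{scan}/{row['view']}", exc)
        out["slices"][row["view"]] = summary
        if row["view"].startswith("SAX"):
            sax.append(summary)
            pts = pd.DataFrame(
                {
                    "pixel": [tuple(p) for p in summary.seed_pixels],
                    "segment": summary.point_segments,
                    "value": summary.point_es_values,
                    "valid": summary.point_valid_es,
                }
            )
            out["points"][row["view"]] = pts[pts.valid]
    if len(sax) >= 2:
        out["torsion"] = strain.compute_torsion(
            [s.es_twist for s in sax], [s.slice_location for s in sax]
        )
    if sax:
        out["global_ecc"] = float(np.mean([s.es_ecc for s in sax]))
        out["global_err"] = float(np.mean([s.es_err for s in sax]))
    lax = out["slices"].get("LAX-4CH")
    if lax is not None:
        out["global_ell"] = lax.global_ell
    return out


def run_pipeline(config: StudyConfig) -> str:
    """Execute simulate -> analyze -> compare; returns the output directory.

    Deterministic under the master seed: the cohort, every emulated user's
    jitter, and all noise realizations derive from it.  Outputs under
    ``config.outdir``: data/ (series + manifest), qc.csv, strain.csv,
    comparisons.csv / comparisons.json, bullseye_cv.csv / bullseye_icc.csv,
    run_manifest.json.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    datadir = os.path.join(outdir, "data")
    comparisons = config.validated_comparisons()
    n_total = config.n_healthy + config.n_patient
    if n_total == 0:
        pd.DataFrame(columns=["subject", "user", "scan", "view"]).to_csv(
            os.path.join(outdir, "strain.csv"), index=False
        )
        pd.DataFrame(columns=["comparison", "endpoint", "n"]).to_csv(
            os.path.join(outdir, "comparisons.csv"), index=False
        )
        with open(os.path.join(outdir, "run_manifest.json"), "w") as f:
            json.dump({"config": config.model_dump(), "n_subjects": 0}, f, indent=2)
        return outdir

    ss = np.random.SeedSequence(config.seed)
    cohort_seed, user_seed_root = [int(s) for s in ss.generate_state(2) >> 1]
    manifest = phantom.render_cohort(
        config.n_healthy,
        config.n_patient,
        datadir,
        seed=cohort_seed,
        pixel_spacing=config.pixel_spacing,
        noise_sd=config.noise_sd,
        scanb_z_offset=config.scanb_z_offset,
        septal_reduction_patient=config.septal_reduction_patient,
        views=tuple(config.views),
        n_frames=config.n_frames,
    )

    # QC report over all series
    qc_pairs = [
        core.read_series(os.path.join(datadir, p)) for p in manifest.path
    ]
    core.quality_filter(
        qc_pairs, threshold=config.snr_threshold,
        report_path=os.path.join(outdir, "qc.csv"),
    )

    # which (user, scan) observations does the design need?
    needed = sorted({obs for pair in comparisons.values() for obs in pair})
    analyses: dict[tuple[str, str, str], dict] = {}
    for subject in manifest.subject.unique():
        for user_name, scan in needed:
            key = f"{subject}|{user_name}|{scan}".encode()
            seed = (zlib.crc32(key) ^ user_seed_root) % (2**31)
            analyses[(subject, user_name, scan)] = _subject_scan_analysis(
                datadir, manifest, subject, scan,
                config.users[user_name], seed, config,
            )

    strain_rows = []
    for (subject, user_name, scan), res in analyses.items():
        for view, summary in res["slices"].items():
            strain_rows.append(
                {
                    "subject": subject,
                    "user": user_name,
                    "scan": scan,
                    "view": view,
                    "slice_location": summary.slice_location,
                    "es_frame": summary.es_frame,
                    "es_ecc": summary.es_ecc,
                    "es_err": summary.es_err,
                    "es_ell": summary.es_ell,
                    "global_ell": summary.global_ell,
                    "es_twist": summary.es_twist,
                }
            )
        for key in ("torsion", "global_ecc", "global_err", "global_ell"):
            if key in res:
                strain_rows.append(
                    {"subject": subject, "user": user_name, "scan": scan,
                     "view": "(stack)", "endpoint": key, "value": res[key]}
                )
    pd.DataFrame(strain_rows).to_csv(os.path.join(outdir, "strain.csv"), index=False)

    unit_rows, point_rows = [], []
    for comp_name, (obs1, obs2) in comparisons.items():
        for subject in manifest.subject.unique():
            r1 = analyses[(subject, obs1[0], obs1[1])]
            r2 = analyses[(subject, obs2[0], obs2[1])]
            if "whole-slice-Ecc" in config.endpoints:
                for view in ("SAX-base", "SAX-mid", "SAX-apex"):
                    s1, s2 = r1["slices"].get(view), r2["slices"].get(view)
                    if s1 and s2:
                        unit_rows.append(
                            {"comparison": comp_name, "endpoint": "whole-slice-Ecc",
                             "unit": f"{subject}/{view}",
                             "value_1": s1.es_ecc, "value_2": s2.es_ecc}
                        )
                        if "whole-slice-Err" in config.endpoints:
                            unit_rows.append(
                                {"comparison": comp_name, "endpoint": "whole-slice-Err",
                                 "unit": f"{subject}/{view}",
                                 "value_1": s1.es_err, "value_2": s2.es_err}
                            )
            for endpoint, key in (("global-Ell", "global_ell"), ("torsion", "torsion")):
                if endpoint in config.endpoints and key in r1 and key in r2:
                    if r1[key] is not None and r2[key] is not None:
                        unit_rows.append(
                            {"comparison": comp_name, "endpoint": endpoint,
                             "unit": subject, "value_1": r1[key], "value_2": r2[key]}
                        )
            if "segmental-Ecc" in config.endpoints:
                for view in ("SAX-base", "SAX-mid", "SAX-apex"):
                    p1, p2 = r1["points"].get(view), r2["points"].get(view)
                    if p1 is None or p2 is None:
                        continue
                    merged = p1.merge(p2, on="pixel", suffixes=("_1", "_2"))
                    for _, m in merged.iterrows():
                        point_rows.append(
                            {"comparison": comp_name, "subject": subject,
                             "segment": int(m.segment_1),
                             "point": f"{view}:{m.pixel}",
                             "value_1": m.value_1, "value_2": m.value_2}
                        )

    unit_tables = pd.DataFrame(unit_rows)
    point_tables = pd.DataFrame(point_rows)
    reports = stats.comparison_suite(
        unit_tables if not unit_tables.empty else
        pd.DataFrame(columns=["comparison", "endpoint", "unit", "value_1", "value_2"]),
        point_tables if not point_tables.empty else None,
        mean_floor=config.cv_mean_floor,
    )
    report_df = pd.DataFrame([r.to_row() for r in reports])
    report_df.to_csv(os.path.join(outdir, "comparisons.csv"), index=False)
    with open(os.path.join(outdir, "comparisons.json"), "w") as f:
        json.dump(
            [
                {**r.to_row(), "segment_cv": r.segment_cv, "segment_icc": r.segment_icc}
                for r in reports
            ],
            f,
            indent=2,
            default=float,
        )
    for name, attr in (("bullseye_cv.csv", "segment_cv"), ("bullseye_icc.csv", "segment_icc")):
        rows = [
            {"comparison": r.comparison, "segment": seg, "value": v}
            for r in reports
            if r.endpoint == "segmental-Ecc"
            for seg, v in getattr(r, attr).items()
        ]
        pd.DataFrame(rows).to_csv(os.path.join(outdir, name), index=False)
    with open(os.path.join(outdir, "run_manifest.json"), "w") as f:
        json.dump(
            {
                "config": config.model_dump(),
                "n_subjects": int(n_total),
                "cohort_seed": cohort_seed,
                "stages": ["simulate", "qc", "analyze", "compare"],
            },
            f,
            indent=2,
        )
    return outdir
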