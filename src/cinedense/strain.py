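"""Strain tensors from trajectories and their reduction to study endpoints.

The local deformation gradient F at each material point is fit by least
squares over its reference-configuration neighbourhood (dx ~ F dX), the
Green-Lagrange tensor is E = (F'F - I)/2, and E is projected to the
circumferential/radial directions about the LV center of mass (short axis)
or the wall-centerline tangent (long axis).  Endpoints: whole-slice and
segmental strain-time curves, end-systolic values (end systole = frame of
minimum whole-slice Ecc, or Ell on the long axis), twist per slice, torsion
(the least-squares slope of end-systolic twist versus longitudinal position,
in degrees/cm), and global Ell (the mean of AHA segments 9 and 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import InputError
from .phase import MaterialTrajectories

AHA_BASAL = tuple(range(1, 7))
AHA_MID = tuple(range(7, 13))
AHA_APICAL = tuple(range(13, 17))

_LEVEL_BY_VIEW = {"SAX-base": "base", "SAX-mid": "mid", "SAX-apex": "apex"}


# ---------------------------------------------------------------------------
# tensor machinery

def deformation_gradient(
    traj: MaterialTrajectories,
    frame: int,
    neighborhood_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares deformation gradient per material point at one frame.

    For each point, the local map dx ~ F dX is fit over neighbours within
    ``neighborhood_radius`` (default 2.5 pixels) in the reference
    configuration.  Where at least 8 neighbours are available the fit
    includes quadratic terms and F is the Jacobian of that local model —
    at the wall boundary the neighbourhood is one-sided, and a purely
    linear fit there is biased by the curvature of the deformation field;
    for an affine local motion both fits coincide.  Points with fewer than
    3 neighbours, or with a collinear neighbour set, are flagged invalid
    rather than raising.  Returns (F, valid) with F of shape
    (n_points, 2, 2).
    """
    if neighborhood_radius is None:
        neighborhood_radius = 2.5 * traj.pixel_spacing
    h = neighborhood_radius
    X = traj.X
    x = traj.positions()[frame]
    ok = traj.valid[frame]
    n = X.shape[0]
    tree = cKDTree(X)
    pairs = tree.query_pairs(neighborhood_radius, output_type="ndarray")
    if pairs.size:
        edges = np.concatenate([pairs, pairs[:, ::-1]], axis=0)
        keep = ok[edges[:, 0]] & ok[edges[:, 1]]
        edges = edges[keep]
    else:
        edges = np.empty((0, 2), dtype=int)
    i, j = edges[:, 0], edges[:, 1]
    dX = (X[j] - X[i]) / h          # scaled for conditioning
    dx = x[j] - x[i]
    # basis: [dX1, dX2, dX1^2, dX1*dX2, dX2^2]; no intercept (dx(0) = 0)
    phi = np.stack([dX[:, 0], dX[:, 1], dX[:, 0] ** 2, dX[:, 0] * dX[:, 1], dX[:, 1] ** 2], axis=1)
    G = np.zeros((n, 5, 5))
    Y = np.zeros((n, 5, 2))
    count = np.zeros(n, dtype=int)
    np.add.at(G, i, phi[:, :, None] * phi[:, None, :])
    np.add.at(Y, i, phi[:, :, None] * dx[:, None, :])
    np.add.at(count, i, 1)
    # collinearity check on the linear sub-block sum(dX dX')
    M2 = G[:, :2, :2]
    tr = M2[:, 0, 0] + M2[:, 1, 1]
    det = M2[:, 0, 0] * M2[:, 1, 1] - M2[:, 0, 1] * M2[:, 1, 0]
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    eig_min = tr / 2 - disc
    eig_max = tr / 2 + disc
    valid = ok & (count >= 3) & (eig_min > 1e-8 * np.maximum(eig_max, 1e-300))
    F = np.tile(np.eye(2), (n, 1, 1))
    quad = valid & (count >= 8)
    lin = valid & ~quad
    if quad.any():
        Gq = G[quad] + 1e-12 * np.eye(5)
        coef = np.linalg.solve(Gq, Y[quad])        # (m, 5, 2)
        F[quad] = np.transpose(coef[:, :2, :], (0, 2, 1)) / h
    if lin.any():
        coef = np.linalg.solve(M2[lin], Y[lin, :2, :])
        F[lin] = np.transpose(coef, (0, 2, 1)) / h
    return F, valid


def green_strain(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange tensor E = (F'F - I)/2 (batched over leading axes)."""
    F = np.asarray(F, dtype=float)
    E = 0.5 * (np.einsum("...ji,...jk->...ik", F, F) - np.eye(2))
    return E


def polar_project(E: np.ndarray, X: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project E to circumferential/radial directions about the center C.

    ``e_r`` points from C to the reference position X; ``e_c`` is ``e_r``
    rotated +90 degrees (counter-clockwise).  Returns (Ecc, Err).
    """
    X = np.asarray(X, dtype=float)
    d = X - np.asarray(C, dtype=float)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise InputError("a point coincides with the LV center")
    e_r = d / norm
    e_c = np.stack([-e_r[..., 1], e_r[..., 0]], axis=-1)
    ecc = np.einsum("...i,...ij,...j->...", e_c, E, e_c)
    err = np.einsum("...i,...ij,...j->...", e_r, E, e_r)
    return ecc, err


def wall_centerline_tangents(
    X: np.ndarray,
    mitral_mid: np.ndarray,
    apex: np.ndarray,
    bin_width: float,
) -> np.ndarray:
    """Unit tangent of the wall centerline at each long-axis point.

    Points are split into the two walls by their transverse coordinate
    about the long axis (mitral-annulus midpoint -> apex).  Each wall's
    centerline is the midline of its points binned along the longitudinal
    coordinate; tangents come from central differences and each point takes
    the tangent of its bin.
    """
    X = np.asarray(X, dtype=float)
    l0 = np.asarray(apex, dtype=float) - np.asarray(mitral_mid, dtype=float)
    l0 = l0 / np.linalg.norm(l0)
    n0 = np.array([-l0[1], l0[0]])
    rel = X - np.asarray(mitral_mid, dtype=float)
    ell = rel @ l0
    tau = rel @ n0
    tangents = np.zeros_like(X)
    for side in (tau >= 0, tau < 0):
        if not side.any():
            continue
        e = ell[side]
        bins = np.floor((e - e.min()) / bin_width).astype(int)
        uniq = np.unique(bins)
        cl = np.empty((uniq.size, 2))
        order = {b: k for k, b in enumerate(uniq)}
        for k, b in enumerate(uniq):
            sel = bins == b
            cl[k] = [e[sel].mean(), tau[side][sel].mean()]
        srt = np.argsort(cl[:, 0])
        cl = cl[srt]
        rank = np.empty(uniq.size, dtype=int)
        rank[srt] = np.arange(uniq.size)
        if uniq.size >= 2:
            d = np.gradient(cl, axis=0)
        else:
            d = np.array([[1.0, 0.0]])
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        t_local = d[rank[np.vectorize(order.get)(bins)]]
        tangents[side] = t_local[:, :1] * l0 + t_local[:, 1:] * n0
    return tangents


def longitudinal_project(
    E: np.ndarray,
    X: np.ndarray,
    mitral_mid: np.ndarray,
    apex: np.ndarray,
    bin_width: float,
) -> np.ndarray:
    """Ell = e_l' E e_l with e_l the local wall-centerline tangent."""
    e_l = wall_centerline_tangents(X, mitral_mid, apex, bin_width)
    return np.einsum("...i,...ij,...j->...", e_l, E, e_l)


# ---------------------------------------------------------------------------
# segmentation bookkeeping

def assign_segments(
    points: np.ndarray, C: np.ndarray, rv_insertion: np.ndarray, level: str
) -> np.ndarray:
    """AHA segment id per short-axis point.

    The angular origin is the ray from the LV center of mass through the
    anterior RV insertion; angles grow counter-clockwise.  Basal and mid
    levels use six 60-degree sectors (ids 1-6 and 7-12), the apical level
    four 90-degree sectors (13-16); sectors are half-open [start, end).
    """
    if rv_insertion is None:
        raise InputError("missing RV-insertion landmark")
    points = np.asarray(points, dtype=float)
    d = points - np.asarray(C, dtype=float)
    ang = np.arctan2(d[..., 1], d[..., 0])
    rv = np.asarray(rv_insertion, dtype=float) - np.asarray(C, dtype=float)
    alpha = np.mod(ang - np.arctan2(rv[1], rv[0]), 2.0 * np.pi)
    if level in ("base", "mid"):
        sector = np.minimum((alpha // (np.pi / 3)).astype(int), 5)
        offset = 1 if level == "base" else 7
    elif level == "apex":
        sector = np.minimum((alpha // (np.pi / 2)).astype(int), 3)
        offset = 13
    else:
        raise InputError(f"unknown level {level!r}")
    return offset + sector


#: AHA ids of the segments a 4-chamber long-axis view cuts through,
#: by wall side and longitudinal third (base -> apex)
_LAX_IDS = {"septal": (3, 9, 14), "lateral": (6, 12, 16)}


def assign_segments_lax(
    points: np.ndarray, mitral_mid: np.ndarray, apex: np.ndarray
) -> np.ndarray:
    """AHA segment id per 4-chamber long-axis point.

    Each wall is split into basal / mid / apical thirds along the long axis;
    the wall on the positive transverse side of the mitral->apex axis is
    treated as septal (3, 9, 14), the other as lateral (6, 12, 16).
    """
    points = np.asarray(points, dtype=float)
    l0 = np.asarray(apex, dtype=float) - np.asarray(mitral_mid, dtype=float)
    length = np.linalg.norm(l0)
    l0 = l0 / length
    n0 = np.array([-l0[1], l0[0]])
    rel = points - np.asarray(mitral_mid, dtype=float)
    frac = np.clip((rel @ l0) / length, 0.0, 1.0 - 1e-12)
    third = (frac * 3).astype(int)
    side = np.where(rel @ n0 >= 0, 0, 1)
    ids = np.empty(points.shape[0], dtype=int)
    ids[side == 0] = np.asarray(_LAX_IDS["septal"])[third[side == 0]]
    ids[side == 1] = np.asarray(_LAX_IDS["lateral"])[third[side == 1]]
    return ids


# ---------------------------------------------------------------------------
# twist and torsion

def compute_twist(traj: MaterialTrajectories, C: np.ndarray, frame: int) -> float:
    """Mean signed angular displacement (degrees) of material points about C.

    Counter-clockwise positive in image orientation (viewing convention:
    apex to base); the angle of each point is measured between X - C and
    x(t) - C.
    """
    C = np.asarray(C, dtype=float)
    ok = traj.valid[frame]
    X = traj.X[ok] - C
    x = traj.positions()[frame][ok] - C
    cross = X[:, 0] * x[:, 1] - X[:, 1] * x[:, 0]
    dot = (X * x).sum(axis=1)
    return float(np.degrees(np.arctan2(cross, dot)).mean())


def compute_torsion(twists_deg: np.ndarray, z_mm: np.ndarray) -> float:
    """Least-squares slope of end-systolic twist versus z, in degrees/cm.

    z increases base to apex; counter-directional base/apex rotation (apex
    rotating counter-clockwise relative to the base) yields positive
    torsion.
    """
    twists_deg = np.asarray(twists_deg, dtype=float)
    z_cm = np.asarray(z_mm, dtype=float) / 10.0
    if twists_deg.size < 2:
        raise InputError("torsion requires twists from at least 2 slices")
    return float(np.polyfit(z_cm, twists_deg, 1)[0])


# ---------------------------------------------------------------------------
# per-slice strain field and summary

@dataclass
class StrainField:
    """Per-point, per-frame projected strain for one slice."""

    X: np.ndarray                 # (n_points, 2) reference positions, mm
    valid: np.ndarray             # (frames, n_points)
    ecc: np.ndarray | None        # (frames, n_points) SAX
    err: np.ndarray | None
    ell: np.ndarray | None        # LAX
    segments: np.ndarray          # (n_points,) AHA ids
    view: str
    times_ms: np.ndarray
    center_mm: np.ndarray | None = None
    slice_location: float = 0.0


@dataclass
class StrainSummary:
    """Whole-slice / segmental strain-time data for one slice."""

    view: str
    slice_location: float
    times_ms: np.ndarray
    es_frame: int
    ecc_curve: np.ndarray | None = None      # whole-slice mean per frame
    err_curve: np.ndarray | None = None
    ell_curve: np.ndarray | None = None
    segment_curves: dict = field(default_factory=dict)  # id -> (frames,) array
    twist_curve: np.ndarray | None = None    # degrees per frame (SAX)
    es_ecc: float | None = None
    es_err: float | None = None
    es_ell: float | None = None
    es_twist: float | None = None
    global_ell: float | None = None          # mean of AHA segments 9 and 12
    point_segments: np.ndarray | None = None
    point_es_values: np.ndarray | None = None  # ES Ecc (SAX) or Ell (LAX)
    point_valid_es: np.ndarray | None = None
    seed_pixels: np.ndarray | None = None


def compute_strain_field(
    traj: MaterialTrajectories,
    view: str,
    landmarks: dict,
    center_mm: np.ndarray | None = None,
    neighborhood_radius: float | None = None,
) -> StrainField:
    """Run F -> E -> projection -> segment assignment for every frame."""
    n_frames = traj.x_raw.shape[0]
    n_pts = traj.n_points
    spacing = traj.pixel_spacing
    is_sax = view.startswith("SAX")

    def lm(name):
        v = np.asarray(landmarks[name], dtype=float)
        return np.array([v[1] * spacing, v[0] * spacing])  # (row,col) px -> (x,y) mm

    ecc = np.full((n_frames, n_pts), np.nan) if is_sax else None
    err = np.full((n_frames, n_pts), np.nan) if is_sax else None
    ell = None if is_sax else np.full((n_frames, n_pts), np.nan)
    valid = np.zeros((n_frames, n_pts), dtype=bool)
    for k in range(n_frames):
        F, ok = deformation_gradient(traj, k, neighborhood_radius)
        E = green_strain(F)
        if is_sax:
            e_cc, e_rr = polar_project(E, traj.X, center_mm)
            ecc[k], err[k] = e_cc, e_rr
        else:
            ell[k] = longitudinal_project(
                E, traj.X, lm("mitral_mid"), lm("apex"), bin_width=2.0 * spacing
            )
        valid[k] = ok
    if is_sax:
        segments = assign_segments(
            traj.X, center_mm, lm("rv_insertion"), _LEVEL_BY_VIEW[view]
        )
    else:
        segments = assign_segments_lax(traj.X, lm("mitral_mid"), lm("apex"))
    return StrainField(
        X=traj.X,
        valid=valid,
        ecc=ecc,
        err=err,
        ell=ell,
        segments=segments,
        view=view,
        times_ms=traj.times_ms,
        center_mm=center_mm,
    )


def _masked_mean(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.where(valid, values, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(out, axis=1)


def strain_summary(
    fieldd: StrainField,
    traj: MaterialTrajectories | None = None,
    slice_location: float = 0.0,
) -> StrainSummary:
    """Reduce a strain field to whole-slice / segmental curves and ES values.

    End systole is the frame minimizing the whole-slice Ecc curve (Ell on
    the long axis); Err is read at that same frame.  The long-axis global
    Ell is the mean of the segment-9 and segment-12 end-systolic values.
    """
    is_sax = fieldd.view.startswith("SAX")
    primary = fieldd.ecc if is_sax else fieldd.ell
    curve = _masked_mean(primary, fieldd.valid)
    es_frame = int(np.nanargmin(curve))
    seg_curves = {}
    for seg in np.unique(fieldd.segments):
        sel = fieldd.segments == seg
        seg_curves[int(seg)] = _masked_mean(primary[:, sel], fieldd.valid[:, sel])
    summary = StrainSummary(
        view=fieldd.view,
        slice_location=slice_location,
        times_ms=fieldd.times_ms,
        es_frame=es_frame,
        segment_curves=seg_curves,
        point_segments=fieldd.segments,
        point_es_values=primary[es_frame],
        point_valid_es=fieldd.valid[es_frame],
        seed_pixels=traj.seed_pixels if traj is not None else None,
    )
    if is_sax:
        summary.ecc_curve = curve
        summary.err_curve = _masked_mean(fieldd.err, fieldd.valid)
        summary.es_ecc = float(curve[es_frame])
        summary.es_err = float(summary.err_curve[es_frame])
        if traj is not None and fieldd.center_mm is not None:
            summary.twist_curve = np.array(
                [compute_twist(traj, fieldd.center_mm, k) for k in range(len(curve))]
            )
            summary.es_twist = float(summary.twist_curve[es_frame])
    else:
        summary.ell_curve = curve
        summary.es_ell = float(curve[es_frame])
        mid = [seg_curves[s][es_frame] for s in (9, 12) if s in seg_curves]
        summary.global_ell = float(np.mean(mid)) if mid else None
    return summary
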