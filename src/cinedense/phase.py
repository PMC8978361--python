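"""Wrapped DENSE phase -> Lagrangian material-point trajectories.

Two stages of the measurement chain live here:

* **Phase unwrapping** — quality-guided region growing within the myocardial
  mask of each frame.  The quality map is the inverse local variance of the
  wrapped phase gradients in a 3x3 window (the standard "phase derivative
  variance" criterion); growth starts at the maximum-quality pixel and each
  new pixel is unwrapped against its best already-unwrapped neighbour.
  Frame-to-frame phase continuity fixes each frame's global 2*pi offset: the
  seed's unwrapped value is brought within pi of the previous frame's value
  at the same location.  The first frame's offset is fixed by the
  small-displacement assumption |u| < 1/(2*ke), i.e. its wrapped phase is
  taken as already unwrapped.

* **Tissue tracking** — the unwrapped phase gives the Eulerian displacement
  u at each current pixel (u points from the reference position to the
  current one).  The scattered map X = x - u(x) is inverted by interpolating
  u over the computed reference positions onto material points seeded on the
  reference-frame myocardial grid.  Near the mask edge, where a seed falls
  marginally outside the convex hull of the data, a local linear
  least-squares extrapolation from nearby data points is used; seeds farther
  outside are flagged invalid from that frame on.  Trajectories are
  optionally smoothed per coordinate by a least-squares polynomial in time.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, cKDTree

from .core import DenseSeries, InputError, RoiMask, wrap_phase


class TrackingError(RuntimeError):
    """Too few valid pixels to track a frame."""


@dataclass
class UnwrappedPhase:
    """Unwrapped phase per frame and encoding direction (NaN outside mask)."""

    phase_x: np.ndarray        # (frames, rows, cols)
    phase_y: np.ndarray
    disconnected: bool = False  # any frame's mask had >1 connected component


@dataclass
class DisplacementField:
    """Eulerian displacement in mm, sampled at current pixel positions.

    ``u_x``/``u_y`` are NaN outside the per-frame myocardial mask.  The
    vector at a pixel points from that material point's reference
    (first-frame) position to its current position.
    """

    u_x: np.ndarray            # (frames, rows, cols), mm
    u_y: np.ndarray
    pixel_spacing: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.u_x) & np.isfinite(self.u_y)


@dataclass
class MaterialTrajectories:
    """Lagrangian trajectories of material points seeded at the reference frame.

    ``x_raw[0] == X`` for valid points by construction; ``x_fit`` holds the
    temporally smoothed version when smoothing was applied.  ``valid`` is
    monotone: once a point drops out it stays invalid.
    """

    X: np.ndarray              # (n_points, 2) reference positions, mm (x, y)
    x_raw: np.ndarray          # (frames, n_points, 2) mm
    valid: np.ndarray          # (frames, n_points) bool
    seed_pixels: np.ndarray    # (n_points, 2) int (row, col)
    times_ms: np.ndarray
    pixel_spacing: float
    x_fit: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    def positions(self) -> np.ndarray:
        """Smoothed positions when available, raw otherwise."""
        return self.x_fit if self.x_fit is not None else self.x_raw


# ---------------------------------------------------------------------------
# unwrapping

_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _quality_map(phase: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Inverse local variance of wrapped phase gradients (3x3 windows)."""
    grads = []
    gx = np.zeros_like(phase)
    gx[:, :-1] = wrap_phase(np.diff(phase, axis=1))
    vx = np.zeros_like(mask, dtype=bool)
    vx[:, :-1] = mask[:, :-1] & mask[:, 1:]
    grads.append((gx, vx))
    gy = np.zeros_like(phase)
    gy[:-1, :] = wrap_phase(np.diff(phase, axis=0))
    vy = np.zeros_like(mask, dtype=bool)
    vy[:-1, :] = mask[:-1, :] & mask[1:, :]
    grads.append((gy, vy))
    total_var = np.zeros_like(phase)
    for g, v in grads:
        cnt = ndimage.uniform_filter(v.astype(float), size=3)
        s1 = ndimage.uniform_filter(np.where(v, g, 0.0), size=3)
        s2 = ndimage.uniform_filter(np.where(v, g * g, 0.0), size=3)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s1 / cnt, 0.0)
            var = np.where(cnt > 0, np.maximum(s2 / cnt - mean**2, 0.0), np.inf)
        total_var += var
    return 1.0 / (total_var + 1e-12)


def _unwrap_component(
    phase: np.ndarray, comp: np.ndarray, quality: np.ndarray
) -> tuple[np.ndarray, tuple[int, int]]:
    """Quality-guided region growing in one connected component.

    Returns the unwrapped values (NaN outside the component) and the seed
    pixel.  The seed keeps its wrapped value; ties in quality resolve to the
    lowest (row, col) index.
    """
    out = np.full(phase.shape, np.nan)
    q = np.where(comp, quality, -np.inf)
    seed_flat = int(np.argmax(q))  # first occurrence = lowest (row, col)
    seed = np.unravel_index(seed_flat, phase.shape)
    out[seed] = phase[seed]
    nrows, ncols = phase.shape
    visited = ~comp  # treat outside as done
    visited[seed] = True
    heap: list[tuple[float, int, int]] = []
    for dr, dc in _NEIGHBORS:
        r, c = seed[0] + dr, seed[1] + dc
        if 0 <= r < nrows and 0 <= c < ncols and not visited[r, c]:
            heapq.heappush(heap, (-quality[r, c], r, c))
            visited[r, c] = True
    while heap:
        _, r, c = heapq.heappop(heap)
        best = None
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and np.isfinite(out[rr, cc]):
                key = (quality[rr, cc], -rr, -cc)
                if best is None or key > best[0]:
                    best = (key, rr, cc)
        ref = out[best[1], best[2]]
        out[r, c] = phase[r, c] + 2.0 * np.pi * round((ref - phase[r, c]) / (2.0 * np.pi))
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and not visited[rr, cc]:
                heapq.heappush(heap, (-quality[rr, cc], rr, cc))
                visited[rr, cc] = True
    return out, seed


def _unwrap_stack(phase: np.ndarray, masks: np.ndarray) -> tuple[np.ndarray, bool]:
    n_frames = phase.shape[0]
    out = np.full(phase.shape, np.nan)
    disconnected = False
    prev = None
    for k in range(n_frames):
        mask = masks[k]
        if not mask.any():
            raise InputError(f"frame {k}: empty myocardial mask")
        quality = _quality_map(phase[k], mask)
        labels, n_comp = ndimage.label(mask)
        if n_comp > 1:
            disconnected = True
        frame_out = np.full(phase.shape[1:], np.nan)
        for comp_id in range(1, n_comp + 1):
            comp = labels == comp_id
            vals, seed = _unwrap_component(phase[k], comp, quality)
            if prev is not None:
                ref = prev[seed]
                if not np.isfinite(ref):
                    # mask moved: use the nearest valid pixel of the previous frame
                    valid_prev = np.argwhere(np.isfinite(prev))
                    tree = cKDTree(valid_prev)
                    _, j = tree.query(np.array(seed, dtype=float))
                    ref = prev[tuple(valid_prev[j])]
                k2pi = np.round((ref - vals[seed]) / (2.0 * np.pi))
                vals = vals + 2.0 * np.pi * k2pi
            frame_out[comp] = vals[comp]
        out[k] = frame_out
        prev = frame_out
    return out, disconnected


def unwrap_phase(series: DenseSeries, mask: RoiMask) -> UnwrappedPhase:
    """Unwrap both encoding directions of a series within the per-frame mask.

    The output differs from the input by an integer multiple of 2*pi at
    every masked pixel.  Disconnected mask components are unwrapped
    independently and flagged.
    """
    if mask.mask.shape != series.magnitude.shape:
        raise InputError("mask shape does not match series")
    ux, dis_x = _unwrap_stack(series.phase_x, mask.mask)
    uy, dis_y = _unwrap_stack(series.phase_y, mask.mask)
    return UnwrappedPhase(phase_x=ux, phase_y=uy, disconnected=dis_x or dis_y)


def to_displacement(unwrapped: UnwrappedPhase, ke: float, pixel_spacing: float) -> DisplacementField:
    """Convert unwrapped phase to displacement: ``u_d = phi_d / (2*pi*ke)`` (mm)."""
    if not ke > 0:
        raise InputError("encoding frequency ke must be > 0")
    factor = 1.0 / (2.0 * np.pi * ke)
    return DisplacementField(
        u_x=unwrapped.phase_x * factor,
        u_y=unwrapped.phase_y * factor,
        pixel_spacing=pixel_spacing,
    )


# ---------------------------------------------------------------------------
# tracking

def _pixel_positions(mask: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) mm positions and (row, col) indices of masked pixels."""
    rc = np.argwhere(mask)
    xy = np.stack([rc[:, 1] * spacing, rc[:, 0] * spacing], axis=-1)
    return xy, rc


def _interpolate_displacement(
    X_data: np.ndarray, u_data: np.ndarray, X_query: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear scattered interpolation of u with a local-polynomial edge fallback.

    Returns (u at query points, validity).  Queries outside the convex hull
    of the data (seeds at the mask rim) are extrapolated by a weighted local
    quadratic fit over data points within 3 pixels — the displacement field
    curves on the scale of the endocardial radius, so a linear fit biases
    the rim — degrading to a linear fit when fewer than 8 points are
    available and to invalid below 4 points.
    """
    tri = Delaunay(X_data)
    interp = LinearNDInterpolator(tri, u_data)
    u = interp(X_query)
    valid = np.isfinite(u).all(axis=-1)
    # an annular point cloud is triangulated across the cavity; interpolation
    # over those spanning simplices is meaningless, so reroute their queries
    # to the local fit
    simplex = tri.find_simplex(X_query)
    inside = simplex >= 0
    verts = tri.points[tri.simplices[simplex[inside]]]
    edge = np.stack(
        [
            np.linalg.norm(verts[:, 0] - verts[:, 1], axis=1),
            np.linalg.norm(verts[:, 1] - verts[:, 2], axis=1),
            np.linalg.norm(verts[:, 2] - verts[:, 0], axis=1),
        ]
    ).max(axis=0)
    oversized = np.zeros(len(X_query), dtype=bool)
    oversized[inside] = edge > 3.0 * spacing
    valid &= ~oversized
    u[oversized] = np.nan
    missing = np.nonzero(~valid)[0]
    if missing.size:
        tree = cKDTree(X_data)
        groups = tree.query_ball_point(X_query[missing], r=3.0 * spacing)
        for idx, neigh in zip(missing, groups):
            if len(neigh) < 4:
                continue
            P = (X_data[neigh] - X_query[idx]) / spacing
            cols = [np.ones(len(neigh)), P[:, 0], P[:, 1]]
            if len(neigh) >= 8:
                cols += [P[:, 0] ** 2, P[:, 0] * P[:, 1], P[:, 1] ** 2]
            A = np.stack(cols, axis=1)
            w = 1.0 / (1.0 + (P**2).sum(axis=1))
            Aw = A * w[:, None]
            G = Aw.T @ Aw + 1e-10 * np.eye(A.shape[1])
            try:
                coef = np.linalg.solve(G, Aw.T @ (u_data[neigh] * w[:, None]))
            except np.linalg.LinAlgError:
                continue
            u[idx] = coef[0]
            valid[idx] = True
    return u, valid


def track_trajectories(
    disp: DisplacementField,
    reference_mask: np.ndarray,
    times_ms: np.ndarray | None = None,
    smooth_degree: int | None = 6,
    min_frames_for_smoothing: int = 10,
) -> MaterialTrajectories:
    """Invert Eulerian displacement fields into material-point trajectories.

    Material points are seeded at the reference-frame mask pixels.  For each
    frame the data points are the masked current pixels x with computed
    reference positions X = x - u(x); u is interpolated over those reference
    positions and evaluated at the seeds.  Pass ``smooth_degree=None`` to
    disable temporal polynomial smoothing.
    """
    n_frames = disp.u_x.shape[0]
    if n_frames < 2:
        raise TrackingError("need at least 2 frames of displacement")
    spacing = disp.pixel_spacing
    if times_ms is None:
        times_ms = np.arange(n_frames, dtype=float)
    X_seeds, seed_rc = _pixel_positions(reference_mask, spacing)
    n_pts = X_seeds.shape[0]
    if n_pts < 3:
        raise TrackingError("fewer than 3 seed points in the reference mask")
    x = np.full((n_frames, n_pts, 2), np.nan)
    valid = np.zeros((n_frames, n_pts), dtype=bool)
    x[0] = X_seeds
    valid[0] = True
    alive = np.ones(n_pts, dtype=bool)
    for k in range(1, n_frames):
        vmask = disp.valid[k]
        if vmask.sum() < 3:
            raise TrackingError(f"frame {k}: fewer than 3 valid displacement pixels")
        xy_cur, _ = _pixel_positions(vmask, spacing)
        u_cur = np.stack([disp.u_x[k][vmask], disp.u_y[k][vmask]], axis=-1)
        X_data = xy_cur - u_cur
        u_at_seed, ok = _interpolate_displacement(X_data, u_cur, X_seeds, spacing)
        alive = alive & ok
        x[k, alive] = X_seeds[alive] + u_at_seed[alive]
        valid[k] = alive
    traj = MaterialTrajectories(
        X=X_seeds,
        x_raw=x,
        valid=valid,
        seed_pixels=seed_rc,
        times_ms=np.asarray(times_ms, dtype=float),
        pixel_spacing=spacing,
    )
    if smooth_degree is not None and n_frames >= min_frames_for_smoothing:
        traj.x_fit = _smooth_trajectories(traj, smooth_degree)
    return traj


def _smooth_trajectories(traj: MaterialTrajectories, degree: int) -> np.ndarray:
    """Least-squares polynomial fit of each coordinate's time course."""
    n_frames, n_pts, _ = traj.x_raw.shape
    t = traj.times_ms / traj.times_ms.max() if traj.times_ms.max() > 0 else traj.times_ms
    V = np.vander(t, degree + 1)
    out = traj.x_raw.copy()
    full = traj.valid.all(axis=0)
    if full.any():
        y = traj.x_raw[:, full, :].reshape(n_frames, -1)
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        out[:, full, :] = (V @ coef).reshape(n_frames, -1, 2)
    for j in np.nonzero(~full)[0]:
        n_ok = int(traj.valid[:, j].sum())
        if n_ok >= degree + 2:
            Vj = V[: n_ok]
            coef, *_ = np.linalg.lstsq(Vj, traj.x_raw[:n_ok, j, :], rcond=None)
            out[:n_ok, j, :] = Vj @ coef
    return out
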