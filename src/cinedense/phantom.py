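"""Analytic deforming-LV phantom rendered through the DENSE encoding equation.

The short-axis myocardium is modelled as an annulus deforming by an affine
radial map plus a rigid in-plane twist,

    r(R, t) = a(t) * R + b(t),      theta(Theta, z, t) = Theta + psi(z, t),

which gives closed-form principal stretches ``lambda_r = a`` and
``lambda_c = (a R + b) / R`` and hence exact Green-Lagrange strains

    Err = (a^2 - 1) / 2,            Ecc = (lambda_c^2 - 1) / 2.

The affine map was chosen over incompressible maps because it decouples the
transmural-mean Ecc and Err, which the target strain table prescribes
independently; phantom realism is subordinate to controllable ground truth.
The long-axis (4-chamber) phantom is a pair of straight wall strips under a
uniform longitudinal stretch ``lambda_l``, giving ``Ell = (lambda_l^2-1)/2``.

An optional septal "dysfunction" multiplier scales the deformation down over
a smooth angular window centred on the septum; the closed-form strain then
acquires the exact angular-derivative terms, which this module includes, so
the analytic strain remains an oracle for every configuration.

Geometry and twist are continuous functions of the slice position z, so a
repositioned second scan ("Scan B") can be rendered at perturbed z without
redefining the subject.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .core import DenseSeries, RoiMask, wrap_phase, write_series


class InfeasibleTargetError(ValueError):
    """Requested strain targets cannot be met by the deformation family."""


class GeometryError(ValueError):
    """Pixel grid too small to contain the phantom."""


class DomainError(ValueError):
    """Material point outside the reference myocardium."""


@dataclass
class PhantomSpec:
    """Complete parameterization of one synthetic subject.

    Radii taper linearly with z (base -> apex); the end-systolic twist is
    specified per short-axis slice and interpolated (linearly, with
    extrapolation) for intermediate slice positions.
    """

    r_endo_base: float = 25.0          # mm, at z = 0
    r_epi_base: float = 35.0
    taper_per_level: float = 0.10      # fractional radius loss per level
    level_spacing: float = 25.0        # mm between SAX levels
    sax_z: tuple[float, float, float] = (0.0, 25.0, 50.0)
    a_es: float = 1.0                  # radial stretch lambda_r at end systole
    target_mean_ecc: float = 0.0       # transmural-mean Ecc at end systole
    twists_es: tuple[float, float, float] = (0.0, 0.0, 0.0)  # deg, per SAX slice
    lambda_l_es: float = 1.0           # longitudinal stretch at end systole
    lax_length: float = 80.0           # mm, base-to-apex extent of LAX walls
    lax_cavity_halfwidth: float = 25.0  # mm
    lax_wall_thickness: float = 10.0   # mm
    n_frames: int = 40
    dt_ms: float = 15.0                # protocol temporal resolution
    t_es_ms: float = 345.0             # end-systolic time
    relax_fraction: float = 0.3        # activation at the last frame
    m0: float = 100.0                  # myocardial magnitude
    noise_sd: float = 0.0              # complex-noise SD
    rv_insertion_angle_deg: float = 180.0
    septal_reduction: float = 0.0      # deformation multiplier deficit in septum
    septal_halfwidth_deg: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_epi_base <= self.r_endo_base:
            raise InfeasibleTargetError("R_epi must exceed R_endo")
        if self.a_es <= 0:
            raise InfeasibleTargetError("a(t) must stay positive")
        if not (0 <= self.septal_reduction < 1):
            raise InfeasibleTargetError("septal_reduction must lie in [0, 1)")

    # -- time course --------------------------------------------------------

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms

    def activation(self, t_ms: np.ndarray | float) -> np.ndarray | float:
        """Activation s(t): sin^2 rise to 1 at t_es, then linear relaxation."""
        t = np.asarray(t_ms, dtype=float)
        t_end = (self.n_frames - 1) * self.dt_ms
        rise = np.sin(np.pi * t / (2.0 * self.t_es_ms)) ** 2
        if t_end > self.t_es_ms:
            fall = 1.0 + (self.relax_fraction - 1.0) * (t - self.t_es_ms) / (
                t_end - self.t_es_ms
            )
        else:
            fall = np.ones_like(t)
        return np.where(t <= self.t_es_ms, rise, fall)

    # -- geometry and coefficients as functions of z ------------------------

    def radii_at(self, z: float) -> tuple[float, float]:
        scale = 1.0 - self.taper_per_level * z / self.level_spacing
        if scale <= 0:
            raise GeometryError(f"taper collapses the annulus at z={z} mm")
        return self.r_endo_base * scale, self.r_epi_base * scale

    def b_es_at(self, z: float) -> float:
        """Radial-map offset hitting the transmural-mean Ecc target at z."""
        r_endo, r_epi = self.radii_at(z)
        return _solve_b(self.a_es, self.target_mean_ecc, r_endo, r_epi)

    def twist_es_at(self, z: float) -> float:
        f = interp1d(self.sax_z, self.twists_es, fill_value="extrapolate")
        return float(f(z))

    # -- septal modulation ---------------------------------------------------

    @property
    def septal_center_rad(self) -> float:
        # window centred one sector-pair into the septum from the RV insertion
        return np.deg2rad(self.rv_insertion_angle_deg + 120.0)

    def _modulation(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """g(Theta) in [1-m, 1] and its derivative dg/dTheta (radians)."""
        theta = np.asarray(theta, dtype=float)
        m = self.septal_reduction
        if m == 0.0:
            return np.ones_like(theta), np.zeros_like(theta)
        hw = np.deg2rad(self.septal_halfwidth_deg)
        delta = wrap_phase(theta - self.septal_center_rad)
        inside = np.abs(delta) < hw
        w = np.where(inside, np.cos(np.pi * delta / (2.0 * hw)) ** 2, 0.0)
        dw = np.where(
            inside,
            -np.pi / (2.0 * hw) * np.sin(np.pi * delta / hw),
            0.0,
        )
        return 1.0 - m * w, -m * dw

    def coefficients(
        self, theta_ref: np.ndarray, z: float, t_ms: float
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (A, B, psi_rad) of the map at reference angle(s) Theta."""
        s = float(self.activation(t_ms))
        g, _ = self._modulation(theta_ref)
        a_t = 1.0 + (self.a_es - 1.0) * s
        b_t = self.b_es_at(z) * s
        A = 1.0 + g * (a_t - 1.0)
        B = g * b_t
        psi = np.deg2rad(self.twist_es_at(z)) * s
        return A, B, psi

    def lambda_l(self, t_ms: float) -> float:
        s = float(self.activation(t_ms))
        return 1.0 + (self.lambda_l_es - 1.0) * s


def _solve_b(a: float, target_mean_ecc: float, r_endo: float, r_epi: float) -> float:
    """Offset b such that the area-weighted transmural-mean Ecc hits target.

    mean(lambda_c^2) over the annulus has the closed form
    ``a^2 + (4ab(Rp-Re) + 2 b^2 ln(Rp/Re)) / (Rp^2 - Re^2)``; setting it to
    ``2*Ecc + 1`` is a quadratic in b.
    """
    lam2 = 2.0 * target_mean_ecc + 1.0
    if lam2 <= 0:
        raise InfeasibleTargetError(
            f"target Ecc {target_mean_ecc} implies non-positive stretch^2"
        )
    span = r_epi**2 - r_endo**2
    alpha = 2.0 * np.log(r_epi / r_endo) / span
    beta = 4.0 * a * (r_epi - r_endo) / span
    gamma = a**2 - lam2
    disc = beta**2 - 4.0 * alpha * gamma
    if disc < 0:
        raise InfeasibleTargetError(
            f"no radial map with a={a:.4f} reaches mean Ecc {target_mean_ecc}"
        )
    roots = [(-beta + np.sqrt(disc)) / (2 * alpha), (-beta - np.sqrt(disc)) / (2 * alpha)]
    valid = [b for b in roots if a * r_endo + b > 0]
    if not valid:
        raise InfeasibleTargetError(
            "all candidate maps collapse the endocardium (r(R_endo) <= 0)"
        )
    return min(valid, key=abs)


# ---------------------------------------------------------------------------
# calibration

def calibrate_deformation(
    target_mean_ecc: float,
    target_mean_err: float,
    target_ell: float,
    target_twists_per_slice: Sequence[float],
    geometry: PhantomSpec | None = None,
    **overrides,
) -> PhantomSpec:
    """Build a PhantomSpec whose analytic end-systolic means hit the targets.

    ``Err`` is spatially constant for the affine radial map, so it fixes
    ``a = sqrt(2*Err + 1)``; the offset b is then solved per slice for the
    transmural-mean Ecc; ``Ell`` inverts algebraically to
    ``lambda_l = sqrt(2*Ell + 1)``.
    """
    for name, v in (("Ecc", target_mean_ecc), ("Err", target_mean_err), ("Ell", target_ell)):
        if v <= -0.5:
            raise InfeasibleTargetError(f"target {name}={v} implies stretch^2 <= 0")
    base = geometry if geometry is not None else PhantomSpec()
    a_es = float(np.sqrt(2.0 * target_mean_err + 1.0))
    lambda_l = float(np.sqrt(2.0 * target_ell + 1.0))
    spec = replace(
        base,
        a_es=a_es,
        target_mean_ecc=float(target_mean_ecc),
        lambda_l_es=lambda_l,
        twists_es=tuple(float(p) for p in target_twists_per_slice),
        **overrides,
    )
    for z in spec.sax_z:
        spec.b_es_at(z)  # raises InfeasibleTargetError if any slice fails
    return spec


def twists_for_torsion(
    spec_or_z: PhantomSpec | Sequence[float],
    torsion_deg_per_cm: float,
    base_twist_deg: float = -2.0,
) -> tuple[float, ...]:
    """Per-slice end-systolic twists varying linearly with z at a given slope."""
    z = spec_or_z.sax_z if isinstance(spec_or_z, PhantomSpec) else spec_or_z
    return tuple(base_twist_deg + torsion_deg_per_cm * zi / 10.0 for zi in z)


# ---------------------------------------------------------------------------
# closed-form displacement and strain

def analytic_displacement(
    spec: PhantomSpec, X: np.ndarray, t_ms: float, z: float
) -> np.ndarray:
    """Displacement u = x(X, t) - X (mm) at reference position(s) X.

    X is given in mm relative to the slice center, shape (..., 2) as (x, y).
    """
    X = np.asarray(X, dtype=float)
    R = np.hypot(X[..., 0], X[..., 1])
    theta = np.arctan2(X[..., 1], X[..., 0])
    r_endo, r_epi = spec.radii_at(z)
    if np.any(R < r_endo - 1e-9) or np.any(R > r_epi + 1e-9):
        raise DomainError("reference point outside the annulus")
    A, B, psi = spec.coefficients(theta, z, t_ms)
    r = A * R + B
    th = theta + psi
    x = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
    return x - X


def analytic_strain(
    spec: PhantomSpec, X: np.ndarray, t_ms: float, z: float | None = None, view: str = "SAX"
) -> tuple[np.ndarray, np.ndarray] | np.ndarray:
    """Exact Green-Lagrange strain at reference position(s) X.

    SAX: returns (Ecc, Err).  In the reference polar basis the deformation
    gradient is ``F = [[dr/dR, (dr/dTheta)/R], [0, r/R]]`` (the rigid twist
    contributes a rotation only), so

        Err = (A^2 - 1)/2
        Ecc = ((r_Theta/R)^2 + (r/R)^2 - 1)/2

    with the angular-derivative term exactly zero for an unmodulated
    (healthy) phantom.  LAX: returns Ell = (lambda_l^2 - 1)/2.
    """
    if view == "LAX":
        lam = spec.lambda_l(t_ms)
        val = 0.5 * (lam**2 - 1.0)
        X = np.asarray(X, dtype=float)
        return np.full(X.shape[:-1], val) if X.ndim > 1 else val
    assert z is not None
    X = np.asarray(X, dtype=float)
    R = np.hypot(X[..., 0], X[..., 1])
    theta = np.arctan2(X[..., 1], X[..., 0])
    r_endo, r_epi = spec.radii_at(z)
    if np.any(R < r_endo - 1e-9) or np.any(R > r_epi + 1e-9):
        raise DomainError("reference point outside the annulus")
    s = float(spec.activation(t_ms))
    g, dg = spec._modulation(theta)
    a_t = 1.0 + (spec.a_es - 1.0) * s
    b_t = spec.b_es_at(z) * s
    A = 1.0 + g * (a_t - 1.0)
    r = A * R + g * b_t
    r_theta = dg * ((a_t - 1.0) * R + b_t)
    err = 0.5 * (A**2 - 1.0)
    ecc = 0.5 * ((r_theta / R) ** 2 + (r / R) ** 2 - 1.0)
    return ecc, err


def analytic_mean_strains(
    spec: PhantomSpec, z: float, t_ms: float, n_r: int = 200, n_theta: int = 720
) -> tuple[float, float]:
    """Area-weighted transmural means of (Ecc, Err) by dense quadrature."""
    r_endo, r_epi = spec.radii_at(z)
    R = np.linspace(r_endo, r_epi, n_r)
    TH = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    Rg, THg = np.meshgrid(R, TH, indexing="ij")
    X = np.stack([Rg * np.cos(THg), Rg * np.sin(THg)], axis=-1)
    ecc, err = analytic_strain(spec, X, t_ms, z)
    w = Rg  # annular area element ~ R dR dTheta
    return float((ecc * w).sum() / w.sum()), float((err * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# rendering

_SAX_VIEW_BY_INDEX = {0: "SAX-base", 1: "SAX-mid", 2: "SAX-apex"}


def render_dense_series(
    spec: PhantomSpec,
    view: str,
    pixel_spacing: float,
    seed: int,
    encoding_frequency: float = 0.1,
    fov_mm: float = 120.0,
    z_override: float | None = None,
) -> tuple[DenseSeries, RoiMask]:
    """Render one slice of the phantom as a wrapped-phase DENSE series.

    The encoded phase per in-plane direction d is ``wrap(2*pi*ke*u_d)``;
    additive complex Gaussian noise of SD ``spec.noise_sd`` is applied to
    the complex image of each direction independently per frame, before
    magnitude/phase extraction.  The same seed gives bit-identical output.
    ``view`` is one of SAX-base / SAX-mid / SAX-apex / LAX-4CH; the ground
    truth ROI mask is derived from the analytic geometry.
    """
    n_px = int(round(fov_mm / pixel_spacing))
    c_mm = (n_px - 1) / 2.0 * pixel_spacing
    idx = np.arange(n_px) * pixel_spacing
    xg, yg = np.meshgrid(idx - c_mm, idx - c_mm, indexing="xy")
    # xg varies along columns (x direction), yg along rows (y direction)
    yg = yg.copy()
    times = spec.times_ms
    rng = np.random.default_rng(seed)
    mag = np.zeros((spec.n_frames, n_px, n_px))
    phx = np.zeros_like(mag)
    phy = np.zeros_like(mag)
    masks = np.zeros_like(mag, dtype=bool)

    if view.startswith("SAX"):
        slice_idx = {"SAX-base": 0, "SAX-mid": 1, "SAX-apex": 2}[view]
        z = spec.sax_z[slice_idx] if z_override is None else z_override
        r_endo, r_epi = spec.radii_at(z)
        if r_epi + 2 * pixel_spacing > fov_mm / 2.0:
            raise GeometryError("grid too small to contain the epicardium")
        for k, t in enumerate(times):
            r = np.hypot(xg, yg)
            th = np.arctan2(yg, xg)
            _, _, psi = spec.coefficients(0.0, z, t)
            theta_ref = th - psi
            A, B, _ = spec.coefficients(theta_ref, z, t)
            R = (r - B) / A
            m = (R >= r_endo) & (R <= r_epi)
            ux = np.where(m, xg - R * np.cos(theta_ref), 0.0)
            uy = np.where(m, yg - R * np.sin(theta_ref), 0.0)
            masks[k] = m
            mag[k], phx[k], phy[k] = _encode(
                m, ux, uy, spec.m0, spec.noise_sd, encoding_frequency, rng
            )
        ang = np.linspace(-np.pi, np.pi, 100, endpoint=False)
        endo = np.stack(
            [(c_mm + r_endo * np.sin(ang)) / pixel_spacing,
             (c_mm + r_endo * np.cos(ang)) / pixel_spacing], axis=-1)
        epi = np.stack(
            [(c_mm + r_epi * np.sin(ang)) / pixel_spacing,
             (c_mm + r_epi * np.cos(ang)) / pixel_spacing], axis=-1)
        rv_ang = np.deg2rad(spec.rv_insertion_angle_deg)
        landmarks = {
            "rv_insertion": np.array(
                [(c_mm + r_epi * np.sin(rv_ang)) / pixel_spacing,
                 (c_mm + r_epi * np.cos(rv_ang)) / pixel_spacing])
        }
        slice_location = z
    elif view == "LAX-4CH":
        L = spec.lax_length
        y_apex = L / 2.0
        cav, wall = spec.lax_cavity_halfwidth, spec.lax_wall_thickness
        if cav + wall + 2 * pixel_spacing > fov_mm / 2.0 or y_apex + 2 * pixel_spacing > fov_mm / 2.0:
            raise GeometryError("grid too small to contain the LAX walls")
        for k, t in enumerate(times):
            lam = spec.lambda_l(t)
            y_ref = y_apex + (yg - y_apex) / lam
            m = (
                (np.abs(xg) >= cav)
                & (np.abs(xg) <= cav + wall)
                & (y_ref >= -L / 2.0)
                & (y_ref <= L / 2.0)
            )
            uy = np.where(m, yg - y_ref, 0.0)
            ux = np.zeros_like(uy)
            masks[k] = m
            mag[k], phx[k], phy[k] = _encode(
                m, ux, uy, spec.m0, spec.noise_sd, encoding_frequency, rng
            )
        # cavity (endo) and outer (epi) wall rectangles as closed polygons
        def rect(x0, x1):
            pts = [(-L / 2, x0), (L / 2, x0), (L / 2, x1), (-L / 2, x1)]
            return np.array([[(c_mm + y) / pixel_spacing, (c_mm + x) / pixel_spacing]
                             for y, x in pts])
        endo = np.concatenate([rect(-cav, -cav), rect(cav, cav)])
        epi = np.concatenate([rect(-cav - wall, -cav - wall), rect(cav + wall, cav + wall)])
        landmarks = {
            "mitral_mid": np.array([(c_mm - L / 2.0) / pixel_spacing, c_mm / pixel_spacing]),
            "apex": np.array([(c_mm + L / 2.0) / pixel_spacing, c_mm / pixel_spacing]),
        }
        slice_location = 0.0
    else:
        raise ValueError(f"unknown view {view!r}")

    series = DenseSeries(
        magnitude=mag,
        phase_x=phx,
        phase_y=phy,
        trigger_times=times,
        pixel_spacing=pixel_spacing,
        encoding_frequency=encoding_frequency,
        view=view,
        slice_location=slice_location,
        landmarks=landmarks,
        noise_sd=spec.noise_sd,
    )
    roi = RoiMask(
        mask=masks,
        endo_contour=endo,
        epi_contour=epi,
        center=np.array([c_mm / pixel_spacing, c_mm / pixel_spacing]),
    )
    return series, roi


def _encode(mask, ux, uy, m0, noise_sd, ke, rng):
    """DENSE phase encoding with additive complex Gaussian noise."""
    out = []
    mags = []
    for u in (ux, uy):
        phase_true = wrap_phase(2.0 * np.pi * ke * u)
        z = m0 * mask * np.exp(1j * phase_true)
        if noise_sd > 0:
            z = z + noise_sd * (rng.standard_normal(z.shape) + 1j * rng.standard_normal(z.shape))
        out.append(wrap_phase(np.angle(z)))
        mags.append(np.abs(z))
    magnitude = 0.5 * (mags[0] + mags[1])
    return magnitude, out[0], out[1]


# ---------------------------------------------------------------------------
# cohort generation

#: strain-table means +/- SDs used as cohort sampling distributions
HEALTHY_DISTRIBUTIONS = {
    "ecc": (-0.18, 0.03),
    "err": (0.35, 0.16),
    "ell": (-0.15, 0.02),
    "torsion": (2.79, 0.75),
}
PATIENT_DISTRIBUTIONS = {
    "ecc": (-0.15, 0.05),
    "err": (0.28, 0.15),
    "ell": (-0.14, 0.04),
    "torsion": (2.43, 1.56),
}

_ALL_VIEWS = ("SAX-base", "SAX-mid", "SAX-apex", "LAX-4CH")


def render_cohort(
    n_healthy: int,
    n_patient: int,
    outdir: str | os.PathLike,
    seed: int,
    parameter_distributions: dict | None = None,
    pixel_spacing: float = 3.4,
    noise_sd: float = 4.0,
    scanb_z_offset: float = 2.0,
    septal_reduction_patient: float = 0.5,
    views: Sequence[str] = _ALL_VIEWS,
    n_frames: int = 40,
) -> pd.DataFrame:
    """Generate a duplicate-scan study cohort and write it to disk.

    Per subject, every requested view is rendered twice: Scan A at the
    nominal slice positions and Scan B with all z positions shifted by
    ``scanb_z_offset`` mm and independent noise, emulating removal and
    repositioning of the subject between scans.  Subject-level strain
    targets are drawn from group distributions (defaults above); patients
    additionally receive a septal deformation reduction.  Returns the
    manifest, also written to ``outdir/manifest.csv``.
    """
    if n_healthy + n_patient < 1:
        raise ValueError("cohort must contain at least one subject")
    dists = {"healthy": HEALTHY_DISTRIBUTIONS, "patient": PATIENT_DISTRIBUTIONS}
    if parameter_distributions:
        for grp, d in parameter_distributions.items():
            dists[grp] = {**dists[grp], **d}
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["healthy"] * n_healthy + ["patient"] * n_patient
    for i, group in enumerate(groups):
        subject = f"{group[:1]}{i:03d}"
        d = dists[group]
        ecc = min(rng.normal(*d["ecc"]), -0.02)
        err = max(rng.normal(*d["err"]), 0.02)
        ell = min(rng.normal(*d["ell"]), -0.02)
        torsion = rng.normal(*d["torsion"])
        spec = calibrate_deformation(
            ecc, err, ell,
            twists_for_torsion((0.0, 25.0, 50.0), torsion),
            noise_sd=noise_sd,
            n_frames=n_frames,
            septal_reduction=septal_reduction_patient if group == "patient" else 0.0,
            seed=int(rng.integers(2**31)),
        )
        for scan, z_off in (("A", 0.0), ("B", scanb_z_offset)):
            for view in views:
                render_seed = int(rng.integers(2**31))
                z_override = None
                if view.startswith("SAX"):
                    base_z = spec.sax_z[{"SAX-base": 0, "SAX-mid": 1, "SAX-apex": 2}[view]]
                    z_override = base_z + z_off
                series, roi = render_dense_series(
                    spec, view, pixel_spacing, render_seed, z_override=z_override
                )
                fname = f"{subject}_scan{scan}_{view}.h5"
                write_series(series, os.path.join(outdir, fname), mask=roi, force=True)
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "scan": scan,
                        "view": view,
                        "z": series.slice_location,
                        "path": fname,
                        "prescribed_ecc": ecc,
                        "prescribed_err": err,
                        "prescribed_ell": ell,
                        "prescribed_torsion": torsion,
                        "septal_reduction": spec.septal_reduction,
                        "noise_sd": noise_sd,
                        "render_seed": render_seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest
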