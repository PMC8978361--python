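"""Domain types, interchange I/O, and acquisition-level quality control.

A cine DENSE series is a stack of frames, each holding one magnitude image
and one wrapped-phase image per in-plane displacement-encoding direction.
Phase is proportional to the displacement accumulated since the encoding
instant (end diastole): ``phi_d = 2*pi*ke*u_d``, observed modulo 2*pi in
``(-pi, pi]``.  Series are stored on disk as a single HDF5 container with a
JSON metadata block, so round trips are bit-exact for arrays and lossless
for metadata.

Coordinate conventions: pixel indices are 0-based ``(row, col)``; physical
position in mm is ``index * pixel_spacing``; the x encoding direction is the
column axis and y is the row axis; slice location ``z`` (mm) increases from
base to apex.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

VIEWS = ("SAX-base", "SAX-mid", "SAX-apex", "LAX-4CH")
SAX_VIEWS = ("SAX-base", "SAX-mid", "SAX-apex")

#: slices with phase SNR below this were excluded from analysis
PHASE_SNR_THRESHOLD = 12.0


class MetadataError(ValueError):
    """A required metadata field is missing or malformed."""


class FormatError(ValueError):
    """The on-disk container layout is inconsistent (e.g. shape mismatch)."""


class InputError(ValueError):
    """An operation received invalid in-memory input."""


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase into the half-open interval ``(-pi, pi]``.

    ``wrap(pi) == pi`` and ``wrap(1.2*pi) == -0.8*pi``.
    """
    return phi - 2.0 * np.pi * np.ceil((np.asarray(phi) - np.pi) / (2.0 * np.pi))


@dataclass
class DenseSeries:
    """One cine DENSE slice acquisition (or simulation).

    Arrays are stacked frame-first: ``magnitude``, ``phase_x`` and
    ``phase_y`` all have shape ``(n_frames, n_rows, n_cols)``.  Phase is in
    radians, wrapped into ``(-pi, pi]``.
    """

    magnitude: np.ndarray
    phase_x: np.ndarray
    phase_y: np.ndarray
    trigger_times: np.ndarray          # ms, one per frame
    pixel_spacing: float               # mm/pixel, isotropic
    encoding_frequency: float          # ke, cycles/mm
    view: str                          # one of VIEWS
    slice_location: float              # z in mm, base -> apex increasing
    landmarks: dict = field(default_factory=dict)
    noise_sd: float | None = None      # complex-noise SD used at generation

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_x = wrap_phase(np.asarray(self.phase_x, dtype=float))
        self.phase_y = wrap_phase(np.asarray(self.phase_y, dtype=float))
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.magnitude.shape[1:]

    def validate(self) -> None:
        if self.magnitude.ndim != 3:
            raise FormatError("magnitude must be a (frames, rows, cols) stack")
        for name in ("phase_x", "phase_y"):
            arr = getattr(self, name)
            if arr.shape != self.magnitude.shape:
                raise FormatError(
                    f"{name} shape {arr.shape} != magnitude shape "
                    f"{self.magnitude.shape}"
                )
        if self.magnitude.shape[0] < 2:
            raise FormatError("a DENSE series needs at least 2 frames")
        if self.trigger_times.shape != (self.magnitude.shape[0],):
            raise FormatError("trigger_times must have one entry per frame")
        if not self.encoding_frequency > 0:
            raise MetadataError("encoding_frequency (ke) must be > 0")
        if not self.pixel_spacing > 0:
            raise MetadataError("pixel_spacing must be > 0")
        if self.view not in VIEWS:
            raise MetadataError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.view in SAX_VIEWS:
            if "rv_insertion" not in self.landmarks:
                raise MetadataError("SAX series requires 'rv_insertion' landmark")
        else:
            for key in ("mitral_mid", "apex"):
                if key not in self.landmarks:
                    raise MetadataError(f"LAX series requires {key!r} landmark")

    def frame_positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) physical coordinate grids in mm, shape (rows, cols)."""
        n_rows, n_cols = self.grid_shape
        y, x = np.meshgrid(
            np.arange(n_rows) * self.pixel_spacing,
            np.arange(n_cols) * self.pixel_spacing,
            indexing="ij",
        )
        return x, y


@dataclass
class RoiMask:
    """Myocardial region of interest.

    ``mask`` is a per-frame boolean stack.  Contours (closed polygons in
    ``(row, col)`` pixel coordinates) describe endo- and epicardium at the
    reference (first) frame; the LV center of mass ``C`` is derived from the
    reference contours.
    """

    mask: np.ndarray                   # (frames, rows, cols) bool
    endo_contour: np.ndarray           # (n, 2) pixel coords at reference frame
    epi_contour: np.ndarray
    center: np.ndarray = None          # C, (row, col) pixels; derived if None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.endo_contour = np.asarray(self.endo_contour, dtype=float)
        self.epi_contour = np.asarray(self.epi_contour, dtype=float)
        if self.center is None:
            self.center = self.epi_contour.mean(axis=0)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def reference_mask(self) -> np.ndarray:
        return self.mask[0]


# ---------------------------------------------------------------------------
# interchange I/O

_META_FIELDS = (
    "pixel_spacing",
    "encoding_frequency",
    "view",
    "slice_location",
    "landmarks",
)


def write_series(
    series: DenseSeries,
    path: str | os.PathLike,
    mask: RoiMask | None = None,
    force: bool = False,
) -> str:
    """Write a series (and optional ROI) to one HDF5 container.

    Refuses to overwrite an existing file unless ``force`` is given.  Phase
    is stored wrapped into ``(-pi, pi]`` regardless of what the caller
    constructed the series from.
    """
    path = os.fspath(path)
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    series.validate()
    meta = {
        "pixel_spacing": series.pixel_spacing,
        "encoding_frequency": series.encoding_frequency,
        "view": series.view,
        "slice_location": series.slice_location,
        "landmarks": {k: list(np.asarray(v, dtype=float)) for k, v in series.landmarks.items()},
        "noise_sd": series.noise_sd,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=series.magnitude)
        f.create_dataset("phase_x", data=wrap_phase(series.phase_x))
        f.create_dataset("phase_y", data=wrap_phase(series.phase_y))
        f.create_dataset("trigger_times", data=series.trigger_times)
        f.attrs["metadata"] = json.dumps(meta)
        if mask is not None:
            g = f.create_group("roi")
            g.create_dataset("mask", data=mask.mask)
            g.create_dataset("endo_contour", data=mask.endo_contour)
            g.create_dataset("epi_contour", data=mask.epi_contour)
            g.create_dataset("center", data=mask.center)
    return path


def read_series(path: str | os.PathLike) -> tuple[DenseSeries, RoiMask | None]:
    """Read a series container written by :func:`write_series`."""
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        try:
            meta = json.loads(f.attrs["metadata"])
        except KeyError as exc:
            raise MetadataError(f"{path}: missing metadata block") from exc
        for key in _META_FIELDS:
            if key not in meta or meta[key] is None:
                raise MetadataError(f"{path}: metadata lacks {key!r}")
        arrays = {}
        for name in ("magnitude", "phase_x", "phase_y", "trigger_times"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset {name!r}")
            arrays[name] = f[name][()]
        series = DenseSeries(
            magnitude=arrays["magnitude"],
            phase_x=arrays["phase_x"],
            phase_y=arrays["phase_y"],
            trigger_times=arrays["trigger_times"],
            pixel_spacing=float(meta["pixel_spacing"]),
            encoding_frequency=float(meta["encoding_frequency"]),
            view=str(meta["view"]),
            slice_location=float(meta["slice_location"]),
            landmarks={k: np.asarray(v, dtype=float) for k, v in meta["landmarks"].items()},
            noise_sd=meta.get("noise_sd"),
        )
        mask = None
        if "roi" in f:
            g = f["roi"]
            mask = RoiMask(
                mask=g["mask"][()],
                endo_contour=g["endo_contour"][()],
                epi_contour=g["epi_contour"][()],
                center=g["center"][()],
            )
    return series, mask


# ---------------------------------------------------------------------------
# quality control

_CORNER_PATCH = 8  # side length (pixels) of the four background corner patches


def phase_snr(series: DenseSeries, mask: RoiMask) -> float:
    """Phase signal-to-noise ratio of a series.

    Operationalized as mean myocardial magnitude divided by the standard
    deviation of the complex background noise, because phase noise is
    approximately the reciprocal of the magnitude SNR.  The background noise
    SD is estimated from four 8x8 corner patches of the magnitude images
    (across all frames), whose values are Rayleigh distributed with mean
    ``sigma*sqrt(pi/2)`` when only noise is present.  Returns ``inf`` for a
    noise-free background.
    """
    m = mask.mask
    if m.shape != series.magnitude.shape:
        raise InputError("mask shape does not match series")
    if not m.any():
        raise InputError("empty myocardial mask")
    signal = float(series.magnitude[m].mean())
    p = _CORNER_PATCH
    corners = [
        series.magnitude[:, :p, :p],
        series.magnitude[:, :p, -p:],
        series.magnitude[:, -p:, :p],
        series.magnitude[:, -p:, -p:],
    ]
    bg = np.concatenate([c.ravel() for c in corners])
    sigma = float(bg.mean()) * np.sqrt(2.0 / np.pi)
    if sigma == 0.0:
        return float("inf")
    return signal / sigma


def quality_filter(
    pairs: Sequence[tuple[DenseSeries, RoiMask]],
    threshold: float = PHASE_SNR_THRESHOLD,
    report_path: str | os.PathLike | None = None,
) -> tuple[list[tuple[DenseSeries, RoiMask]], list[tuple[DenseSeries, RoiMask]]]:
    """Partition series into (kept, discarded) by the phase-SNR cut.

    A series is discarded when its phase SNR is *less than* the threshold;
    a series exactly at the threshold is kept.  An optional CSV report lists
    per-series SNR and the decision.
    """
    kept, discarded, rows = [], [], []
    for i, (series, mask) in enumerate(pairs):
        snr = phase_snr(series, mask)
        keep = snr >= threshold
        (kept if keep else discarded).append((series, mask))
        rows.append(
            {
                "index": i,
                "view": series.view,
                "slice_location": series.slice_location,
                "phase_snr": snr,
                "kept": keep,
                "reason": "" if keep else f"phase SNR {snr:.2f} < {threshold}",
            }
        )
    if report_path is not None:
        pd.DataFrame(rows).to_csv(report_path, index=False)
    return kept, discarded
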