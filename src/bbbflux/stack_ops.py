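"""Hyperstack handling: I/O, Z-projection, vessel segmentation, ROIs, traces.

A hyperstack is the 4D (time, depth, row, col) image series produced by
two-photon time-lapse acquisition. Every quantification arm starts here:
the stack is reduced by maximum-intensity projection along depth, the
vasculature is segmented on a baseline frame, regions of interest (ROIs)
are placed either in vessel-free parenchyma or inside a vessel lumen, and
mean-intensity traces are extracted over time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, morphology

from .errors import (
    MetadataError,
    PlacementError,
    SegmentationError,
    ShapeError,
    TraceError,
)

_METADATA_FIELDS = ("pixel_size_um", "z_step_um", "frame_interval_min")


@dataclass
class Hyperstack:
    """4D intensity grid (T, Z, Y, X) with acquisition metadata.

    ``t0_min`` is the session time of the first frame; the timestamp of
    frame ``i`` is ``t0_min + i * frame_interval_min`` (frame start).
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    frame_interval_min: float
    t0_min: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ShapeError(f"expected 4D (T,Z,Y,X), got {self.data.ndim}D")
        if (
            np.issubdtype(self.data.dtype, np.floating)
            or np.issubdtype(self.data.dtype, np.signedinteger)
        ) and (self.data < 0).any():
            raise ValueError("intensities must be non-negative")
        for name in _METADATA_FIELDS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise MetadataError(f"{name} must be finite and > 0, got {v}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def times_min(self) -> np.ndarray:
        return self.t0_min + np.arange(self.n_timepoints) * self.frame_interval_min


@dataclass
class RoiSet:
    """Square ROIs on the projected 2D grid, as (row, col, height, width)."""

    rois: list[tuple[int, int, int, int]]
    compartment: str  # "parenchyma" | "blood"

    def __post_init__(self):
        if self.compartment not in ("parenchyma", "blood"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        for r in self.rois:
            if r[2] <= 0 or r[3] <= 0:
                raise ValueError("ROI height/width must be positive")

    def union_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for (r, c, h, w) in self.rois:
            m[r : r + h, c : c + w] = True
        return m


@dataclass
class IntensityTrace:
    """A time-stamped 1D signal from one compartment."""

    times_min: np.ndarray
    values: np.ndarray
    units: str = "raw_au"  # "raw_au" | "relative"
    compartment: str = "parenchyma"

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise TraceError("times and values must have the same length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise TraceError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise TraceError("trace values must be finite")

    def window(self, t_start: float, t_end: float, atol: float = 1e-9
               ) -> "IntensityTrace":
        """Slice the samples with t_start <= t <= t_end."""
        sel = (self.times_min >= t_start - atol) & (self.times_min <= t_end + atol)
        return replace(self, times_min=self.times_min[sel], values=self.values[sel])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "value": self.values,
                "units": self.units,
                "compartment": self.compartment,
            }
        )


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_hyperstack(stack: Hyperstack, path: str | Path) -> Path:
    """Write a hyperstack as a multi-page TIFF (T*Z pages) + JSON sidecar."""
    path = Path(path)
    t, z, y, x = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(t * z, y, x),
                     photometric="minisblack")
    meta = {
        "n_timepoints": t,
        "n_planes": z,
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "frame_interval_min": stack.frame_interval_min,
        "t0_min": stack.t0_min,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_hyperstack(path: str | Path) -> Hyperstack:
    """Read a hyperstack written by :func:`write_hyperstack`.

    Raises :class:`MetadataError` naming any absent sidecar field and
    :class:`ShapeError` if the page count disagrees with the declared shape.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for name in ("n_timepoints", "n_planes", *_METADATA_FIELDS):
        if name not in meta:
            raise MetadataError(f"metadata field {name!r} missing from {sidecar}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    t, z = int(meta["n_timepoints"]), int(meta["n_planes"])
    if pages.shape[0] != t * z:
        raise ShapeError(
            f"{pages.shape[0]} pages inconsistent with declared T={t}, Z={z}"
        )
    data = pages.reshape(t, z, pages.shape[1], pages.shape[2])
    return Hyperstack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        frame_interval_min=float(meta["frame_interval_min"]),
        t0_min=float(meta.get("t0_min", 0.0)),
    )


def write_label_volume(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16),
                     photometric="minisblack")
    return path


def read_label_volume(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


# ---------------------------------------------------------------------------
# Projection and segmentation


def max_project(stack: Hyperstack) -> np.ndarray:
    """Maximum-intensity projection along depth; shape (T, Y, X)."""
    return stack.data.max(axis=1)


def segment_vasculature(
    baseline_frame: np.ndarray,
    closing_radius: int = 1,
    min_size_px: int = 20,
) -> np.ndarray:
    """Binary vessel mask from the first projected frame with tracer present.

    Global Otsu threshold, morphological closing (disk radius 1 px) and
    removal of connected components smaller than ``min_size_px``. The Otsu
    threshold is computed on the frame's own histogram, so the mask is
    invariant to adding a constant offset to every pixel.
    """
    frame = np.asarray(baseline_frame, dtype=float)
    if frame.ndim != 2:
        raise ShapeError("baseline frame must be 2D")
    if np.ptp(frame) == 0:
        raise SegmentationError("blank frame: no contrast to segment")
    thr = filters.threshold_otsu(frame)
    mask = frame > thr
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = morphology.remove_small_objects(mask, max_size=min_size_px - 1)
    if not mask.any():
        raise SegmentationError("no foreground component survived filtering")
    return mask


# ---------------------------------------------------------------------------
# ROI placement


def _place_square_rois(
    allowed: np.ndarray,
    roi_size_px: int,
    n_rois: int,
    rng: np.random.Generator,
    max_attempts_per_roi: int = 2000,
) -> list[tuple[int, int, int, int]]:
    h, w = allowed.shape
    s = roi_size_px
    if s > h or s > w:
        raise PlacementError("ROI larger than the frame", achieved=0)
    # summed-area test: an ROI is valid iff all its pixels are allowed
    ok = ndimage.uniform_filter(allowed.astype(float), size=s, mode="constant")
    # centers of valid s x s squares, converted to top-left corners
    half = s // 2
    rois: list[tuple[int, int, int, int]] = []
    attempts = 0
    budget = max_attempts_per_roi * n_rois
    while len(rois) < n_rois and attempts < budget:
        attempts += 1
        r = int(rng.integers(0, h - s + 1))
        c = int(rng.integers(0, w - s + 1))
        if allowed[r : r + s, c : c + s].all():
            rois.append((r, c, s, s))
    if len(rois) < n_rois:
        # exhaustive feasibility count for the error message
        centers = ok > 1 - 1e-9
        n_possible = int(
            centers[half : h - (s - 1 - half), half : w - (s - 1 - half)].sum()
        )
        raise PlacementError(
            f"placed {len(rois)}/{n_rois} ROIs; ~{n_possible} valid positions exist",
            achieved=len(rois),
        )
    return rois


def place_parenchymal_rois(
    mask: np.ndarray,
    roi_size_px: int = 8,
    n_rois: int = 10,
    seed: int = 0,
    dilation_px: int = 3,
) -> RoiSet:
    """Place square ROIs in parenchyma, excluding the dilated vessel mask.

    The vessel mask is dilated by ``dilation_px`` so that the perivascular
    halo stays out of the parenchymal signal. Placement is uniform random
    with rejection and deterministic under ``seed``; if fewer than
    ``n_rois`` placements exist a :class:`PlacementError` reports the
    achievable count.
    """
    mask = np.asarray(mask, dtype=bool)
    excluded = morphology.dilation(mask, morphology.disk(dilation_px)) \
        if dilation_px > 0 else mask
    rng = np.random.default_rng(seed)
    rois = _place_square_rois(~excluded, roi_size_px, n_rois, rng)
    return RoiSet(rois=rois, compartment="parenchyma")


def place_blood_rois(
    mask: np.ndarray,
    roi_size_px: int = 4,
    n_rois: int = 3,
    seed: int = 0,
    erosion_px: int = 1,
) -> RoiSet:
    """Place square ROIs fully inside vessel lumina (eroded vessel mask)."""
    mask = np.asarray(mask, dtype=bool)
    allowed = morphology.erosion(mask, morphology.disk(erosion_px)) \
        if erosion_px > 0 else mask
    rng = np.random.default_rng(seed)
    rois = _place_square_rois(allowed, roi_size_px, n_rois, rng)
    return RoiSet(rois=rois, compartment="blood")


# ---------------------------------------------------------------------------
# Traces


def extract_trace(
    frames: np.ndarray,
    roiset: RoiSet,
    frame_interval_min: float = 1.0,
    t0_min: float = 0.0,
) -> IntensityTrace:
    """Mean intensity over the union of ROI pixels at each timepoint."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ShapeError("frames must be 3D (T, Y, X)")
    union = roiset.union_mask(frames.shape[1:])
    if not union.any():
        raise TraceError("empty ROI union")
    values = frames[:, union].mean(axis=1)
    times = t0_min + np.arange(frames.shape[0]) * frame_interval_min
    return IntensityTrace(times, values, units="raw_au",
                          compartment=roiset.compartment)


def relative_change(trace: IntensityTrace, baseline_offset: float = 0.0
                    ) -> IntensityTrace:
    """Express a raw trace as fractional change over its first value.

    ``value_t = (F_t - F_0) / (F_0 + baseline_offset)``, so the first value
    is exactly 0. ``baseline_offset`` restores a previously subtracted
    constant background to the denominator, reproducing the
    fraction-of-measured-baseline convention while the numerator remains
    the background-free increase.
    """
    if trace.values.size == 0:
        raise TraceError("empty trace")
    f0 = trace.values[0]
    denom = f0 + baseline_offset
    if denom <= 0:
        raise TraceError(
            f"baseline {denom:.4g} <= 0 (background subtraction overshoot?)"
        )
    values = (trace.values - f0) / denom
    values[0] = 0.0
    return IntensityTrace(trace.times_min.copy(), values, units="relative",
                          compartment=trace.compartment)
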