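"""Transcytosis quantification: wall-vesicle puncta per vessel surface.

Albumin conjugate taken up by the endothelium appears as discrete bright
puncta on vessel walls. The statistic is the vesicle surface density:
distinct puncta per 100 um^2 of vessel surface (surface = pi * d * L),
resolved over time and aggregated per vessel category. Counting is
cumulative — puncta persist, so per-vessel density is non-decreasing,
matching the non-saturating uptake kinetics seen in vivo.

Detection is automated with Laplacian-of-Gaussian blob detection
restricted to a wall band around the segmented vessel boundary, plus a
robust median + m*MAD intensity threshold (scale-invariant, so a global
detector-gain change does not alter counts). Distinct-punctum identity
across timepoints uses nearest-neighbour linking within 1 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import feature, morphology

from .errors import TraceError
from .vessels import VesselSegment, classify_vessel, vessel_surface_area

__all__ = [
    "VesicleDetection",
    "VesicleDensityRecord",
    "DetectionParams",
    "classify_vessel",
    "vessel_surface_area",
    "detect_vesicles",
    "link_detections",
    "assign_to_vessels",
    "density_kinetics",
    "rate_recovery",
    "analyze_vesicle_frames",
]


@dataclass(frozen=True)
class VesicleDetection:
    """One detected punctum on the projected grid."""

    time_min: float
    row: float
    col: float
    peak_intensity: float
    radius_um: float
    vessel_id: int | None = None
    punctum_id: int | None = None  # identity across timepoints after linking


@dataclass(frozen=True)
class VesicleDensityRecord:
    """Cumulative distinct-punctum count of one vessel at one timepoint."""

    vessel_id: int
    category: str
    time_min: float
    count: int
    surface_area_um2: float

    def __post_init__(self):
        if self.surface_area_um2 <= 0:
            raise ValueError("surface area must be > 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")

    @property
    def density_per_100um2(self) -> float:
        return 100.0 * self.count / self.surface_area_um2


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the blob detector.

    ``radius_band_um`` is the accepted punctum radius range; ``mad_factor``
    sets the intensity threshold at wall-band median + m*MAD; ``wall_margin_px``
    is the half-width of the band around the vessel boundary;
    ``log_threshold`` applies to the MAD-normalized frame, keeping the
    detector invariant to global gain.
    """

    radius_band_um: tuple[float, float] = (0.25, 1.5)
    mad_factor: float = 12.0
    wall_margin_px: int = 2
    log_threshold: float = 8.0
    num_sigma: int = 6


def wall_band(vessel_mask: np.ndarray, margin_px: int = 2) -> np.ndarray:
    """Band of pixels around the vessel boundary (boundary +/- margin)."""
    mask = np.asarray(vessel_mask, dtype=bool)
    selem = morphology.disk(margin_px)
    band = morphology.dilation(mask, selem) & ~morphology.erosion(
        mask, selem
    )
    if not band.any():
        raise TraceError("empty wall band")
    return band


def detect_vesicles(
    projected_frames: np.ndarray,
    vessel_mask: np.ndarray,
    pixel_size_um: float,
    frame_times_min: np.ndarray | None = None,
    params: DetectionParams | None = None,
) -> list[VesicleDetection]:
    """Multi-scale LoG blob detection restricted to the vessel wall band.

    Puncta accumulate over the session, so each frame is reduced to its
    difference from the first (pre-uptake) frame, which removes the static
    vessel structure; the difference is then MAD-normalized over the wall
    band, making counts invariant to detector gain. Detections outside the
    band, outside the radius band, or with a difference peak below
    band median + m*MAD are discarded.
    """
    params = params or DetectionParams()
    frames = np.asarray(projected_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    band = wall_band(vessel_mask, params.wall_margin_px)
    if frame_times_min is None:
        frame_times_min = np.arange(frames.shape[0], dtype=float)
    r_lo, r_hi = params.radius_band_um
    sigma_lo = max(r_lo / pixel_size_um / np.sqrt(2.0), 0.5)
    sigma_hi = max(r_hi / pixel_size_um / np.sqrt(2.0), sigma_lo + 0.5)
    baseline = frames[0]
    detections: list[VesicleDetection] = []
    for i in range(1, frames.shape[0]):
        raw_diff = frames[i] - baseline
        band_vals = raw_diff[band]  # robust stats before clipping
        med = float(np.median(band_vals))
        mad = float(np.median(np.abs(band_vals - med)))
        scale = mad if mad > 0 else max(band_vals.std(), 1e-9)
        diff = np.clip(raw_diff, 0.0, None)
        blobs = feature.blob_log(
            diff / scale,
            min_sigma=sigma_lo,
            max_sigma=sigma_hi,
            num_sigma=params.num_sigma,
            threshold=params.log_threshold,
        )
        thr = med + params.mad_factor * scale
        for row, col, sigma in blobs:
            r, c = int(round(row)), int(round(col))
            if not band[r, c]:
                continue
            peak = float(diff[r, c])
            if peak < thr:
                continue
            radius_um = float(sigma * np.sqrt(2.0) * pixel_size_um)
            if not (r_lo <= radius_um <= r_hi * 1.5):
                continue
            detections.append(
                VesicleDetection(
                    time_min=float(frame_times_min[i]),
                    row=float(row),
                    col=float(col),
                    peak_intensity=peak,
                    radius_um=radius_um,
                )
            )
    return detections


def link_detections(
    detections: list[VesicleDetection],
    pixel_size_um: float,
    link_radius_um: float = 1.0,
) -> list[VesicleDetection]:
    """Assign punctum identities across timepoints by nearest neighbour.

    A detection within ``link_radius_um`` of a punctum known from any
    earlier frame inherits its identity; otherwise it founds a new
    punctum. Unlinked reappearances therefore count as new puncta.
    """
    r_px = link_radius_um / pixel_size_um
    times = sorted({d.time_min for d in detections})
    known_pos: list[tuple[float, float]] = []
    linked: list[VesicleDetection] = []
    for t in times:
        frame_dets = [d for d in detections if d.time_min == t]
        if known_pos:
            cost = np.array(
                [
                    [np.hypot(d.row - p[0], d.col - p[1]) for p in known_pos]
                    for d in frame_dets
                ]
            )
        else:
            cost = np.empty((len(frame_dets), 0))
        assigned: dict[int, int] = {}
        if cost.size:
            rows, cols = linear_sum_assignment(cost)
            for ri, ci in zip(rows, cols):
                if cost[ri, ci] <= r_px:
                    assigned[ri] = ci
        for idx, d in enumerate(frame_dets):
            if idx in assigned:
                pid = assigned[idx]
            else:
                pid = len(known_pos)
                known_pos.append((d.row, d.col))
            linked.append(
                VesicleDetection(
                    time_min=d.time_min,
                    row=d.row,
                    col=d.col,
                    peak_intensity=d.peak_intensity,
                    radius_um=d.radius_um,
                    vessel_id=d.vessel_id,
                    punctum_id=pid,
                )
            )
    return linked


def assign_to_vessels(
    detections: list[VesicleDetection],
    label_projection: np.ndarray,
    max_distance_px: int = 4,
) -> list[VesicleDetection]:
    """Attach each detection to the nearest vessel label within reach.

    ``label_projection`` is the 2D max-projection of the label volume;
    detections sit on the wall band which extends slightly outside the
    footprint, so the nearest nonzero label within ``max_distance_px`` is
    used. Unassignable detections keep ``vessel_id=None``.
    """
    labels2d = np.asarray(label_projection)
    # nearest-label map via distance transform on the background
    dist, (iy, ix) = ndimage.distance_transform_edt(
        labels2d == 0, return_indices=True
    )
    out = []
    for d in detections:
        r, c = int(round(d.row)), int(round(d.col))
        r = min(max(r, 0), labels2d.shape[0] - 1)
        c = min(max(c, 0), labels2d.shape[1] - 1)
        if dist[r, c] <= max_distance_px:
            vid = int(labels2d[iy[r, c], ix[r, c]])
        else:
            vid = None
        out.append(
            VesicleDetection(
                time_min=d.time_min,
                row=d.row,
                col=d.col,
                peak_intensity=d.peak_intensity,
                radius_um=d.radius_um,
                vessel_id=vid,
                punctum_id=d.punctum_id,
            )
        )
    return out


def density_kinetics(
    detections: list[VesicleDetection],
    segments: list[VesselSegment],
    timepoints_min: np.ndarray,
) -> list[VesicleDensityRecord]:
    """Cumulative distinct-punctum density per vessel and timepoint.

    For every vessel and timepoint, the number of distinct puncta
    (``punctum_id``) seen up to and including that time, normalized per
    100 um^2 of the vessel's pi*d*L surface. Detections without a vessel
    assignment are ignored here (they are never silently dropped upstream:
    they remain in the detection list).
    """
    timepoints_min = np.asarray(timepoints_min, dtype=float)
    first_seen: dict[int, dict[int, float]] = {s.id: {} for s in segments}
    for d in detections:
        if d.vessel_id is None or d.vessel_id not in first_seen:
            continue
        pid = d.punctum_id if d.punctum_id is not None else id(d)
        seen = first_seen[d.vessel_id]
        if pid not in seen or d.time_min < seen[pid]:
            seen[pid] = d.time_min
    records = []
    for seg in segments:
        area = seg.surface_area_um2
        arrivals = np.sort(np.array(list(first_seen[seg.id].values())))
        for t in timepoints_min:
            count = int(np.searchsorted(arrivals, t, side="right"))
            records.append(
                VesicleDensityRecord(
                    vessel_id=seg.id,
                    category=seg.category,
                    time_min=float(t),
                    count=count,
                    surface_area_um2=area,
                )
            )
    return records


def records_frame(records: list[VesicleDensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "vessel_id": r.vessel_id,
                "category": r.category,
                "time_min": r.time_min,
                "count": r.count,
                "surface_area_um2": r.surface_area_um2,
                "density_per_100um2": r.density_per_100um2,
            }
            for r in records
        ],
        columns=[
            "vessel_id",
            "category",
            "time_min",
            "count",
            "surface_area_um2",
            "density_per_100um2",
        ],
    )


def category_aggregate(records: list[VesicleDensityRecord]) -> pd.DataFrame:
    """Per-category mean density with SEM over vessels, per timepoint."""
    df = records_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["category", "time_min", "n_vessels", "mean", "sem"]
        )
    g = df.groupby(["category", "time_min"])["density_per_100um2"]
    out = g.agg(["count", "mean", "sem"]).reset_index()
    return out.rename(columns={"count": "n_vessels"})


def rate_recovery(
    records: list[VesicleDensityRecord],
) -> dict[str, float]:
    """Per-category vesicle appearance rate from the density time course.

    Least-squares slope through the origin of the category-mean density
    versus time; under the cumulative Poisson model the expected density
    is ``rate * t``, so the slope estimates the configured rate per
    100 um^2 per min.
    """
    df = records_frame(records)
    if df.empty:
        return {}
    out: dict[str, float] = {}
    for cat, sub in df.groupby("category"):
        mean_by_t = sub.groupby("time_min")["density_per_100um2"].mean()
        t = mean_by_t.index.to_numpy(dtype=float)
        y = mean_by_t.to_numpy(dtype=float)
        if t.size < 2:
            raise TraceError(f"category {cat}: need >= 2 timepoints")
        denom = float(np.sum(t * t))
        out[cat] = float(np.sum(t * y) / denom) if denom > 0 else 0.0
    return out


def analyze_vesicle_frames(
    projected_frames: np.ndarray,
    labels: np.ndarray,
    segments: list[VesselSegment],
    pixel_size_um: float,
    frame_times_min: np.ndarray,
    params: DetectionParams | None = None,
) -> tuple[list[VesicleDetection], list[VesicleDensityRecord]]:
    """Full transcytosis pipeline on projected frames.

    Detect puncta in the wall band of the vessel footprint, link identities
    across time, assign them to vessels via the projected label volume, and
    compute the cumulative surface-density kinetics.
    """
    labels2d = np.asarray(labels).max(axis=0) if np.asarray(labels).ndim == 3 \
        else np.asarray(labels)
    mask = labels2d > 0
    dets = detect_vesicles(projected_frames, mask, pixel_size_um,
                           frame_times_min, params)
    dets = link_detections(dets, pixel_size_um)
    dets = assign_to_vessels(dets, labels2d)
    records = density_kinetics(dets, segments, frame_times_min)
    return dets, records
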