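"""Ground-truth simulator for two-photon BBB permeability sessions.

The generator emulates the statistical structure the analysis assumes,
with every parameter known:

* a cortical vessel tree rendered into a label volume (pial vessels
  in-plane at the surface, penetrating arterioles / ascending venules
  through-plane, capillary bed in depth);
* paracellular tracer sessions: intravascular signal with mono-exponential
  blood clearance ``C0 * exp(-lambda * t)`` and parenchymal accumulation
  driven by a permeability rate ``k`` (two-compartment model), three
  tracers injected sequentially at 30-min intervals into one shared
  detection channel;
* transcytosis sessions: cumulative wall-vesicle puncta appearing as a
  Poisson process with a per-category rate per 100 um^2 of vessel surface,
  persisting once created;
* constant autofluorescence everywhere, Poisson shot noise plus Gaussian
  read noise, 16-bit output as acquired in vivo.

Optical realism (PSF, depth attenuation, motion) is deliberately out of
scope; the traces and puncta carry the kinetics the quantification reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, PlacementError
from .stack_ops import Hyperstack, IntensityTrace
from .vessels import (
    ARTERIAL,
    CATEGORIES,
    DIAMETER_RANGES_UM,
    ORIENTATIONS,
    VesselSegment,
)

# ---------------------------------------------------------------------------
# Configuration dataclasses


@dataclass(frozen=True)
class TracerSpec:
    """One injected fluorophore and its imaging window."""

    name: str
    mw_kda: float
    injection_time_min: float
    window_start_min: float
    window_end_min: float
    leak_class: str = "paracellular"  # "paracellular" | "conjugate"

    def __post_init__(self):
        if self.window_end_min <= self.window_start_min:
            raise ConfigError(f"{self.name}: empty imaging window")
        if self.injection_time_min > self.window_start_min:
            raise ConfigError(f"{self.name}: injection after window start")
        if self.leak_class not in ("paracellular", "conjugate"):
            raise ConfigError(f"{self.name}: unknown leak class")


def validate_schedule(
    schedule: list[TracerSpec],
    window_min: float = 30.0,
    conjugate_window_min: float = 120.0,
    injection_offset_min: float = 1.0,
) -> None:
    """Check window lengths and injection offsets of a session schedule."""
    for spec in schedule:
        want = window_min if spec.leak_class == "paracellular" else conjugate_window_min
        got = spec.window_end_min - spec.window_start_min
        if not math.isclose(got, want, rel_tol=1e-9):
            raise ConfigError(f"{spec.name}: window length {got} != {want} min")
        off = spec.window_start_min - spec.injection_time_min
        if not math.isclose(off, injection_offset_min, rel_tol=1e-9):
            raise ConfigError(
                f"{spec.name}: injection-to-window offset {off} != "
                f"{injection_offset_min} min"
            )
    times = [s.injection_time_min for s in schedule]
    if times != sorted(times):
        raise ConfigError("schedule must be ordered by injection time")


def default_tracer_schedule(
    first_injection_min: float = 1.0,
    window_min: float = 30.0,
    injection_offset_min: float = 1.0,
) -> list[TracerSpec]:
    """Three-tracer sequence: 10 kDa FITC-dextran, then AF488, then NaFluo.

    Each bolus is injected ``injection_offset_min`` before its first
    recorded frame and followed by a ``window_min`` time-lapse recording;
    the next bolus goes in as soon as the recording ends, so consecutive
    injections are separated by the 30-min imaging interval (31 min wall
    time) and the windows do not overlap.
    """
    names = [("FITC-dx", 10.0), ("AF488", 0.643), ("NaFluo", 0.365)]
    spacing = window_min + injection_offset_min
    out = []
    for i, (name, mw) in enumerate(names):
        inj = first_injection_min + i * spacing
        start = inj + injection_offset_min
        out.append(TracerSpec(name, mw, inj, start, start + window_min))
    return out


@dataclass(frozen=True)
class NoiseParams:
    """Photon-limited imaging noise: Poisson shot noise then Gaussian read."""

    poisson_gain: float = 1.0
    read_sigma: float = 2.0
    enabled: bool = True

    def __post_init__(self):
        if self.poisson_gain <= 0:
            raise ConfigError("poisson_gain must be > 0")
        if self.read_sigma < 0:
            raise ConfigError("read_sigma must be >= 0")

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(enabled=False)


@dataclass(frozen=True)
class GroundTruth:
    """Simulation parameters against which recovery is tested.

    Rates are per minute; ``leak_rate_per_min`` (k), ``blood_clearance_per_min``
    (lambda) and ``blood_amplitude`` (C0, a.u.) are keyed by tracer name;
    ``vesicle_rate_per_100um2_per_min`` by vessel category. The clearance
    half-lives are order-of-magnitude choices (not measured quantities) and
    can be overridden freely.
    """

    leak_rate_per_min: dict = field(default_factory=dict)
    blood_clearance_per_min: dict = field(default_factory=dict)
    blood_amplitude: dict = field(default_factory=dict)
    autofluorescence_offset: float = 50.0
    vesicle_rate_per_100um2_per_min: dict = field(default_factory=dict)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self):
        for d, what in (
            (self.leak_rate_per_min, "leak rate"),
            (self.blood_clearance_per_min, "clearance"),
            (self.vesicle_rate_per_100um2_per_min, "vesicle rate"),
        ):
            for key, v in d.items():
                if not (math.isfinite(v) and v >= 0):
                    raise ConfigError(f"{what} for {key!r} must be finite, >= 0")
        for key, v in self.blood_amplitude.items():
            if not (math.isfinite(v) and v > 0):
                raise ConfigError(f"blood amplitude for {key!r} must be > 0")
        if self.autofluorescence_offset < 0:
            raise ConfigError("autofluorescence_offset must be >= 0")


#: Blood clearance rates (1/min). Small free dyes clear faster than the
#: 10 kDa dextran or conjugated albumin; absolute values are plausible
#: order-of-magnitude defaults, not measurements.
DEFAULT_CLEARANCE = {"FITC-dx": 0.005, "AF488": 0.02, "NaFluo": 0.04,
                     "BSA-AF488": 0.001}
DEFAULT_AMPLITUDE = {"FITC-dx": 2000.0, "AF488": 2000.0, "NaFluo": 2000.0,
                     "BSA-AF488": 150.0}

#: Leak rates k (1/min) per experimental group, calibrated so the pipeline's
#: AUC scores land in the regime reported for WT / ApoM-null cortex (small
#: dyes leak, 10 kDa dextran essentially does not; the knockout leaks
#: several-fold more).
DEFAULT_LEAK = {
    "WT": {"FITC-dx": 2e-6, "AF488": 6e-5, "NaFluo": 5e-4},
    "ApoM_KO": {"FITC-dx": 2e-6, "AF488": 1.6e-4, "NaFluo": 2.7e-3},
    "ApoM_KO_SEW": {"FITC-dx": 2e-6, "AF488": 5e-5, "NaFluo": 5.3e-4},
}

#: Vesicle appearance rates per 100 um^2 per min (120-min endpoint density
#: divided by 120). The knockout is elevated only on the arterial side,
#: most strongly in penetrating arterioles.
DEFAULT_VESICLE_RATES = {
    "WT": {
        "pial_arteriole": 2.9e-4,
        "penetrating_arteriole": 3.2e-4,
        "capillary": 5.0e-4,
        "post_capillary_venule": 4.0e-4,
        "ascending_venule": 3.5e-4,
        "pial_venule": 3.0e-4,
    },
    "ApoM_KO": {
        "pial_arteriole": 8.25e-4,
        "penetrating_arteriole": 2.5e-3,
        "capillary": 5.0e-4,
        "post_capillary_venule": 4.0e-4,
        "ascending_venule": 3.5e-4,
        "pial_venule": 3.0e-4,
    },
    "ApoM_KO_SEW": {
        "pial_arteriole": 8.0e-4,
        "penetrating_arteriole": 3.8e-4,
        "capillary": 5.0e-4,
        "post_capillary_venule": 4.0e-4,
        "ascending_venule": 3.5e-4,
        "pial_venule": 3.0e-4,
    },
}

GROUPS = ("WT", "ApoM_KO", "ApoM_KO_SEW")


def default_ground_truth(group: str = "WT", seed: int = 0,
                         noise: NoiseParams | None = None) -> GroundTruth:
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    return GroundTruth(
        leak_rate_per_min=dict(DEFAULT_LEAK[group]),
        blood_clearance_per_min=dict(DEFAULT_CLEARANCE),
        blood_amplitude=dict(DEFAULT_AMPLITUDE),
        autofluorescence_offset=50.0,
        vesicle_rate_per_100um2_per_min=dict(DEFAULT_VESICLE_RATES[group]),
        noise=noise if noise is not None else NoiseParams(),
        seed=seed,
    )


def sample_cohort_truths(
    group: str,
    n_mice: int,
    seed: int,
    leak_cv: float = 0.5,
    vesicle_cv: float = 0.3,
    noise: NoiseParams | None = None,
) -> list[GroundTruth]:
    """Per-animal ground truths with lognormal inter-animal variability.

    Each mouse's leak and vesicle rates are the group defaults multiplied
    by a lognormal factor with unit mean and the given coefficient of
    variation, emulating the large animal-to-animal spread visible in
    in-vivo cohorts.
    """
    rng = np.random.default_rng(seed)
    base = default_ground_truth(group, noise=noise)

    def _factor(cv):
        if cv <= 0:
            return 1.0
        s2 = math.log1p(cv * cv)
        return float(rng.lognormal(-s2 / 2, math.sqrt(s2)))

    out = []
    for i in range(n_mice):
        leak = {k: v * _factor(leak_cv) for k, v in base.leak_rate_per_min.items()}
        ves = {k: v * _factor(vesicle_cv)
               for k, v in base.vesicle_rate_per_100um2_per_min.items()}
        out.append(
            replace(
                base,
                leak_rate_per_min=leak,
                vesicle_rate_per_100um2_per_min=ves,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Vessel tree generation


@dataclass(frozen=True)
class TreeConfig:
    """Geometry of the synthetic vascular volume.

    ``shape`` is (Z, Y, X); lengths in um. Default grids are small so a
    session simulates in seconds; larger fields are supported.
    """

    shape: tuple[int, int, int] = (8, 256, 256)
    pixel_size_um: float = 1.5
    z_step_um: float = 5.0
    counts: dict = field(
        default_factory=lambda: {
            "pial_arteriole": 1,
            "pial_venule": 1,
            "penetrating_arteriole": 2,
            "ascending_venule": 2,
            "post_capillary_venule": 2,
            "capillary": 4,
        }
    )
    diameter_ranges_um: dict = field(default_factory=lambda: dict(DIAMETER_RANGES_UM))
    length_ranges_um: dict = field(
        default_factory=lambda: {
            "pial_arteriole": (100.0, 180.0),
            "pial_venule": (100.0, 180.0),
            "capillary": (40.0, 80.0),
            "post_capillary_venule": (40.0, 80.0),
        }
    )
    gap_px: int = 2
    max_attempts: int = 200

    def __post_init__(self):
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ConfigError("shape must be (Z, Y, X) with positive extents")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ConfigError("pixel_size_um and z_step_um must be > 0")
        for cat in self.counts:
            if cat not in CATEGORIES:
                raise ConfigError(f"unknown category {cat!r} in counts")


def small_tree_config() -> TreeConfig:
    """Compact field for repeated simulation studies (seconds per session)."""
    return TreeConfig(
        shape=(4, 128, 128),
        pixel_size_um=1.5,
        z_step_um=5.0,
        counts={
            "pial_venule": 1,
            "penetrating_arteriole": 1,
            "ascending_venule": 1,
            "post_capillary_venule": 1,
            "capillary": 2,
        },
        max_attempts=2000,
    )


def vesicle_tree_config() -> TreeConfig:
    """Higher-magnification field used for transcytosis sessions."""
    return TreeConfig(shape=(8, 384, 384), pixel_size_um=0.75, z_step_um=5.0,
                      max_attempts=2000)


#: Placement order: large surface vessels first, capillary bed last.
_PLACEMENT_ORDER = (
    "pial_venule",
    "pial_arteriole",
    "penetrating_arteriole",
    "ascending_venule",
    "post_capillary_venule",
    "capillary",
)


def _capsule_footprint(shape_yx, p0, p1, radius_px):
    """Boolean 2D footprint of a thick line segment (capsule)."""
    h, w = shape_yx
    r0 = max(int(math.floor(min(p0[0], p1[0]) - radius_px - 1)), 0)
    r1 = min(int(math.ceil(max(p0[0], p1[0]) + radius_px + 1)) + 1, h)
    c0 = max(int(math.floor(min(p0[1], p1[1]) - radius_px - 1)), 0)
    c1 = min(int(math.ceil(max(p0[1], p1[1]) + radius_px + 1)) + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    py = yy - p0[0]
    px = xx - p0[1]
    t = np.clip((py * d[0] + px * d[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    dist2 = (py - t * d[0]) ** 2 + (px - t * d[1]) ** 2
    box = dist2 <= radius_px**2
    foot = np.zeros(shape_yx, dtype=bool)
    foot[r0:r1, c0:c1] = box
    return foot


def _disk_footprint(shape_yx, center, radius_px):
    return _capsule_footprint(shape_yx, center, center, radius_px)


def generate_vessel_tree(
    config: TreeConfig | None = None, seed: int = 0
) -> tuple[list[VesselSegment], np.ndarray]:
    """Place non-overlapping vessel segments and render a label volume.

    In-plane vessels are rasterized as capsules in a single Z-plane (pial
    vessels at the surface plane, capillary-bed vessels at random depth);
    through-plane vessels as full-depth circular columns. Footprints are
    kept disjoint in projection with a ``gap_px`` margin, so 3D masks are
    disjoint too. Deterministic under ``seed``; an unplaceable request
    raises :class:`PlacementError` naming the category.
    """
    config = config or TreeConfig()
    rng = np.random.default_rng(seed)
    nz, ny, nx = config.shape
    px = config.pixel_size_um
    labels = np.zeros(config.shape, dtype=np.uint16)
    occupied = np.zeros((ny, nx), dtype=bool)
    segments: list[VesselSegment] = []
    next_label = 1

    for cat in _PLACEMENT_ORDER:
        n = int(config.counts.get(cat, 0))
        d_lo, d_hi = config.diameter_ranges_um.get(cat, DIAMETER_RANGES_UM[cat])
        for _ in range(n):
            placed = False
            for _attempt in range(config.max_attempts):
                diameter = float(rng.uniform(d_lo, d_hi))
                radius_px = diameter / 2.0 / px
                if ORIENTATIONS[cat] == "through_plane":
                    cy = rng.uniform(radius_px + 1, ny - radius_px - 2)
                    cx = rng.uniform(radius_px + 1, nx - radius_px - 2)
                    foot = _disk_footprint((ny, nx), (cy, cx), radius_px)
                    zsel = None  # spans all planes
                    length = nz * config.z_step_um
                else:
                    l_lo, l_hi = config.length_ranges_um[cat]
                    fit = (min(ny, nx) - 2 * radius_px - 4) * px
                    if fit <= l_lo:
                        continue
                    length = float(rng.uniform(l_lo, min(l_hi, fit)))
                    half_px = length / 2.0 / px
                    cy = rng.uniform(0, ny - 1)
                    cx = rng.uniform(0, nx - 1)
                    ang = rng.uniform(0, 2 * math.pi)
                    dy, dx = math.sin(ang), math.cos(ang)
                    p0 = (cy - half_px * dy, cx - half_px * dx)
                    p1 = (cy + half_px * dy, cx + half_px * dx)
                    m = radius_px + 1
                    if not all(
                        m <= p[0] <= ny - 1 - m and m <= p[1] <= nx - 1 - m
                        for p in (p0, p1)
                    ):
                        continue
                    foot = _capsule_footprint((ny, nx), p0, p1, radius_px)
                    if cat in SURFACE_CATS:
                        zsel = 0
                    else:
                        zsel = int(rng.integers(1, nz)) if nz > 1 else 0
                grown = (
                    ndimage.binary_dilation(foot, iterations=config.gap_px)
                    if config.gap_px > 0
                    else foot
                )
                if (grown & occupied).any():
                    continue
                occupied |= foot
                if zsel is None:
                    labels[:, foot] = next_label
                else:
                    labels[zsel][foot] = next_label
                segments.append(
                    VesselSegment(
                        id=next_label,
                        category=cat,
                        diameter_um=diameter,
                        length_um=length,
                        orientation=ORIENTATIONS[cat],
                        arterial=ARTERIAL[cat],
                        label=next_label,
                    )
                )
                next_label += 1
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a {cat} without overlap after "
                    f"{config.max_attempts} attempts"
                )
    return segments, labels


SURFACE_CATS = frozenset({"pial_arteriole", "pial_venule"})


# ---------------------------------------------------------------------------
# Two-compartment tracer kinetics


def blood_expectation(spec: TracerSpec, truth: GroundTruth, times_min: np.ndarray
                      ) -> np.ndarray:
    """Noiseless intravascular signal of one tracer (no offset)."""
    t = np.asarray(times_min, dtype=float)
    lam = truth.blood_clearance_per_min[spec.name]
    c0 = truth.blood_amplitude[spec.name]
    dt = t - spec.injection_time_min
    out = np.where(dt >= 0, c0 * np.exp(-lam * np.maximum(dt, 0.0)), 0.0)
    return out


def parenchyma_expectation(spec: TracerSpec, truth: GroundTruth,
                           times_min: np.ndarray) -> np.ndarray:
    """Noiseless parenchymal accumulation of one tracer (no offset).

    The integral of the blood curve times the leak rate k:
    ``(k*C0/lambda)*(1 - exp(-lambda*dt))`` for lambda > 0, or the linear
    limit ``k*C0*dt`` for lambda = 0.
    """
    t = np.asarray(times_min, dtype=float)
    lam = truth.blood_clearance_per_min[spec.name]
    k = truth.leak_rate_per_min[spec.name]
    c0 = truth.blood_amplitude[spec.name]
    dt = np.maximum(t - spec.injection_time_min, 0.0)
    if lam > 0:
        acc = (k * c0 / lam) * (1.0 - np.exp(-lam * dt))
    else:
        acc = k * c0 * dt
    return np.where(t >= spec.injection_time_min, acc, 0.0)


def _apply_noise(expect: np.ndarray, noise: NoiseParams,
                 rng: np.random.Generator) -> np.ndarray:
    if not noise.enabled:
        return expect.astype(np.float32)
    g = noise.poisson_gain
    out = rng.poisson(expect * g).astype(np.float32) / g
    if noise.read_sigma > 0:
        out += rng.normal(0.0, noise.read_sigma, size=out.shape).astype(np.float32)
    np.clip(out, 0.0, 65535.0, out=out)
    return np.rint(out).astype(np.uint16)


def _noise_frame_structured(
    shape: tuple,
    scalar_classes: list[tuple[np.ndarray, float]],
    varying_mask: np.ndarray | None,
    varying_lam: np.ndarray | None,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shot + read noise for one frame, exploiting piecewise-constant lambda.

    ``scalar_classes`` are (mask, expectation) pairs covering voxels whose
    expectation is spatially constant; ``varying_mask``/``varying_lam`` give
    the remainder (e.g. punctum neighbourhoods) with per-voxel rates. Same
    noise model as :func:`_apply_noise`, but the scalar-rate Poisson path
    is several-fold faster on large volumes.
    """
    g = noise.poisson_gain
    out = np.empty(shape, dtype=np.float32)
    for mask, lam in scalar_classes:
        n = int(mask.sum())
        if n:
            out[mask] = rng.poisson(lam * g, size=n).astype(np.float32) / g
    if varying_mask is not None and varying_lam is not None and len(varying_lam):
        out[varying_mask] = rng.poisson(varying_lam * g).astype(np.float32) / g
    if noise.read_sigma > 0:
        out += noise.read_sigma * rng.standard_normal(
            out.shape, dtype=np.float32
        )
    np.clip(out, 0.0, 65535.0, out=out)
    return np.rint(out).astype(np.uint16)


@dataclass
class TracerSession:
    """A simulated sequential-tracer imaging session."""

    stack: Hyperstack
    schedule: list[TracerSpec]
    truth: GroundTruth
    reference: dict  # "blood"/"parenchyma" -> noiseless IntensityTrace
    per_tracer_parenchyma: dict  # tracer name -> noiseless component array


def simulate_tracer_session(
    tree: tuple[list[VesselSegment], np.ndarray],
    schedule: list[TracerSpec],
    truth: GroundTruth,
    frame_interval_min: float = 1.0,
    pixel_size_um: float = 1.5,
    z_step_um: float = 5.0,
    t0_min: float = 0.0,
    seed: int | None = None,
) -> TracerSession:
    """Render a paracellular session into a hyperstack.

    The session runs from ``t0_min`` (default 0, one frame before the first
    injection at t=1) to the last tracer's window end. Tracers share the
    channel and sum; a constant autofluorescence offset is added everywhere;
    noise is applied last. Noiseless per-compartment reference traces are
    returned alongside (and the noiseless stack is float32 so it reproduces
    them exactly).
    """
    segments, labels = tree
    if all(s.leak_class == "paracellular" for s in schedule):
        validate_schedule(schedule)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    t_end = max(s.window_end_min for s in schedule)
    n_t = int(round((t_end - t0_min) / frame_interval_min)) + 1
    times = t0_min + np.arange(n_t) * frame_interval_min

    blood = np.full(n_t, truth.autofluorescence_offset, dtype=float)
    paren = np.full(n_t, truth.autofluorescence_offset, dtype=float)
    per_tracer = {}
    for spec in schedule:
        b = blood_expectation(spec, truth, times)
        p = parenchyma_expectation(spec, truth, times)
        blood += b
        paren += p
        per_tracer[spec.name] = p

    vessel3d = labels > 0
    if truth.noise.enabled:
        paren3d = ~vessel3d
        data = np.empty((n_t, *labels.shape), dtype=np.uint16)
        for i in range(n_t):
            data[i] = _noise_frame_structured(
                labels.shape,
                [(vessel3d, blood[i]), (paren3d, paren[i])],
                None, None, truth.noise, rng,
            )
    else:
        data = np.empty((n_t, *labels.shape), dtype=np.float32)
        for i in range(n_t):
            data[i] = np.where(vessel3d, blood[i], paren[i])
    stack = Hyperstack(
        data=data,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        frame_interval_min=frame_interval_min,
        t0_min=t0_min,
    )
    reference = {
        "blood": IntensityTrace(times, blood, "raw_au", "blood"),
        "parenchyma": IntensityTrace(times, paren, "raw_au", "parenchyma"),
    }
    return TracerSession(stack, list(schedule), truth, reference, per_tracer)


# ---------------------------------------------------------------------------
# Vesicle (transcytosis) sessions


@dataclass(frozen=True)
class VesicleEvent:
    """One ground-truth wall punctum: where and when it appeared."""

    vessel_id: int
    time_min: float
    z: int
    row: float
    col: float
    radius_um: float


@dataclass
class VesicleSession:
    stack: Hyperstack
    events: list[VesicleEvent]
    segments: list[VesselSegment]
    labels: np.ndarray
    truth: GroundTruth


def _wall_pixels(labels: np.ndarray, label: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(z, y, x) arrays of boundary voxels of one segment's projected footprint."""
    foot = (labels == label).any(axis=0)
    interior = ndimage.binary_erosion(foot)
    wall = foot & ~interior
    ys, xs = np.nonzero(wall)
    # z-planes the segment occupies at each wall pixel's column
    zplanes = np.argmax(labels == label, axis=0)
    return zplanes[ys, xs], ys, xs


def simulate_vesicle_session(
    tree: tuple[list[VesselSegment], np.ndarray],
    truth: GroundTruth,
    duration_min: float = 120.0,
    frame_interval_min: float = 7.5,
    pixel_size_um: float = 0.75,
    z_step_um: float = 5.0,
    punctum_amplitude: float = 400.0,
    min_separation_px: float = 4.0,
    seed: int | None = None,
    conjugate_name: str = "BSA-AF488",
) -> VesicleSession:
    """Render a conjugate-tracer session with cumulative wall puncta.

    Per segment, the number of puncta appearing by time t is Poisson with
    mean ``rate * (surface_area/100) * t``; appearance times are uniform
    over the session and puncta persist once created (non-saturating
    kinetics). Each punctum is a compact Gaussian spot on the vessel wall.
    The ground-truth event list is returned for recall/precision scoring.
    """
    segments, labels = tree
    if duration_min <= 0:
        raise ConfigError("duration_min must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_t = int(round(duration_min / frame_interval_min)) + 1
    times = np.arange(n_t) * frame_interval_min
    nz, ny, nx = labels.shape

    events: list[VesicleEvent] = []
    for seg in segments:
        rate = truth.vesicle_rate_per_100um2_per_min.get(seg.category, 0.0)
        mean = rate * (seg.surface_area_um2 / 100.0) * duration_min
        n_ev = int(rng.poisson(mean))
        if n_ev == 0:
            continue
        zs, ys, xs = _wall_pixels(labels, seg.label)
        if len(ys) == 0:
            continue
        t_ev = np.sort(rng.uniform(0.0, duration_min, size=n_ev))
        taken: list[tuple[float, float]] = []
        for t in t_ev:
            for _try in range(40):
                j = int(rng.integers(0, len(ys)))
                y, x = float(ys[j]), float(xs[j])
                if all((y - py) ** 2 + (x - px_) ** 2 >= min_separation_px**2
                       for py, px_ in taken):
                    break
            taken.append((y, x))
            events.append(
                VesicleEvent(
                    vessel_id=seg.id,
                    time_min=float(t),
                    z=int(zs[j]),
                    row=y,
                    col=x,
                    radius_um=float(rng.uniform(0.8, 1.3)),
                )
            )
    events.sort(key=lambda e: e.time_min)

    # static base: lumen = offset + conjugate blood pool, parenchyma = offset
    lam = truth.blood_clearance_per_min.get(conjugate_name, 0.0)
    c0 = truth.blood_amplitude.get(conjugate_name, 150.0)
    vessel3d = labels > 0
    offset = truth.autofluorescence_offset
    puncta = np.zeros((nz, ny, nx), dtype=np.float32)
    data = np.empty(
        (n_t, nz, ny, nx),
        dtype=np.uint16 if truth.noise.enabled else np.float32,
    )
    ev_idx = 0
    for i, t in enumerate(times):
        while ev_idx < len(events) and events[ev_idx].time_min <= t:
            e = events[ev_idx]
            _add_gaussian_spot(puncta[e.z], e.row, e.col,
                               e.radius_um / pixel_size_um / math.sqrt(2.0),
                               punctum_amplitude)
            ev_idx += 1
        blood_t = offset + c0 * math.exp(-lam * t)
        if truth.noise.enabled:
            pmask = puncta > 1e-3
            varying = (
                np.where(vessel3d[pmask], blood_t, offset) + puncta[pmask]
            )
            data[i] = _noise_frame_structured(
                labels.shape,
                [(vessel3d & ~pmask, blood_t), (~vessel3d & ~pmask, offset)],
                pmask, varying, truth.noise, rng,
            )
        else:
            data[i] = np.where(vessel3d, blood_t, offset) + puncta
    stack = Hyperstack(
        data=data,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        frame_interval_min=frame_interval_min,
        t0_min=0.0,
    )
    return VesicleSession(stack, events, segments, labels, truth)


def _add_gaussian_spot(img: np.ndarray, row: float, col: float,
                       sigma_px: float, amplitude: float, extent: int = 5):
    h, w = img.shape
    r0 = max(int(row) - extent, 0)
    r1 = min(int(row) + extent + 1, h)
    c0 = max(int(col) - extent, 0)
    c1 = min(int(col) + extent + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -(((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma_px**2))
    ).astype(np.float32)


# ---------------------------------------------------------------------------
# Morphometry tables (TEM arm consumed as numbers)

MORPHOMETRY_MEASURES = (
    "endothelial_thickness_um",
    "basement_membrane_um",
    "junction_width_um",
    "junction_length_um",
    "cleft_width_um",
    "junction_coverage_pct",
    "cell_area_um2",
)

#: (mean, CV) per group per measure. Endothelial thickness and cell area
#: reproduce the reported group means; junctional measures are equal across
#: groups (no structural junction defect); CVs back-computed from reported
#: SEMs at n ~ 104.
DEFAULT_MORPHOMETRY = {
    "WT": {
        "endothelial_thickness_um": (0.071, 0.36),
        "basement_membrane_um": (0.040, 0.30),
        "junction_width_um": (0.012, 0.30),
        "junction_length_um": (0.40, 0.40),
        "cleft_width_um": (0.020, 0.30),
        "junction_coverage_pct": (70.0, 0.20),
        "cell_area_um2": (4.78, 0.50),
    },
    "ApoM_KO": {
        "endothelial_thickness_um": (0.078, 0.34),
        "basement_membrane_um": (0.040, 0.30),
        "junction_width_um": (0.012, 0.30),
        "junction_length_um": (0.40, 0.40),
        "cleft_width_um": (0.020, 0.30),
        "junction_coverage_pct": (70.0, 0.20),
        "cell_area_um2": (5.80, 0.65),
    },
    "ApoM_KO_SEW": {
        "endothelial_thickness_um": (0.070, 0.36),
        "basement_membrane_um": (0.040, 0.30),
        "junction_width_um": (0.012, 0.30),
        "junction_length_um": (0.40, 0.40),
        "cleft_width_um": (0.020, 0.30),
        "junction_coverage_pct": (70.0, 0.20),
        "cell_area_um2": (4.24, 0.55),
    },
}


def generate_morphometry_table(
    group_params: dict | None = None,
    n_per_group: int = 104,
    seed: int = 0,
):
    """Sample a long-format morphometry table (group, measure, value).

    Values are drawn log-normally with the configured arithmetic mean and
    coefficient of variation, guaranteeing positive support. The coverage
    percentage is resampled while above 100 to respect its (0, 100] range.
    """
    import pandas as pd

    params = group_params if group_params is not None else DEFAULT_MORPHOMETRY
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(params):
        for measure in sorted(params[group]):
            mean, cv = params[group][measure]
            if mean <= 0 or cv <= 0:
                raise ConfigError(
                    f"{group}/{measure}: mean and CV must be positive"
                )
            s2 = math.log1p(cv * cv)
            mu = math.log(mean) - s2 / 2.0
            sigma = math.sqrt(s2)
            for _ in range(n_per_group):
                v = float(rng.lognormal(mu, sigma))
                if measure == "junction_coverage_pct":
                    tries = 0
                    while v > 100.0 and tries < 1000:
                        v = float(rng.lognormal(mu, sigma))
                        tries += 1
                    v = min(v, 100.0)
                rows.append({"group": group, "measure": measure, "value": v})
    return pd.DataFrame(rows, columns=["group", "measure", "value"])
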