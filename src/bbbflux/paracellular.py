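"""Paracellular-permeability scoring of parenchymal tracer accumulation.

The leak score of one tracer is the area under its relative parenchymal
fluorescence trace over the 30-min window after injection (AUC, in
minutes). Because three tracers are injected sequentially into one
detection channel without waiting for blood clearance, fluorescence is
additive and later tracers ride on the tails of earlier ones. The
decoupling correction exploits that additivity: the constant
autofluorescence background is subtracted, an exponential (saturating
growth) fit to each earlier tracer's corrected trace is extrapolated into
the later windows and subtracted there, uncoupling each tracer's own
kinetics. The same scheme with an exponential *decay* fit accounts for
baseline changes of earlier fluorophores in the bloodstream.

The saturating-growth form ``a + b*(1 - exp(-c*t))`` is used for the
parenchymal correction because its extrapolation never decreases and never
exceeds ``a + b``: it bounds the largest theoretical contribution of a
preceding tracer without ever inventing extra signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, optimize

from .errors import FitError, TraceError
from .stack_ops import IntensityTrace, relative_change
from .synthetic import TracerSpec

logger = logging.getLogger(__name__)

_C_MAX_PER_MIN = 10.0  # upper bound for fitted rates


@dataclass(frozen=True)
class ExponentialFit:
    """A fitted exponential trend, anchored at its window start.

    ``saturating_growth`` evaluates as ``a + b*(1 - exp(-c*(t - t_start)))``
    and ``decay`` as ``a + b*exp(-c*(t - t_start))``. The degenerate
    ``c == 0`` case of the growth model is the linear limit: it evaluates
    ``a + b*(t - t_start)/(t_end - t_start)``, i.e. ``b`` holds
    ``slope * window_length``; a decay with ``c == 0`` is the constant
    ``a + b``.
    """

    model: str  # "saturating_growth" | "decay"
    a: float
    b: float
    c: float
    rmse: float
    window: tuple[float, float]

    def __post_init__(self):
        if self.model not in ("saturating_growth", "decay"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("a", "b", "c", "rmse"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite fit parameter {name}")
        if self.c < 0:
            raise ValueError("rate c must be >= 0")

    def __call__(self, times_min) -> np.ndarray:
        t = np.asarray(times_min, dtype=float) - self.window[0]
        if self.model == "decay":
            return self.a + self.b * np.exp(-self.c * t)
        if self.c == 0.0:
            length = self.window[1] - self.window[0]
            return self.a + self.b * (t / length if length > 0 else 0.0)
        return self.a + self.b * (1.0 - np.exp(-self.c * t))


def extrapolate_fit(fit: ExponentialFit, times_min) -> np.ndarray:
    """Evaluate a fit's closed form at arbitrary times (outside its window)."""
    return fit(times_min)


def subtract_background(
    trace: IntensityTrace, background_level: float
) -> IntensityTrace:
    """Remove the constant autofluorescence background from a raw trace.

    Negative results are clipped at 0 and the number of clipped points is
    logged. A background exceeding the trace minimum by more than half the
    dynamic range triggers a mis-estimation warning.
    """
    if background_level < 0:
        raise TraceError("background_level must be >= 0")
    span = float(np.ptp(trace.values))
    if span > 0 and background_level > trace.values.min() + 0.5 * span:
        warnings.warn(
            f"background {background_level:.4g} exceeds the trace minimum by "
            ">50% of its dynamic range; likely mis-estimated",
            stacklevel=2,
        )
    values = trace.values - background_level
    n_clip = int((values < 0).sum())
    if n_clip:
        logger.info("subtract_background clipped %d negative points", n_clip)
        values = np.clip(values, 0.0, None)
    return replace(trace, values=values)


def _growth(t, a, b, c):
    return a + b * (1.0 - np.exp(-c * t))


def _decay(t, a, b, c):
    return a + b * np.exp(-c * t)


def fit_exponential(
    trace: IntensityTrace, model: str = "saturating_growth"
) -> ExponentialFit:
    """Nonlinear least-squares exponential fit to a trace window.

    Initialization: a = first value, b = last - first, c = 1/window_length,
    with c bounded in [0, 10] per min. If the nonlinear fit fails, a linear
    fallback is reported in the c -> 0 parameterization (see
    :class:`ExponentialFit`); if even that is impossible a
    :class:`FitError` carries the diagnostics.
    """
    t = trace.times_min
    y = trace.values
    if t.size < 5:
        raise FitError(f"need >= 5 timepoints, got {t.size}")
    if model not in ("saturating_growth", "decay"):
        raise FitError(f"unknown model {model!r}")
    t0, t1 = float(t[0]), float(t[-1])
    length = t1 - t0
    ts = t - t0
    fun = _growth if model == "saturating_growth" else _decay
    if model == "saturating_growth":
        p0 = (float(y[0]), float(y[-1] - y[0]), 1.0 / length)
    else:
        p0 = (float(y[-1]), float(y[0] - y[-1]), 1.0 / length)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                fun,
                ts,
                y,
                p0=p0,
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, _C_MAX_PER_MIN]),
                maxfev=20000,
            )
        resid = fun(ts, *popt) - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        if np.all(np.isfinite(popt)):
            return ExponentialFit(model, float(popt[0]), float(popt[1]),
                                  float(popt[2]), rmse, (t0, t1))
    except (RuntimeError, ValueError) as exc:  # fall through to linear
        last_exc = exc
    else:
        last_exc = None
    # linear fallback in the c -> 0 limit
    try:
        slope, intercept = np.polyfit(ts, y, 1)
    except Exception as exc:  # pragma: no cover - degenerate input
        raise FitError(
            "exponential fit and linear fallback both failed",
            diagnostics={"model": model, "n": int(t.size), "cause": repr(exc)},
        ) from exc
    if model == "decay":
        # a decay with c = 0 is constant a + b; use the window mean
        a, b = float(np.mean(y)), 0.0
        resid = a - y
    else:
        a, b = float(intercept), float(slope * length)
        resid = (intercept + slope * ts) - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    logger.info("fit_exponential fell back to linear (%s)", last_exc)
    return ExponentialFit(model, a, b, 0.0, rmse, (t0, t1))


def decouple_sequential(
    traces_in_order: list[tuple[TracerSpec, IntensityTrace]],
    model: str = "saturating_growth",
) -> tuple[list[IntensityTrace], list[list[ExponentialFit]]]:
    """Subtract each earlier tracer's extrapolated fit from later traces.

    Traces must be background-subtracted and given in injection order on
    non-overlapping windows. Trace 1 is returned unchanged; for i >= 2 the
    fits of all *corrected* predecessors (each fitted on its own window)
    are subtracted. Negative corrected values are retained so systematic
    over-correction stays visible. Returns the corrected traces and, per
    trace, the list of correction fits applied (empty for the first).
    """
    corrected: list[IntensityTrace] = []
    fits_of: list[ExponentialFit] = []
    applied: list[list[ExponentialFit]] = []
    for i, (spec, trace) in enumerate(traces_in_order):
        values = trace.values.astype(float).copy()
        used = []
        for pred_fit in fits_of[:i]:
            values -= extrapolate_fit(pred_fit, trace.times_min)
            used.append(pred_fit)
        corr = IntensityTrace(trace.times_min.copy(), values, trace.units,
                              trace.compartment)
        corrected.append(corr)
        applied.append(used)
        if i < len(traces_in_order) - 1:  # fit only needed for successors
            try:
                fits_of.append(fit_exponential(corr, model=model))
            except FitError as exc:
                raise FitError(
                    f"correction fit failed for tracer {spec.name!r}",
                    diagnostics=exc.diagnostics,
                ) from exc
    return corrected, applied


def blood_clearance_fit(
    blood_trace: IntensityTrace,
) -> tuple[ExponentialFit, IntensityTrace]:
    """Exponential-decay fit to a blood trace plus baseline normalization.

    The normalized trace is the raw trace divided by its first value
    (fraction of baseline), invariant to detector gain. A blood signal
    that increases over the full window triggers a warning (injection
    timing suspect).
    """
    y = blood_trace.values
    if y.size < 2:
        raise TraceError("blood trace too short")
    if y[0] <= 0:
        raise TraceError("blood baseline must be > 0 for normalization")
    if y[-1] > y[0] and np.all(np.diff(y) >= 0):
        warnings.warn("blood signal increases over the window; "
                      "injection timing suspect", stacklevel=2)
    fit = fit_exponential(blood_trace, model="decay")
    norm = replace(blood_trace, values=y / y[0], units="relative")
    return fit, norm


def compute_auc(trace: IntensityTrace, window: tuple[float, float]) -> float:
    """Trapezoidal integral of a relative trace over a time window (min).

    The trace must cover the window; integration is on the native grid
    with linear interpolation only at the exact window endpoints.
    """
    w0, w1 = window
    t, y = trace.times_min, trace.values
    atol = 1e-9
    if w1 <= w0:
        raise TraceError("empty AUC window")
    if t.size < 2 or t[0] > w0 + atol or t[-1] < w1 - atol:
        raise TraceError(
            f"trace [{t[0] if t.size else '-'}, {t[-1] if t.size else '-'}] "
            f"does not cover window [{w0}, {w1}]"
        )
    sel = (t > w0 + atol) & (t < w1 - atol)
    tt = np.concatenate(([w0], t[sel], [w1]))
    yy = np.concatenate(([np.interp(w0, t, y)], y[sel], [np.interp(w1, t, y)]))
    return float(np.trapezoid(yy, tt))


def estimate_leak_rate(
    parenchyma_trace: IntensityTrace, blood_trace: IntensityTrace
) -> float:
    """Least-squares leak rate k from paired parenchyma and blood traces.

    Under the two-compartment model ``dP/dt = k * B(t)``, so P is fit as
    ``intercept + k * cumulative_trapezoid(B)`` on the common grid (the
    intercept absorbs accumulation before the window start). Both traces
    must be background-subtracted and on the same grid. Serves as the
    parameter-recovery oracle; the leak score proper is the AUC.
    """
    t = parenchyma_trace.times_min
    if t.shape != blood_trace.times_min.shape or not np.allclose(
        t, blood_trace.times_min
    ):
        raise TraceError("traces must share one time grid")
    b = blood_trace.values
    if not np.any(b != 0):
        raise TraceError("all-zero blood trace")
    cum = integrate.cumulative_trapezoid(b, t, initial=0.0)
    design = np.column_stack([np.ones_like(cum), cum])
    coef, *_ = np.linalg.lstsq(design, parenchyma_trace.values, rcond=None)
    return float(coef[1])


# ---------------------------------------------------------------------------
# Session-level pipeline


@dataclass
class PermeabilityResult:
    """Per-tracer leak score and the corrections that produced it."""

    tracer: str
    corrected_trace: IntensityTrace  # relative units, over the tracer window
    auc_min: float
    correction_fits: list[ExponentialFit] = field(default_factory=list)
    blood_fit: ExponentialFit | None = None

    def to_dict(self) -> dict:
        def fit_d(f):
            return None if f is None else {
                "model": f.model, "a": f.a, "b": f.b, "c": f.c,
                "rmse": f.rmse, "window": list(f.window),
            }

        return {
            "tracer": self.tracer,
            "auc_min": self.auc_min,
            "correction_fits": [fit_d(f) for f in self.correction_fits],
            "blood_fit": fit_d(self.blood_fit),
        }


def estimate_background(trace: IntensityTrace, first_injection_min: float
                        ) -> float:
    """Mean of the pre-injection samples of a raw trace."""
    pre = trace.values[trace.times_min < first_injection_min - 1e-9]
    if pre.size == 0:
        raise TraceError("no pre-injection samples to estimate background from")
    return float(pre.mean())


def analyze_session_traces(
    parenchyma: IntensityTrace,
    blood: IntensityTrace,
    schedule: list[TracerSpec],
    background: float | None = None,
) -> list[PermeabilityResult]:
    """Score every tracer of a sequential session from its raw traces.

    Steps: estimate (or accept) the constant background and subtract it
    from both compartments; slice each tracer's window; decouple the
    parenchymal windows with saturating-growth fits and the blood windows
    with decay fits; convert each corrected parenchymal window to relative
    change over its first frame, normalizing by the measured (background-
    inclusive) baseline; integrate the 30-min AUC.
    """
    if not schedule:
        return []
    first_inj = min(s.injection_time_min for s in schedule)
    if background is None:
        background = estimate_background(parenchyma, first_inj)
    par_bs = subtract_background(parenchyma, background)
    blo_bs = subtract_background(blood, background)

    par_windows = [
        (s, par_bs.window(s.window_start_min, s.window_end_min)) for s in schedule
    ]
    blo_windows = [
        (s, blo_bs.window(s.window_start_min, s.window_end_min)) for s in schedule
    ]
    par_corr, par_fits = decouple_sequential(par_windows, "saturating_growth")
    blo_corr, _ = decouple_sequential(blo_windows, "decay")

    results = []
    for (spec, _), corr, blo, fits in zip(
        par_windows, par_corr, blo_corr, par_fits
    ):
        rel = relative_change(corr, baseline_offset=background)
        auc = compute_auc(rel, (spec.window_start_min, spec.window_end_min))
        try:
            blood_fit, _ = blood_clearance_fit(
                replace(blo, values=np.maximum(blo.values, 1e-12))
            )
        except (FitError, TraceError):
            blood_fit = None
        results.append(
            PermeabilityResult(
                tracer=spec.name,
                corrected_trace=rel,
                auc_min=auc,
                correction_fits=list(fits),
                blood_fit=blood_fit,
            )
        )
    return results
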