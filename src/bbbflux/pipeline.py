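"""End-to-end pipelines from hyperstacks to permeability scores.

These helpers wire the front end (projection, segmentation, ROI placement,
trace extraction) to the quantification arms, mirroring how a session is
processed interactively: project the stack, segment the vasculature on the
first frame with tracer present, pool parenchymal ROIs away from vessels
and blood ROIs inside them, then score.
"""

from __future__ import annotations

import numpy as np

from .paracellular import PermeabilityResult, analyze_session_traces
from .stack_ops import (
    Hyperstack,
    IntensityTrace,
    extract_trace,
    max_project,
    place_blood_rois,
    place_parenchymal_rois,
    segment_vasculature,
)
from .synthetic import TracerSession, TracerSpec


def extract_compartment_traces(
    stack: Hyperstack,
    first_window_start_min: float,
    roi_seed: int = 0,
    n_parenchyma_rois: int = 10,
    roi_size_px: int = 8,
) -> tuple[IntensityTrace, IntensityTrace, np.ndarray]:
    """Project, segment, place ROIs and extract (parenchyma, blood) traces.

    Segmentation uses the first projected frame at or after
    ``first_window_start_min`` (the first frame with intravascular tracer),
    never the pre-injection frame. Returns the two raw traces and the
    vessel mask.
    """
    frames = max_project(stack)
    times = stack.times_min
    idx = int(np.searchsorted(times, first_window_start_min - 1e-9))
    idx = min(idx, frames.shape[0] - 1)
    mask = segment_vasculature(frames[idx])
    par_rois = place_parenchymal_rois(
        mask, roi_size_px=roi_size_px, n_rois=n_parenchyma_rois, seed=roi_seed
    )
    blood_rois = place_blood_rois(mask, seed=roi_seed)
    par = extract_trace(frames, par_rois, stack.frame_interval_min, stack.t0_min)
    blood = extract_trace(frames, blood_rois, stack.frame_interval_min,
                          stack.t0_min)
    return par, blood, mask


def score_tracer_session(
    session: TracerSession,
    roi_seed: int = 0,
    background: float | None = None,
) -> list[PermeabilityResult]:
    """Score every tracer of a simulated (or loaded) sequential session."""
    first_start = min(s.window_start_min for s in session.schedule)
    par, blood, _ = extract_compartment_traces(
        session.stack, first_start, roi_seed=roi_seed
    )
    return analyze_session_traces(par, blood, session.schedule,
                                  background=background)


def score_stack(
    stack: Hyperstack,
    schedule: list[TracerSpec],
    roi_seed: int = 0,
    background: float | None = None,
) -> list[PermeabilityResult]:
    """Score a hyperstack read from disk against a session schedule."""
    first_start = min(s.window_start_min for s in schedule)
    par, blood, _ = extract_compartment_traces(stack, first_start,
                                               roi_seed=roi_seed)
    return analyze_session_traces(par, blood, schedule, background=background)
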