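"""Parameter-recovery studies used to validate the pipeline end to end.

Each study simulates sessions with known ground truth, runs the *full*
measurement path (rendering, projection, segmentation, ROI placement,
trace extraction or blob detection, scoring) and returns the measured
quantities for comparison against the configured truth or a closed form
computed by the caller. Nothing here shortcuts the pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .paracellular import (
    analyze_session_traces,
    estimate_background,
    estimate_leak_rate,
    subtract_background,
)
from .pipeline import extract_compartment_traces, score_tracer_session
from .stack_ops import max_project
from .synthetic import (
    GroundTruth,
    NoiseParams,
    TracerSpec,
    default_ground_truth,
    default_tracer_schedule,
    generate_vessel_tree,
    simulate_tracer_session,
    simulate_vesicle_session,
    small_tree_config,
    vesicle_tree_config,
)
from .transcytosis import analyze_vesicle_frames


def single_tracer_truth(
    k: float,
    lam: float,
    c0: float = 2000.0,
    offset: float = 50.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> GroundTruth:
    return GroundTruth(
        leak_rate_per_min={"tracer": k},
        blood_clearance_per_min={"tracer": lam},
        blood_amplitude={"tracer": c0},
        autofluorescence_offset=offset,
        noise=noise if noise is not None else NoiseParams.none(),
        seed=seed,
    )


def single_tracer_spec() -> TracerSpec:
    return TracerSpec("tracer", 0.365, 1.0, 2.0, 32.0)


def score_single_tracer_session(
    truth: GroundTruth,
    seed: int = 0,
    tree_seed: int = 11,
) -> tuple[float, float]:
    """Full-pipeline (AUC, estimated leak rate) for one single-tracer session."""
    spec = single_tracer_spec()
    tree = generate_vessel_tree(small_tree_config(), seed=tree_seed)
    sess = simulate_tracer_session(tree, [spec], truth, seed=seed)
    par, blood, _ = extract_compartment_traces(sess.stack, spec.window_start_min,
                                               roi_seed=seed)
    bg = estimate_background(par, spec.injection_time_min)
    res = analyze_session_traces(par, blood, [spec])
    w = (spec.window_start_min, spec.window_end_min)
    par_w = subtract_background(par, bg).window(*w)
    blood_w = subtract_background(blood, bg).window(*w)
    khat = estimate_leak_rate(par_w, blood_w)
    return res[0].auc_min, khat


def decoupling_equivalence_study(
    seeds: list[int],
    noise: NoiseParams,
    group: str = "WT",
) -> dict[str, tuple[list[float], list[float]]]:
    """Joint-session vs alone-session AUCs for the downstream tracers.

    Returns {tracer: ([joint AUC per seed], [alone AUC per seed])} for the
    second and third tracer of the default sequence. The alone session
    keeps the tracer's own injection time and parameters, so any
    difference is attributable to the decoupling correction.
    """
    schedule = default_tracer_schedule()
    out: dict[str, tuple[list[float], list[float]]] = {
        s.name: ([], []) for s in schedule[1:]
    }
    for seed in seeds:
        truth = default_ground_truth(group, seed=seed, noise=noise)
        tree = generate_vessel_tree(small_tree_config(), seed=seed % 17)
        joint_sess = simulate_tracer_session(tree, schedule, truth, seed=seed)
        joint = {
            r.tracer: r.auc_min
            for r in score_tracer_session(joint_sess, roi_seed=seed)
        }
        for spec in schedule[1:]:
            alone_sess = simulate_tracer_session(
                tree, [spec], truth, seed=seed + 10_000
            )
            alone = score_tracer_session(alone_sess, roi_seed=seed)[0].auc_min
            out[spec.name][0].append(joint[spec.name])
            out[spec.name][1].append(alone)
    return out


def vesicle_detection_pr(
    seed: int = 3,
    truth_seed: int = 7,
    group: str = "ApoM_KO",
    noise: NoiseParams | None = None,
    match_radius_px: float = 2.0,
) -> tuple[float, float]:
    """(recall, precision) of final-frame detections vs ground-truth events."""
    tree_config = vesicle_tree_config()
    tree = generate_vessel_tree(tree_config, seed=seed)
    truth = default_ground_truth(
        group, seed=truth_seed,
        noise=noise if noise is not None else NoiseParams.none(),
    )
    sess = simulate_vesicle_session(
        tree, truth,
        pixel_size_um=tree_config.pixel_size_um,
        z_step_um=tree_config.z_step_um,
    )
    frames = max_project(sess.stack)
    dets, _ = analyze_vesicle_frames(
        frames, sess.labels, sess.segments,
        tree_config.pixel_size_um, sess.stack.times_min,
    )
    final_t = sess.stack.times_min[-1]
    final = [d for d in dets if d.time_min == final_t]
    gt = [(e.row, e.col) for e in sess.events]
    if not gt:
        return 1.0, 1.0 if not final else 0.0
    if not final:
        return 0.0, 1.0
    cost = np.array(
        [[np.hypot(d.row - y, d.col - x) for (y, x) in gt] for d in final]
    )
    ri, ci = linear_sum_assignment(cost)
    matched = sum(1 for a, b in zip(ri, ci) if cost[a, b] <= match_radius_px)
    recall = matched / len(gt)
    precision = matched / len(final)
    return recall, precision
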