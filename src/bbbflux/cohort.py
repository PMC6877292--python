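"""Synthetic cohort studies: group-level recreations of the in-vivo design.

A cohort is n animals per experimental group (wild type, ApoM-deficient,
agonist-rescued), each with its own ground truth drawn around the group
defaults with lognormal inter-animal variability. Each animal contributes
one sequential-tracer session (paracellular arm) and/or one conjugate
session (transcytosis arm); group comparisons then use the same
normality-gated tests as the in-vivo analysis.
"""

from __future__ import annotations

import numpy as np

from .pipeline import score_tracer_session
from .stack_ops import max_project
from .stats_report import GroupComparisonResult, compare_two_groups
from .synthetic import (
    TreeConfig,
    default_tracer_schedule,
    generate_vessel_tree,
    sample_cohort_truths,
    simulate_tracer_session,
    simulate_vesicle_session,
    small_tree_config,
    vesicle_tree_config,
)
from .transcytosis import VesicleDensityRecord, analyze_vesicle_frames


def run_paracellular_cohort(
    group: str,
    n_mice: int,
    seed: int,
    tree_config: TreeConfig | None = None,
    leak_cv: float = 0.5,
) -> dict[str, list[float]]:
    """AUC per tracer for each animal of one group.

    Returns {tracer name: [AUC of mouse 1, ...]}; each mouse gets its own
    vessel tree, ground truth and noise stream, all derived from ``seed``.
    """
    tree_config = tree_config or small_tree_config()
    rng = np.random.default_rng(seed)
    truths = sample_cohort_truths(group, n_mice, seed=int(rng.integers(2**31)),
                                  leak_cv=leak_cv)
    schedule = default_tracer_schedule()
    aucs: dict[str, list[float]] = {}
    for i, truth in enumerate(truths):
        tree = generate_vessel_tree(tree_config, seed=int(rng.integers(2**31)))
        session = simulate_tracer_session(
            tree, schedule, truth,
            pixel_size_um=tree_config.pixel_size_um,
            z_step_um=tree_config.z_step_um,
        )
        for res in score_tracer_session(session, roi_seed=i):
            aucs.setdefault(res.tracer, []).append(res.auc_min)
    return aucs


def run_vesicle_cohort(
    group: str,
    n_mice: int,
    seed: int,
    tree_config: TreeConfig | None = None,
    vesicle_cv: float = 0.3,
    duration_min: float = 120.0,
    frame_interval_min: float = 7.5,
) -> list[list[VesicleDensityRecord]]:
    """Density records per animal of one group (full detection pipeline)."""
    tree_config = tree_config or vesicle_tree_config()
    rng = np.random.default_rng(seed)
    truths = sample_cohort_truths(group, n_mice, seed=int(rng.integers(2**31)),
                                  vesicle_cv=vesicle_cv)
    out = []
    for truth in truths:
        tree = generate_vessel_tree(tree_config, seed=int(rng.integers(2**31)))
        session = simulate_vesicle_session(
            tree, truth,
            duration_min=duration_min,
            frame_interval_min=frame_interval_min,
            pixel_size_um=tree_config.pixel_size_um,
            z_step_um=tree_config.z_step_um,
        )
        frames = max_project(session.stack)
        _, records = analyze_vesicle_frames(
            frames, session.labels, session.segments,
            tree_config.pixel_size_um, session.stack.times_min,
        )
        out.append(records)
    return out


def final_density_by_category(
    cohort_records: list[list[VesicleDensityRecord]],
) -> dict[str, list[float]]:
    """Per-animal mean endpoint density per category (animal = unit)."""
    out: dict[str, list[float]] = {}
    for records in cohort_records:
        if not records:
            continue
        t_end = max(r.time_min for r in records)
        per_cat: dict[str, list[float]] = {}
        for r in records:
            if r.time_min == t_end:
                per_cat.setdefault(r.category, []).append(r.density_per_100um2)
        for cat, vals in per_cat.items():
            out.setdefault(cat, []).append(float(np.mean(vals)))
    return out


def vesicle_rate_recovery_study(
    group: str = "ApoM_KO",
    n_seeds: int = 20,
    mice_per_seed: int = 5,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Recover per-category vesicle rates through the full detection pipeline.

    Pools density records from ``n_seeds`` cohorts of ``mice_per_seed``
    sessions each, all at the group's configured rates (no inter-animal
    variability, since this is a parameter-recovery study), and returns
    (estimated slopes, configured rates) per category.
    """
    from .synthetic import default_ground_truth
    from .transcytosis import rate_recovery

    rng = np.random.default_rng(seed)
    tree_config = vesicle_tree_config()
    all_records = []
    for _ in range(n_seeds * mice_per_seed):
        s = int(rng.integers(2**31))
        tree = generate_vessel_tree(tree_config, seed=s)
        truth = default_ground_truth(group, seed=s)
        session = simulate_vesicle_session(
            tree, truth,
            pixel_size_um=tree_config.pixel_size_um,
            z_step_um=tree_config.z_step_um,
        )
        frames = max_project(session.stack)
        _, records = analyze_vesicle_frames(
            frames, session.labels, session.segments,
            tree_config.pixel_size_um, session.stack.times_min,
        )
        all_records.extend(records)
    est = rate_recovery(all_records)
    true = dict(default_ground_truth(group).vesicle_rate_per_100um2_per_min)
    return est, true


def compare_groups_auc(
    aucs_a: dict[str, list[float]],
    aucs_b: dict[str, list[float]],
    names: tuple[str, str] = ("WT", "ApoM_KO"),
) -> dict[str, GroupComparisonResult]:
    """Per-tracer two-group comparison of cohort AUCs."""
    out = {}
    for tracer in sorted(set(aucs_a) & set(aucs_b)):
        out[tracer] = compare_two_groups(
            aucs_a[tracer], aucs_b[tracer], names=names
        )
    return out
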