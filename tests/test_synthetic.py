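"""Generator contracts: geometry, kinetics closed forms, Poisson events."""

import math

import numpy as np
import pytest

import bbbflux as bf
from bbbflux.errors import ConfigError, PlacementError
from bbbflux.synthetic import (
    GroundTruth,
    NoiseParams,
    TracerSpec,
    TreeConfig,
    blood_expectation,
    default_tracer_schedule,
    generate_morphometry_table,
    parenchyma_expectation,
    sample_cohort_truths,
    simulate_tracer_session,
    simulate_vesicle_session,
    small_tree_config,
)


def _single_tracer_truth(k, lam, c0=100.0, offset=0.0, noise=None, seed=0):
    return GroundTruth(
        leak_rate_per_min={"t": k},
        blood_clearance_per_min={"t": lam},
        blood_amplitude={"t": c0},
        autofluorescence_offset=offset,
        noise=noise or NoiseParams.none(),
        seed=seed,
    )


SPEC = TracerSpec("t", 0.365, 0.0, 1.0, 31.0)


class TestVesselTree:
    def test_empty_config(self):
        cfg = TreeConfig(counts={})
        segs, labels = bf.generate_vessel_tree(cfg, seed=0)
        assert segs == []
        assert not labels.any()

    def test_single_capillary_forced_range(self):
        cfg = TreeConfig(
            counts={"capillary": 1},
            diameter_ranges_um={"capillary": (4.0, 5.0)},
        )
        segs, labels = bf.generate_vessel_tree(cfg, seed=2)
        assert len(segs) == 1
        (seg,) = segs
        assert seg.category == "capillary"
        assert 4.0 <= seg.diameter_um < 5.0
        assert set(np.unique(labels)) == {0, seg.label}

    def test_two_of_each_disjoint_and_deterministic(self):
        from bbbflux.vessels import CATEGORIES

        cfg = TreeConfig(shape=(8, 384, 384),
                         counts={c: 2 for c in CATEGORIES},
                         max_attempts=2000)
        segs, labels = bf.generate_vessel_tree(cfg, seed=1)
        assert len(segs) == 12
        # label volume maps voxels to segment ids; masks disjoint by construction
        assert set(np.unique(labels)) == set(range(13))
        for s in segs:
            if s.category == "capillary":
                assert s.diameter_um < 6.0
        segs2, labels2 = bf.generate_vessel_tree(cfg, seed=1)
        assert np.array_equal(labels, labels2)
        assert segs == segs2

    def test_impossible_placement_reports_category(self):
        cfg = TreeConfig(shape=(2, 32, 32), pixel_size_um=1.0,
                         counts={"pial_arteriole": 3}, max_attempts=20)
        with pytest.raises(PlacementError, match="pial_arteriole"):
            bf.generate_vessel_tree(cfg, seed=0)


class TestTracerKinetics:
    def test_zero_leak_gives_flat_parenchyma(self, small_tree):
        truth = _single_tracer_truth(k=0.0, lam=0.1, offset=30.0)
        sess = simulate_tracer_session(small_tree, [SPEC], truth)
        par = sess.reference["parenchyma"].values
        assert np.allclose(par, 30.0)

    def test_closed_form_parenchyma_value(self):
        """(k*C0/lam)*(1-exp(-lam*t)) at t=30 for k=0.01, lam=0.1, C0=100."""
        truth = _single_tracer_truth(k=0.01, lam=0.1)
        val = parenchyma_expectation(SPEC, truth, np.array([30.0]))[0]
        assert val == pytest.approx(9.502, abs=5e-4)

    def test_lambda_zero_linear_limit(self):
        truth = _single_tracer_truth(k=0.01, lam=0.0)
        val = parenchyma_expectation(SPEC, truth, np.array([30.0]))[0]
        assert val == pytest.approx(0.01 * 100.0 * 30.0)

    def test_two_tracer_additivity(self, small_tree):
        """Joint session trace equals the sum of single-tracer runs."""
        s1 = TracerSpec("a", 10.0, 1.0, 2.0, 32.0)
        s2 = TracerSpec("b", 0.365, 32.0, 33.0, 63.0)
        truth = GroundTruth(
            leak_rate_per_min={"a": 1e-3, "b": 2e-3},
            blood_clearance_per_min={"a": 0.01, "b": 0.05},
            blood_amplitude={"a": 500.0, "b": 800.0},
            autofluorescence_offset=10.0,
            noise=NoiseParams.none(),
        )
        joint = simulate_tracer_session(small_tree, [s1, s2], truth)
        t = joint.reference["parenchyma"].times_min
        expected = (
            10.0
            + parenchyma_expectation(s1, truth, t)
            + parenchyma_expectation(s2, truth, t)
        )
        assert np.allclose(joint.reference["parenchyma"].values, expected)

    def test_zero_noise_stack_reproduces_reference_exactly(self, small_tree):
        truth = _single_tracer_truth(k=5e-3, lam=0.04, c0=2000.0, offset=50.0)
        sess = simulate_tracer_session(small_tree, [SPEC], truth)
        _, labels = small_tree
        par_ref = sess.reference["parenchyma"].values
        blood_ref = sess.reference["blood"].values
        zi, yi, xi = np.argwhere(labels == 0)[0]
        zv, yv, xv = np.argwhere(labels > 0)[0]
        assert np.allclose(sess.stack.data[:, zi, yi, xi], par_ref, rtol=1e-6)
        assert np.allclose(sess.stack.data[:, zv, yv, xv], blood_ref, rtol=1e-6)

    def test_blood_conservation_integral(self):
        """Noiseless blood curve integrates to C0/lambda (1-min sampling)."""
        truth = _single_tracer_truth(k=0.0, lam=0.05, c0=300.0)
        t = np.arange(0.0, 400.0, 1.0)
        b = blood_expectation(TracerSpec("t", 1.0, 0.0, 1.0, 31.0), truth, t)
        integral = np.trapezoid(b, t)
        assert integral == pytest.approx(300.0 / 0.05, rel=0.01)

    def test_doubling_k_doubles_plateau(self):
        t = np.array([500.0])  # effectively at plateau
        v1 = parenchyma_expectation(SPEC, _single_tracer_truth(1e-3, 0.1), t)
        v2 = parenchyma_expectation(SPEC, _single_tracer_truth(2e-3, 0.1), t)
        assert v2[0] == pytest.approx(2 * v1[0])

    def test_noisy_stack_is_16bit(self, small_tree):
        truth = _single_tracer_truth(k=1e-3, lam=0.04, c0=2000.0, offset=50.0,
                                     noise=NoiseParams())
        sess = simulate_tracer_session(small_tree, [SPEC], truth, seed=4)
        assert sess.stack.data.dtype == np.uint16

    def test_determinism_under_seed(self, small_tree):
        truth = _single_tracer_truth(k=1e-3, lam=0.04, c0=2000.0, offset=50.0,
                                     noise=NoiseParams())
        a = simulate_tracer_session(small_tree, [SPEC], truth, seed=9)
        b = simulate_tracer_session(small_tree, [SPEC], truth, seed=9)
        assert np.array_equal(a.stack.data, b.stack.data)


class TestSchedule:
    def test_default_schedule_windows(self):
        sched = default_tracer_schedule()
        for s in sched:
            assert s.window_end_min - s.window_start_min == 30.0
            assert s.window_start_min - s.injection_time_min == 1.0
        starts = [s.window_start_min for s in sched]
        ends = [s.window_end_min for s in sched]
        assert all(e <= s for e, s in zip(ends, starts[1:]))

    def test_bad_window_rejected(self):
        with pytest.raises(ConfigError):
            TracerSpec("x", 1.0, 5.0, 4.0, 34.0)  # injection after start


class TestVesicleEvents:
    def test_zero_rates_no_events(self, small_tree):
        truth = GroundTruth(
            blood_amplitude={"BSA-AF488": 150.0},
            blood_clearance_per_min={"BSA-AF488": 0.001},
            autofluorescence_offset=50.0,
            vesicle_rate_per_100um2_per_min={},
            noise=NoiseParams.none(),
        )
        sess = simulate_vesicle_session(small_tree, truth, duration_min=30.0,
                                        frame_interval_min=15.0)
        assert sess.events == []

    def test_poisson_event_count_mean(self):
        """Mean final count over many seeds matches rate*area/100*duration."""
        cfg = TreeConfig(shape=(2, 48, 48), pixel_size_um=1.0,
                         counts={"capillary": 1},
                         length_ranges_um={"capillary": (30.0, 40.0)},
                         max_attempts=2000)
        rate = 0.5 / 120.0  # 0.5 per 100 um^2 per 120 min
        counts, expected = [], []
        for seed in range(500):
            tree = bf.generate_vessel_tree(cfg, seed=3)
            truth = GroundTruth(
                blood_amplitude={"BSA-AF488": 150.0},
                blood_clearance_per_min={"BSA-AF488": 0.001},
                vesicle_rate_per_100um2_per_min={"capillary": rate},
                noise=NoiseParams.none(),
                seed=seed,
            )
            sess = simulate_vesicle_session(
                tree, truth, duration_min=120.0, frame_interval_min=60.0
            )
            counts.append(len(sess.events))
            expected.append(
                rate * tree[0][0].surface_area_um2 / 100.0 * 120.0
            )
        mean_ratio = np.mean(counts) / np.mean(expected)
        se = np.std(counts) / np.mean(expected) / np.sqrt(len(counts))
        assert abs(mean_ratio - 1.0) <= 3 * se + 1e-12

    def test_counts_nondecreasing_in_time(self, small_tree):
        truth = bf.default_ground_truth("ApoM_KO", seed=5,
                                        noise=NoiseParams.none())
        sess = simulate_vesicle_session(small_tree, truth,
                                        pixel_size_um=1.5)
        times = sess.stack.times_min
        for seg in sess.segments:
            per_t = [
                sum(1 for e in sess.events
                    if e.vessel_id == seg.id and e.time_min <= t)
                for t in times
            ]
            assert all(a <= b for a, b in zip(per_t, per_t[1:]))


class TestMorphometry:
    def test_empty_table(self):
        df = generate_morphometry_table(n_per_group=0)
        assert df.empty
        assert list(df.columns) == ["group", "measure", "value"]

    def test_group_means_hit_targets(self):
        """WT 0.071 vs knockout 0.078 um endothelium, tight variance."""
        params = {
            "WT": {"endothelial_thickness_um": (0.071, 0.05)},
            "ApoM_KO": {"endothelial_thickness_um": (0.078, 0.05)},
        }
        df = generate_morphometry_table(params, n_per_group=100, seed=3)
        for group, target in [("WT", 0.071), ("ApoM_KO", 0.078)]:
            vals = df[df.group == group]["value"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) <= 3 * se

    def test_null_groups_rarely_significant(self):
        """Identical group parameters -> ns two-group test in >=90% of seeds."""
        from bbbflux.stats_report import compare_two_groups

        params = {
            "A": {"endothelial_thickness_um": (0.07, 0.3)},
            "B": {"endothelial_thickness_um": (0.07, 0.3)},
        }
        ns = 0
        for seed in range(100):
            df = generate_morphometry_table(params, n_per_group=30, seed=seed)
            a = df[df.group == "A"]["value"].to_numpy()
            b = df[df.group == "B"]["value"].to_numpy()
            if compare_two_groups(a, b).p_value >= 0.05:
                ns += 1
        assert ns >= 90

    def test_positive_support_and_coverage_bound(self):
        df = generate_morphometry_table(n_per_group=200, seed=9)
        assert (df["value"] > 0).all()
        cov = df[df.measure == "junction_coverage_pct"]["value"]
        assert (cov <= 100.0).all()

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigError):
            generate_morphometry_table(
                {"WT": {"cell_area_um2": (5.0, -0.1)}}, n_per_group=5
            )

    def test_determinism(self):
        a = generate_morphometry_table(n_per_group=10, seed=4)
        b = generate_morphometry_table(n_per_group=10, seed=4)
        assert a.equals(b)


class TestCohortTruths:
    def test_deterministic_and_positive(self):
        a = sample_cohort_truths("ApoM_KO", 4, seed=8)
        b = sample_cohort_truths("ApoM_KO", 4, seed=8)
        assert [t.leak_rate_per_min for t in a] == [
            t.leak_rate_per_min for t in b
        ]
        for t in a:
            assert all(v >= 0 for v in t.leak_rate_per_min.values())
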