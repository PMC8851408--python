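"""Schedule sampling, the full loop, best-class logic, and the control."""

import dataclasses
import json
from math import comb

import numpy as np
import pytest

import focalstim as fs
from focalstim.closed_loop import (SCHEDULE, best_attainable_class, class_rank,
                                   control_probability_closed_form, latent_class,
                                   method_success_counts, run_region,
                                   sample_schedule_stimuli)
from focalstim.synthetic import DEFAULT_HYPER, sample_region


@pytest.fixture(scope="module")
def grid():
    return fs.build_grid()


class TestScheduleSampling:
    @pytest.mark.parametrize("k,expected", [(1, 5), (2, 10), (3, 15), (4, 20)])
    def test_counts_per_schedule(self, grid, k, expected):
        stimuli = sample_schedule_stimuli(grid, k, seed=0)
        assert len(stimuli) == expected
        for t in range(1, 6):
            assert sum(p.type_index == t for p in stimuli) == k

    def test_without_replacement(self, grid):
        stimuli = sample_schedule_stimuli(grid, 4, seed=1)
        keys = [(p.type_index, p.cathodic_amplitude) for p in stimuli]
        assert len(keys) == len(set(keys))

    def test_seeded_reproducibility(self, grid):
        s1 = sample_schedule_stimuli(grid, 3, seed=5)
        s2 = sample_schedule_stimuli(grid, 3, seed=5)
        assert [(p.type_index, p.cathodic_amplitude) for p in s1] == \
               [(p.type_index, p.cathodic_amplitude) for p in s2]

    def test_oversized_k_rejected(self, grid):
        with pytest.raises(ValueError, match="exceeds"):
            sample_schedule_stimuli(grid, 7, seed=0)   # ratio 20 has only 6


class TestBestAttainableClass:
    def test_class1_region(self, grid):
        region = sample_region(2)
        classes = {latent_class(region, p) for p in grid}
        assert 1 in classes
        assert best_attainable_class(region, grid) == 1

    def test_desirability_order(self, grid):
        """With classes {0, 2, 4} present the best is 2 (order 1>2>3>4>0)."""
        for s in range(40):
            region = sample_region(s)
            classes = {latent_class(region, p) for p in grid}
            if 1 not in classes and 2 in classes:
                assert best_attainable_class(region, grid) == 2
                return
        pytest.fail("no class-2-best region found in 40 seeds")

    def test_all_subthreshold_region(self, grid):
        hyper = dataclasses.replace(DEFAULT_HYPER, threshold_range=(500.0, 600.0))
        region = sample_region(0, hyper)
        assert best_attainable_class(region, grid) == 0

    def test_class_rank_order(self):
        assert sorted([1, 2, 3, 4, 0], key=class_rank) == [1, 2, 3, 4, 0]


class TestRunRegion:
    def test_reaches_best_class_1(self, grid):
        region = sample_region(2)
        assert best_attainable_class(region, grid) == 1
        log = run_region(region, sampling_seed=5, training_seed=6,
                         render_seed=7, observation="surface")
        assert log.achieved_class == 1
        assert log.stop_iteration is not None

    def test_best_class_2_fallback(self, grid):
        """A region without class 1 runs the whole schedule, delivers class 2."""
        for s in range(40):
            region = sample_region(s)
            if best_attainable_class(region, grid) == 2:
                log = run_region(region, sampling_seed=1, training_seed=2,
                                 render_seed=3, observation="surface")
                assert log.stop_iteration is None
                assert len(log.iterations) == len(SCHEDULE)
                assert log.achieved_class == 2
                return
        pytest.fail("no class-2-best region found")

    def test_subthreshold_region_never_trains(self):
        hyper = dataclasses.replace(DEFAULT_HYPER, threshold_range=(500.0, 600.0))
        region = sample_region(0, hyper)
        log = run_region(region, observation="surface")
        assert log.achieved_class == 0
        assert all(it.surrogate_metrics is None for it in log.iterations)

    def test_schedule_sizes_recorded(self, grid):
        region = sample_region(8)
        log = run_region(region, sampling_seed=0, training_seed=0,
                         render_seed=0, observation="surface")
        sizes = [it.schedule_size for it in log.iterations]
        assert sizes == list(SCHEDULE[:len(sizes)])
        for it in log.iterations:
            assert len(it.sampled) == it.schedule_size

    def test_delivered_stimuli_are_deliverable(self):
        region = sample_region(12)
        log = run_region(region, sampling_seed=2, training_seed=2,
                         render_seed=2, observation="surface")
        for it in log.iterations:
            if it.delivered is None:
                continue
            amp, ratio = it.delivered["cathodic_amplitude_uA"], it.delivered["duration_ratio"]
            assert amp % ratio == 0

    def test_runlog_bit_reproducible(self):
        region = sample_region(4)
        kwargs = dict(sampling_seed=9, training_seed=10, render_seed=11,
                      observation="surface")
        j1 = run_region(region, **kwargs).to_json()
        j2 = run_region(region, **kwargs).to_json()
        assert j1 == j2
        json.loads(j1)                      # valid JSON

    def test_render_and_surface_modes_agree_on_outcome(self):
        region = sample_region(2)
        log_r = run_region(region, sampling_seed=5, training_seed=6,
                           render_seed=7, observation="render")
        log_s = run_region(region, sampling_seed=5, training_seed=6,
                           render_seed=7, observation="surface")
        assert log_r.achieved_class == log_s.achieved_class == 1


class TestMethodSuccessAndControl:
    def test_success_counts_cumulative(self):
        region = sample_region(2)
        log = run_region(region, sampling_seed=5, training_seed=6,
                         render_seed=7, observation="surface")
        success = method_success_counts(log, best_class=1)
        vals = [success[s] for s in sorted(success)]
        # once achieved, success persists at larger budgets
        assert vals == sorted(vals)

    def test_hypergeometric_closed_form(self):
        """1 - C(46-m, k)/C(46, k) against direct enumeration."""
        for m, k in [(5, 5), (12, 10), (1, 20), (46, 5), (0, 10)]:
            p = control_probability_closed_form(m, 46, k)
            if m == 0:
                assert p == 0.0
            else:
                expected = 1.0 - comb(46 - m, k) / comb(46, k) if k <= 46 - m else 1.0
                assert p == pytest.approx(expected, abs=1e-12)

    def test_control_monte_carlo_matches_closed_form(self, grid):
        region = sample_region(7)
        best = best_attainable_class(region, grid)
        classes = np.array([latent_class(region, p) for p in grid])
        m = int((classes == best).sum())
        rng = np.random.default_rng(0)
        k = 10
        hits = sum(
            bool((classes[rng.choice(46, size=k, replace=False)] == best).any())
            for _ in range(3000)
        )
        assert hits / 3000 == pytest.approx(
            control_probability_closed_form(m, 46, k), abs=0.03)


class TestEvaluateEnsembleSmall:
    def test_small_ensemble_curves(self):
        """Method beats or ties the control pointwise on a small ensemble."""
        res = fs.evaluate_ensemble(n_regions=6, n_repeats=4, seed=3)
        assert res.method_probability.shape == (4,)
        assert ((0 <= res.method_probability) & (res.method_probability <= 1)).all()
        assert (res.method_probability >= res.control_probability - 0.15).all()
        assert set(res.best_classes) <= {1, 2}
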