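"""Training-set assembly, tanh-net surrogates, and the |A - C| + E objective."""

import numpy as np
import pandas as pd
import pytest

import focalstim as fs
from focalstim.imaging import ResponseShape
from focalstim.surrogate import (InsufficientDataError, SurrogatePair, TanhNet,
                                 objective, objective_gradient, objective_map,
                                 prepare_training_set, train_surrogates,
                                 _split_sizes)
from focalstim.synthetic import ELECTRODE_AREA_UM2, ground_truth_response, surface_observe

BOX = ((20.0, 110.0), (1.0, 5.0))


def _shape(area, ecc, n_px=100):
    return ResponseShape(area=area, eccentricity=ecc, n_active_pixels=n_px,
                         center=(0, 0), semi_major=1, semi_minor=1, orientation=0)


@pytest.fixture(scope="module")
def trained_pair():
    region = fs.sample_region(3)
    grid = fs.build_grid()
    rng = np.random.default_rng(0)
    trials = [(p, surface_observe(region, p, rng)) for p in grid]
    table, amax = prepare_training_set(trials)
    return train_surrogates(table, seed=1, area_max=amax, box=grid.box)


class TestPrepareTrainingSet:
    def test_class0_trials_excluded(self):
        pulses = [fs.make_pulse(a, 1) for a in (20, 40, 60, 80, 100)]
        shapes = [_shape(0, 0, n_px=0)] + [_shape(30000 + i, 0.4) for i in range(4)]
        table, _ = prepare_training_set(list(zip(pulses, shapes)))
        assert len(table) == 4

    def test_normalization_identity(self):
        pulses = [fs.make_pulse(a, 1) for a in (40, 60, 80)]
        shapes = [_shape(20000, 0.3), _shape(60000, 0.5), _shape(45000, 0.4)]
        table, amax = prepare_training_set(list(zip(pulses, shapes)))
        assert amax == 60000
        assert table["area_normalized"].max() == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(InsufficientDataError):
            prepare_training_set([])

    def test_all_class0_raises(self):
        pulses = [fs.make_pulse(a, 1) for a in (20, 40, 60)]
        shapes = [_shape(0, 0, n_px=0)] * 3
        with pytest.raises(InsufficientDataError):
            prepare_training_set(list(zip(pulses, shapes)))


class TestSplits:
    @pytest.mark.parametrize("n", [5, 10, 15, 20, 46])
    def test_fractions_within_bands(self, n):
        tr, val, te = _split_sizes(n)
        assert tr + val + te == n
        assert 0.6 <= tr / n <= 0.8
        assert val >= 1 and te >= 1


class TestTrainSurrogates:
    def test_noiseless_recovery_46_points(self):
        """Test MSE on normalized area <= 0.05 for a smooth 46-point table."""
        region = fs.sample_region(0)
        grid = fs.build_grid()
        rows = []
        for p in grid:
            a_star, e_star = ground_truth_response(region, p)
            if a_star > 0:
                rows.append((p.cathodic_amplitude, p.type_index, a_star, e_star))
        df = pd.DataFrame(rows, columns=["amplitude", "type_index", "area", "eccentricity"])
        amax = df["area"].max()
        df["area_normalized"] = df["area"] / amax
        table = df[["amplitude", "type_index", "area_normalized", "eccentricity"]]
        pair = train_surrogates(table, seed=0, area_max=amax, box=grid.box)
        assert pair.metrics["area"]["test_mse"] <= 0.05

    def test_constant_table_fits_constant(self):
        table = pd.DataFrame({
            "amplitude": np.linspace(20, 110, 10),
            "type_index": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5],
            "area_normalized": 1.0,
            "eccentricity": 0.42,
        })
        pair = train_surrogates(table, seed=0, area_max=50000, box=BOX)
        for a in (25.0, 60.0, 105.0):
            assert pair.area_net(a, 3.0) == pytest.approx(1.0, abs=1e-3)
            assert pair.ecc_net(a, 3.0) == pytest.approx(0.42, abs=1e-3)

    def test_five_point_table_trains(self):
        """The first-iteration sample (one amplitude per type) is fittable."""
        region = fs.sample_region(6)
        rng = np.random.default_rng(1)
        pulses = [fs.make_pulse(80, r) for r in (1, 2, 5, 10, 20)]
        trials = [(p, surface_observe(region, p, rng)) for p in pulses]
        table, amax = prepare_training_set(trials)
        pair = train_surrogates(table, seed=0, area_max=amax, box=BOX)
        assert np.isfinite(pair.area_net(60.0, 2.5))
        assert pair.split_sizes[0] >= 3

    def test_deterministic_for_fixed_seed(self, trained_pair):
        region = fs.sample_region(3)
        grid = fs.build_grid()
        rng = np.random.default_rng(0)
        trials = [(p, surface_observe(region, p, rng)) for p in grid]
        table, amax = prepare_training_set(trials)
        pair2 = train_surrogates(table, seed=1, area_max=amax, box=grid.box)
        assert np.array_equal(trained_pair.area_net.theta, pair2.area_net.theta)
        m1 = objective_map(trained_pair)
        m2 = objective_map(pair2)
        assert np.array_equal(m1.values, m2.values)

    def test_predictions_finite_over_box(self, trained_pair):
        amps = np.linspace(20, 110, 25)
        types = np.linspace(1, 5, 9)
        for t in types:
            A = trained_pair.area_net(amps, np.full_like(amps, t))
            E = trained_pair.ecc_net(amps, np.full_like(amps, t))
            assert np.isfinite(A).all() and np.isfinite(E).all()

    def test_recovery_improves_with_sample_size(self):
        """Median dense-grid MSE shrinks as noiseless samples grow 5 -> 46."""
        from focalstim.closed_loop import sample_schedule_stimuli
        import dataclasses
        from focalstim.synthetic import DEFAULT_HYPER

        hyper = dataclasses.replace(DEFAULT_HYPER, threshold_range=(25.0, 40.0))
        grid = fs.build_grid()
        mses = {5: [], 46: []}
        for seed in range(8):
            region = fs.sample_region(200 + seed, hyper)
            for n, stimuli in ((5, sample_schedule_stimuli(grid, 1, seed)),
                               (46, list(grid))):
                rows = [(p.cathodic_amplitude, p.type_index,
                         *ground_truth_response(region, p)) for p in stimuli]
                rows = [r for r in rows if r[2] > 0]
                if len(rows) < 3:
                    continue
                df = pd.DataFrame(rows, columns=["amplitude", "type_index",
                                                 "area", "eccentricity"])
                amax = df["area"].max()
                df["area_normalized"] = df["area"] / amax
                pair = train_surrogates(
                    df[["amplitude", "type_index", "area_normalized", "eccentricity"]],
                    seed=seed, area_max=amax, box=grid.box)
                truth, pred = [], []
                for p in grid:
                    a_star, _ = ground_truth_response(region, p)
                    if a_star > 0:
                        truth.append(a_star / amax)
                        pred.append(float(pair.area_net(p.cathodic_amplitude,
                                                        float(p.type_index))))
                mses[n].append(np.mean((np.array(pred) - np.array(truth)) ** 2))
        assert np.median(mses[46]) < np.median(mses[5])


class TestObjective:
    def test_identity_cases(self):
        """f = |A - C| + E pointwise; the focal-round ideal gives f = 0."""
        net_A = _const_net(0.5)
        net_E = _const_net(0.2)
        pair = SurrogatePair(area_net=net_A, ecc_net=net_E, region_area_max=1e5,
                             C=0.3, box=BOX, split_sizes=(3, 1, 1))
        assert objective(pair, 50, 3) == pytest.approx(0.4, abs=1e-12)
        pair_ideal = SurrogatePair(area_net=_const_net(0.3), ecc_net=_const_net(0.0),
                                   region_area_max=1e5, C=0.3, box=BOX,
                                   split_sizes=(3, 1, 1))
        assert objective(pair_ideal, 50, 3) == pytest.approx(0.0, abs=1e-12)

    def test_objective_lower_bounded_by_eccentricity(self, trained_pair):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, t = rng.uniform(20, 110), rng.uniform(1, 5)
            f = objective(trained_pair, a, t)
            E = trained_pair.ecc_net(a, t)
            assert f >= E - 1e-12 >= -1e-12

    def test_gradient_matches_finite_differences(self, trained_pair):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, t = rng.uniform(25, 105), rng.uniform(1.2, 4.8)
            g = objective_gradient(trained_pair, a, t)
            eps = 1e-6
            fd = [(objective(trained_pair, a + eps, t) - objective(trained_pair, a - eps, t)) / (2 * eps),
                  (objective(trained_pair, a, t + eps) - objective(trained_pair, a, t - eps)) / (2 * eps)]
            assert np.allclose(g, fd, atol=1e-5)


class TestObjectiveMap:
    def test_grid_shape_and_nonnegativity(self, trained_pair):
        surf = objective_map(trained_pair)
        assert surf.values.shape == (5, 46)     # (110-20)/2+1 amplitudes
        assert (surf.values >= 0).all()

    def test_argmin_is_brute_force_minimum(self, trained_pair):
        surf = objective_map(trained_pair)
        a, t, v = surf.argmin()
        brute = min(
            objective(trained_pair, aa, tt)
            for aa in surf.amplitudes for tt in surf.types
        )
        assert v == pytest.approx(float(brute), abs=1e-12)


def _const_net(value: float) -> TanhNet:
    theta = np.zeros(TanhNet.n_params)
    theta[-1] = value
    return TanhNet(theta, np.array([20.0, 1.0]), np.array([110.0, 5.0]))
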