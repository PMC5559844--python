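"""Synthetic parents, simulated offspring and the accuracy grid."""

import numpy as np
import pytest
from scipy import stats

from epigenotype.epigenotyping import find_informative_positions, make_bins
from epigenotype.simulate import (
    SimulationConfig,
    accuracy_f1,
    run_grid,
    simulate_offspring,
    synth_parents,
)


class TestSynthParents:
    def test_every_position_informative(self, small_parents):
        m, f = small_parents
        info = find_informative_positions(m, f)["Chr1"]
        assert len(info) == len(m.df)

    def test_deterministic_given_seed(self):
        a = synth_parents(100, 500_000, seed=3)
        b = synth_parents(100, 500_000, seed=3)
        assert a[0].df.equals(b[0].df) and a[1].df.equals(b[1].df)

    def test_zero_positions_gives_empty_tables(self):
        m, f = synth_parents(0, 1000, seed=0)
        assert len(m) == 0 and len(f) == 0

    def test_exactly_one_parent_methylated_per_position(self, small_parents):
        m, f = small_parents
        assert (m.df["is_methylated"].to_numpy()
                ^ f.df["is_methylated"].to_numpy()).all()


class TestSimulateOffspring:
    def test_zero_error_levels_equal_expected(self, small_parents):
        m, f = small_parents
        t, tr = simulate_offspring(m, f, n_breakpoints=4, y=0.0, seed=5)
        g = tr.genotype_at(m.df["pos"].to_numpy())
        ml = (m.df["mc"] / m.df["total"]).to_numpy()
        fl = (f.df["mc"] / f.df["total"]).to_numpy()
        expected = np.select([g == 0, g == 1, g == 2], [ml, (ml + fl) / 2, fl])
        observed = (t.df["mc"] / t.df["total"]).to_numpy()
        np.testing.assert_allclose(observed, expected, atol=1e-12)

    def test_levels_bounded_within_error_band(self, small_parents):
        m, f = small_parents
        t, tr = simulate_offspring(m, f, n_breakpoints=0, y=0.3, seed=6)
        g = tr.genotype_at(m.df["pos"].to_numpy())
        ml = (m.df["mc"] / m.df["total"]).to_numpy()
        fl = (f.df["mc"] / f.df["total"]).to_numpy()
        expected = np.select([g == 0, g == 1, g == 2], [ml, (ml + fl) / 2, fl])
        observed = (t.df["mc"] / t.df["total"]).to_numpy()
        # rounding to counts of 200 adds at most 1/400
        assert (observed >= np.maximum(0, expected - 0.3) - 1 / 400).all()
        assert (observed <= np.minimum(1, expected + 0.3) + 1 / 400).all()
        assert (observed >= 0).all() and (observed <= 1).all()

    def test_levels_stay_in_unit_interval_at_max_error(self, small_parents):
        m, f = small_parents
        t, _ = simulate_offspring(m, f, n_breakpoints=3, y=1.0, seed=7)
        lv = (t.df["mc"] / t.df["total"]).to_numpy()
        assert (lv >= 0).all() and (lv <= 1).all()

    def test_potential_breakpoints_bound_actual_crossovers(self, small_parents):
        m, f = small_parents
        seen = set()
        for s in range(30):
            _, tr = simulate_offspring(m, f, n_breakpoints=5, y=0.0, seed=s)
            assert 0 <= tr.n_crossovers <= 5
            seen.add(tr.n_crossovers)
        assert len(seen) > 2  # adjacent regions may share a genotype

    def test_regions_tile_chromosome(self, small_parents):
        m, f = small_parents
        _, tr = simulate_offspring(m, f, n_breakpoints=7, y=0.0, seed=8)
        assert tr.regions[0][0] == 0
        assert tr.regions[-1][1] == tr.chrom_length
        for (s1, e1, _), (s2, e2, _) in zip(tr.regions[:-1], tr.regions[1:]):
            assert e1 == s2

    def test_invalid_error_rejected(self, small_parents):
        m, f = small_parents
        with pytest.raises(ValueError):
            simulate_offspring(m, f, 1, y=1.5, seed=0)

    def test_deterministic_given_seed(self, small_parents):
        m, f = small_parents
        a, _ = simulate_offspring(m, f, 3, 0.4, seed=9)
        b, _ = simulate_offspring(m, f, 3, 0.4, seed=9)
        assert a.df.equals(b.df)

    def test_genotype_frequencies_follow_1_2_1(self, small_parents):
        m, f = small_parents
        draws = []
        for s in range(60):
            _, tr = simulate_offspring(m, f, n_breakpoints=9, y=0.0, seed=[21, s])
            draws.extend(g for _, _, g in tr.regions)
        counts = np.bincount(draws, minlength=3)
        _, p = stats.chisquare(counts, len(draws) * np.array([0.25, 0.5, 0.25]))
        assert p > 1e-3


class TestTruthProjection:
    def test_majority_vote_in_straddling_bin(self, small_parents):
        m, f = small_parents
        _, tr = simulate_offspring(m, f, n_breakpoints=1, y=0.0, seed=10)
        bins = make_bins(2_000_000, 300_000, m.df["pos"].to_numpy())
        proj = tr.project_to_bins(bins)
        for b, state in zip(bins, proj):
            g = tr.genotype_at(b.positions)
            assert state == np.bincount(g, minlength=3).argmax()


class TestAccuracy:
    def test_perfect_prediction_scores_one(self):
        assert accuracy_f1([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_micro_f1_equals_fraction_correct(self):
        assert accuracy_f1([0, 1, 2, 2], [0, 1, 2, 1]) == pytest.approx(0.75)

    def test_random_predictions_near_analytic_expectation(self):
        # truth 1:2:1, uniform-ish predictions: E[acc] = sum p_i q_i
        rng = np.random.default_rng(0)
        truth = rng.choice(3, 30_000, p=[0.25, 0.5, 0.25])
        pred = rng.choice(3, 30_000, p=[0.25, 0.5, 0.25])
        assert accuracy_f1(pred, truth) == pytest.approx(0.375, abs=0.02)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy_f1([0, 1], [0, 1, 2])


@pytest.fixture(scope="module")
def tiny_grid():
    config = SimulationConfig(
        n_samples=3, errors=(0.0,), bin_sizes=(100_000,), iterations=2,
        seed=5, n_positions=600, chrom_length=2_000_000,
    )
    return config, run_grid(config)


class TestRunGrid:
    def test_grid_shape_and_columns(self, tiny_grid):
        config, grid = tiny_grid
        assert set(grid.columns) >= {"error", "bin_size", "sample",
                                     "n_breakpoints", "accuracy"}
        assert len(grid) == config.n_samples

    def test_noiseless_accuracy_high(self, tiny_grid):
        # on a 20-bin toy chromosome, bins adjacent to a crossover are a
        # large fraction of the map, so accuracy is high but not perfect
        _, grid = tiny_grid
        assert grid["accuracy"].mean() >= 0.9

    def test_reproducible_given_seed(self, tiny_grid):
        config, grid = tiny_grid
        again = run_grid(config)
        assert again["accuracy"].equals(grid["accuracy"])

    def test_invalid_error_grid_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(errors=(0.0, 1.2))
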