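import numpy as np
import pandas as pd
import pytest

from vfa import feature_selection as fs
from vfa import spot_map as sm
from vfa import synthetic_data as syn
from vfa.inference import NetworkConfig

FAST_NET = NetworkConfig(hidden=(16,), dropout=0.0, epochs=30, patience=10)


def make_training(net, conditions, concentration=None, rid=None, fid=None):
    """TrainingSet from a raw (N, P) net-signal matrix."""
    net = np.asarray(net, dtype=float)
    n, p = net.shape
    spots = [(0, i) for i in range(p)]
    conc = np.ones(n) if concentration is None else np.asarray(concentration)
    return fs.TrainingSet(
        net_signals=net,
        spots=spots,
        spot_conditions=np.asarray(conditions),
        concentration=conc,
        rid=np.ones(n, dtype=int) if rid is None else rid,
        fid=np.ones(n, dtype=int) if fid is None else fid,
        sample_id=np.array([f"s{i}" for i in range(n)]),
        test_id=np.array([f"t{i}" for i in range(n)]),
    )


def cost_loop_oracle(s_norm, conditions):
    """Naive triple-loop evaluation of the per-spot cost."""
    n, p = s_norm.shape
    j = np.zeros(p)
    for spot in range(p):
        cond = conditions[spot]
        like = [q for q in range(p) if conditions[q] == cond]
        for test in range(n):
            mean = sum(s_norm[test][q] for q in like) / len(like)
            j[spot] += abs(s_norm[test][spot] - mean) / mean
    return j


class TestCostMap:
    def test_spot_equal_to_like_mean_has_zero_cost(self):
        # two identical spots of one condition: both sit at the mean
        tr = make_training([[1.0, 1.0, 2.0]], ["a", "a", "b"])
        cm = fs.spot_cost_map(tr)
        assert cm.values[(0, 0)] == 0.0
        assert cm.values[(0, 1)] == 0.0
        assert cm.values[(0, 2)] == 0.0  # single-spot condition

    def test_hand_example_two_spots(self):
        # one sample, one condition with net signals {1, 3}: after
        # normalization s' = {0.25, 0.75}, mean 0.5, j = 0.5 for both
        tr = make_training([[1.0, 3.0]], ["a", "a"])
        cm = fs.spot_cost_map(tr)
        assert cm.values[(0, 0)] == pytest.approx(0.5)
        assert cm.values[(0, 1)] == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(5))
    def test_vectorized_matches_loop_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n, p = 13, 12
        conds = rng.choice(["a", "b", "c"], p)
        net = rng.uniform(0.1, 2.0, (n, p))
        tr = make_training(net, conds)
        cm = fs.spot_cost_map(tr)
        oracle = cost_loop_oracle(net / net.sum(1, keepdims=True), conds)
        assert np.max(np.abs(cm.values.to_numpy() - oracle)) < 1e-12

    def test_noisy_spot_has_max_cost_of_its_condition(self, default_map,
                                                      dose_models):
        hits = 0
        for seed in range(20):
            cohort = syn.simulate_cohort(
                syn.CohortDesign(n_hs_samples=20, replicates=2,
                                 acute_concentrations=()),
                default_map, seed=seed, noise_spots=[(4, 3)],
            )
            tr = fs.TrainingSet.from_cohort(cohort)
            cm = fs.spot_cost_map(tr)
            cond = default_map.assignment[(4, 3)]
            like = [tuple(rc) for rc in default_map.spots_of(cond)]
            hits += cm.values[(4, 3)] == cm.values.loc[like].max()
        assert hits >= 19  # >= 95% of runs


class TestHeatmap:
    def test_81_entries_placed_by_position(self, default_map, small_cohort):
        tr = fs.TrainingSet.from_cohort(small_cohort)
        cm = fs.spot_cost_map(tr)
        mat = fs.heatmap_matrix(cm, 9, 9)
        assert mat.shape == (9, 9)
        r, c = np.unravel_index(np.argmax(mat), mat.shape)
        assert (r, c) == cm.argmax_spot()

    def test_constant_cost_constant_raster(self):
        tr = make_training(np.ones((2, 4)), ["a", "a", "b", "b"])
        cm = fs.spot_cost_map(tr)
        raster = fs.heatmap_matrix(cm, 1, 4, upsample=3)
        assert np.allclose(raster, raster.flat[0])

    def test_missing_spot_rejected(self, small_cohort):
        tr = fs.TrainingSet.from_cohort(small_cohort)
        cm = fs.spot_cost_map(tr)
        cm.values = cm.values.drop((0, 0))
        with pytest.raises(ValueError, match="missing"):
            fs.heatmap_matrix(cm, 9, 9)


class TestFolds:
    def test_partition_property(self):
        rng = np.random.default_rng(0)
        conc = rng.uniform(0.1, 10, 100)
        fid = rng.choice([1, 2, 3], 100)
        folds = fs.stratified_folds(conc, fid, 5, seed=1)
        assert len(folds) == 100
        counts = np.bincount(folds, minlength=5)
        assert counts.sum() == 100
        assert counts.max() - counts.min() <= 5  # roughly balanced

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fs.stratified_folds(np.ones(3), np.ones(3), 5, seed=0)


class TestSpotElimination:
    def test_terminal_state_one_spot_per_condition(self, small_cohort):
        tr = fs.TrainingSet.from_cohort(small_cohort)
        trace = fs.eliminate_spots_cv(tr, FAST_NET, k=2, seed=0,
                                      track_metrics=False)
        assert trace.sizes() == list(range(81, 6, -1))
        last = trace.iterations[-1].members
        conds = {tr.spot_conditions[tr.spot_indices([rc])[0]] for rc in last}
        assert len(last) == 7 and len(conds) == 7

    def test_already_terminal_single_iteration(self):
        tr = make_training(
            np.random.default_rng(0).uniform(0.5, 1.5, (10, 3)),
            ["a", "b", "c"],
            concentration=np.linspace(0.5, 5, 10),
        )
        trace = fs.eliminate_spots_cv(tr, FAST_NET, k=2, seed=0,
                                      track_metrics=False)
        assert len(trace) == 1

    def test_elimination_order_follows_cost(self, small_cohort):
        tr = fs.TrainingSet.from_cohort(small_cohort)
        cm = fs.spot_cost_map(tr)
        trace = fs.eliminate_spots_cv(tr, FAST_NET, k=2, seed=0,
                                      track_metrics=False)
        first_removed = trace.iterations[1].removed
        assert cm.values[first_removed] == cm.values.max()


class TestSubsetSelection:
    def test_strictly_decreasing_curve_returns_terminal(self):
        trace = fs.EliminationTrace(
            [
                fs.EliminationIteration(list(range(10 - i)), 1.0 - 0.1 * i, 0.5)
                for i in range(5)
            ]
        )
        assert len(fs.select_spot_subset(trace, window=1)) == 6

    def test_u_shaped_curve_minimum_found(self):
        msle = [5, 4, 3, 2, 3, 4, 5]
        trace = fs.EliminationTrace(
            [
                fs.EliminationIteration(list(range(10 - i)), m, 0.5)
                for i, m in enumerate(msle)
            ]
        )
        assert len(fs.select_spot_subset(trace, window=1)) == 7

    @pytest.mark.parametrize("seed", range(20))
    def test_smoothing_tolerates_noise(self, seed):
        rng = np.random.default_rng(seed)
        base = (np.arange(30) - 18) ** 2 / 40.0  # noiseless minimum at 18
        noisy = base + rng.normal(0, 0.25, 30)
        trace = fs.EliminationTrace(
            [
                fs.EliminationIteration(list(range(40 - i)), m, 0.5)
                for i, m in enumerate(noisy)
            ]
        )
        chosen = 40 - len(fs.select_spot_subset(trace, window=5))
        assert abs(chosen - 18) <= 3


class TestConditionElimination:
    def test_noise_condition_eliminated_first(self):
        # two redundant copies of one informative channel plus a pure-noise
        # channel: the greedy elimination should drop the noise channel first
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            conc = np.exp(rng.uniform(np.log(0.1), np.log(10), n))
            info = 1.0 / (1.0 + conc / 2.0)  # informative channel
            net = np.column_stack(
                [
                    info * rng.lognormal(0, 0.05, n),
                    info * rng.lognormal(0, 0.05, n),
                    rng.uniform(0.2, 1.0, n),  # pure-noise condition
                ]
            )
            tr = make_training(net, ["a", "b", "z"], concentration=conc)
            _, order, _ = fs.eliminate_conditions_cv(
                tr, tr.spots, FAST_NET, k=2, seed=seed
            )
            hits += order[0] == "z"
        assert hits >= 9

    def test_single_condition_rejected(self):
        tr = make_training(np.ones((4, 2)), ["a", "a"],
                           concentration=[1, 2, 3, 4])
        with pytest.raises(ValueError, match="2 conditions"):
            fs.eliminate_conditions_cv(tr, tr.spots, FAST_NET, k=2, seed=0)

    def test_curve_length_counts_conditions(self, small_cohort):
        tr = fs.TrainingSet.from_cohort(small_cohort)
        spots = tr.spots
        trace, order, _ = fs.eliminate_conditions_cv(
            tr, spots, FAST_NET, k=2, seed=0
        )
        # full set + one entry per elimination down to a single condition
        assert len(trace) == 7
        assert len(order) == 6
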