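"""Binned-index GA: grids, genome operators, screening, evolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgtlearn import ga
from cbgtlearn.network import TIMEOUT, TrialBatchResult


class TestGridValues:
    def test_worked_five_point_grids(self):
        np.testing.assert_allclose(
            ga.grid_values(-0.3, 1.0, 5), [-0.3, 0.025, 0.35, 0.675, 1.0]
        )
        np.testing.assert_allclose(ga.grid_values(-2, 2, 5), [-2, -1, 0, 1, 2])

    def test_two_points_are_endpoints(self):
        np.testing.assert_allclose(ga.grid_values(0, 1, 2), [0, 1])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ga.grid_values(1, 0, 5)
        with pytest.raises(ValueError):
            ga.grid_values(0, 1, 1)


@pytest.fixture()
def worked_grid():
    return ga.ParameterGrid(names=("A", "B"), lowers=(-2.0, -0.3), uppers=(2.0, 1.0), n_points=5)


class TestDecode:
    def test_worked_example(self, worked_grid):
        v1 = ga.decode(np.array([0, 1]), worked_grid)
        assert v1["A"] == pytest.approx(-2.0)
        assert v1["B"] == pytest.approx(0.025)
        v2 = ga.decode(np.array([4, 0]), worked_grid)
        assert v2["A"] == pytest.approx(2.0)
        assert v2["B"] == pytest.approx(-0.3)

    def test_symmetric_midpoint(self, worked_grid):
        assert ga.decode(np.array([2, 0]), worked_grid)["A"] == 0.0

    def test_out_of_range_rejected(self, worked_grid):
        with pytest.raises(IndexError):
            ga.decode(np.array([5, 0]), worked_grid)


class TestMate:
    def test_worked_example(self):
        o1, o2 = ga.mate(np.array([0, 1]), np.array([4, 0]), point=1)
        assert o1.tolist() == [4, 1]
        assert o2.tolist() == [0, 0]

    def test_identical_parents(self):
        p = np.array([1, 2, 3])
        o1, o2 = ga.mate(p, p, point=2)
        assert o1.tolist() == o2.tolist() == [1, 2, 3]

    def test_degenerate_crossover_preserves_parent_set(self):
        p1, p2 = np.array([0, 1]), np.array([4, 0])
        o1, o2 = ga.mate(p1, p2, point=0)
        assert {tuple(o1), tuple(o2)} == {tuple(p1), tuple(p2)}


class TestMutate:
    def test_p_zero_unchanged(self, rng):
        g = np.array([3, 1, 4])
        assert ga.mutate(g, p=0.0, rng=rng).tolist() == [3, 1, 4]

    def test_length_one_unchanged(self, rng):
        assert ga.mutate(np.array([2]), p=1.0, rng=rng).tolist() == [2]

    def test_permutation_preserves_multiset(self, rng):
        g = np.array([0, 1, 2])
        out = ga.mutate(g, p=1.0, rng=rng)
        assert sorted(out.tolist()) == [0, 1, 2]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 29), min_size=1, max_size=14))
def test_decoded_values_stay_in_range(indices):
    """Grid-index closure: any genome decodes inside the declared ranges."""
    n = len(indices)
    grid = ga.ParameterGrid(
        names=tuple(f"p{i}" for i in range(n)),
        lowers=tuple(-1.0 - i for i in range(n)),
        uppers=tuple(2.0 + i for i in range(n)),
        n_points=30,
    )
    vals = ga.decode(np.array(indices), grid)
    for i, name in enumerate(grid.names):
        assert grid.lowers[i] <= vals[name] <= grid.uppers[i]


class TestCortexStriatumCorrelation:
    def _result_with_traces(self, cx, spn_each):
        n_trials, n_bins = cx.shape
        names = [f"{r}_ch{c}" for r in ("Cx", "dSPN", "iSPN", "GPe", "STN", "GPi", "Thal")
                 for c in (1, 2)] + ["CxI", "FSI"]
        traces = np.zeros((n_trials, n_bins, len(names)), np.float32)
        idx = {n: i for i, n in enumerate(names)}
        traces[:, :, idx["Cx_ch1"]] = cx / 2
        traces[:, :, idx["Cx_ch2"]] = cx / 2
        for r in ("dSPN", "iSPN"):
            for c in (1, 2):
                traces[:, :, idx[f"{r}_ch{c}"]] = spn_each
        return TrialBatchResult(
            choices=np.ones(n_trials, dtype=int),
            decision_times_ms=np.full(n_trials, n_bins * 5.0),
            pop_rates_hz=np.zeros((n_trials, len(names))),
            pop_names=names,
            final_thal_rates_hz=np.full((n_trials, 2), 30.0),
            rate_traces=traces,
        )

    def test_planted_positive_slope(self, rng):
        cx = rng.uniform(5, 30, size=(10, 40))
        spn = 0.3 * cx / 4 + 0.2 * rng.standard_normal((10, 40))
        res = self._result_with_traces(cx, spn)
        assert ga.cortex_striatum_correlation(res) > 0.5

    def test_anticorrelated_is_negative(self, rng):
        cx = rng.uniform(5, 30, size=(10, 40))
        res = self._result_with_traces(cx, -0.3 * cx / 4)
        assert ga.cortex_striatum_correlation(res) < 0


class TestFitnessRecord:
    def test_always_timeout_rejected(self):
        rec = ga.FitnessRecord(1.0, 0.5, {"Cx": True})
        assert not rec.accepted()

    def test_out_of_range_rate_rejected(self):
        rec = ga.FitnessRecord(0.0, 0.5, {"Cx": False})
        assert not rec.accepted()


class ToySurrogate:
    """2-parameter surrogate fitness with a known acceptance region:
    timeouts fall below 1% inside a disc, correlation is positive in a
    half-plane."""

    def __init__(self):
        self.grid = ga.ParameterGrid(
            names=("x", "y"), lowers=(-1.0, -1.0), uppers=(1.0, 1.0), n_points=30
        )

    def evaluate(self, values):
        x, y = values["x"], values["y"]
        timeout = 0.0 if x**2 + y**2 < 0.5 else 0.5
        corr = 0.8 if x + y > -0.5 else -0.2
        return ga.FitnessRecord(timeout, corr, {"all": True})

    def brute_force_accepted(self):
        region = set()
        for i in range(30):
            for j in range(30):
                v = ga.decode(np.array([i, j]), self.grid)
                if self.evaluate(v).accepted():
                    region.add((i, j))
        return region


class TestEvolve:
    def test_target_zero_returns_empty(self):
        toy = ToySurrogate()
        res = ga.evolve(toy.grid, toy.evaluate, target_solutions=0)
        assert res.accepted == []

    def test_all_acceptable_fills_fast(self):
        grid = ga.ParameterGrid(("x",), (0.0,), (1.0,), n_points=5)
        res = ga.evolve(
            grid, lambda v: ga.FitnessRecord(0.0, 0.5, {"all": True}),
            population_size=10, target_solutions=4, seed=0,
        )
        assert res.n_accepted == 4
        assert res.n_generations <= 1

    def test_recovers_brute_force_region(self):
        """The GA archives >= 90% of the enumerated acceptance region of a
        toy surrogate within 200 generations (mean over a fixed seed set)."""
        toy = ToySurrogate()
        region = toy.brute_force_accepted()
        coverages = []
        for seed in (0, 1, 2):
            res = ga.evolve(
                toy.grid, toy.evaluate, population_size=10, max_iter=200,
                target_solutions=10_000, seed=seed,
            )
            found = {tuple(a["genome"].tolist()) for a in res.accepted}
            coverages.append(len(found & region) / len(region))
            # everything archived is genuinely acceptable
            assert found <= region
        assert np.mean(coverages) >= 0.9

    def test_zero_solutions_reported_not_raised(self):
        toy = ToySurrogate()
        res = ga.evolve(
            toy.grid, lambda v: ga.FitnessRecord(1.0, -1.0, {"all": True}),
            max_iter=3, target_solutions=5, seed=0,
        )
        assert res.n_accepted == 0
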