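"""Binned-index genetic algorithm for sampling acceptable CBGT networks.

Each free projection efficacy's range is discretized into an
endpoint-inclusive grid (30 points by default); a genome is the vector of
grid indices, which mating and mutation manipulate so that decoded values
can never leave their ranges.  Candidates are screened on two criteria:
fewer than 1% probe-trial timeouts (so the DDM has enough decided trials)
and a positive correlation between cortical and striatal activity (so the
network operates in a basal-ganglia-driven rather than a purely
cortico-thalamic regime); mean firing rates must additionally stay inside
the configured physiological ranges.  Tournament selection (size 3) on the
lexicographic fitness (timeout fraction first, correlation second) drives
the search; every candidate that meets the acceptance criteria is
archived, and the run stops after a target number of solutions or a
maximum number of generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .network import (
    FREE_PARAMETERS,
    TIMEOUT,
    NetworkParams,
    build,
    simulate_trials,
)

DEFAULT_RATE_RANGES: dict[str, tuple[float, float]] = {
    # reconstructed physiological ranges (Hz), per region; the thalamic
    # ceiling also rejects networks whose trial-mean relay rate sits near
    # the 30 Hz decision threshold — the cortico-thalamic-driven regime in
    # which the basal ganglia no longer gate the decision
    "Cx": (0.5, 60.0), "CxI": (1.0, 80.0), "FSI": (1.0, 80.0),
    "dSPN": (0.2, 60.0), "iSPN": (0.2, 60.0), "GPe": (10.0, 150.0),
    "STN": (2.0, 100.0), "GPi": (20.0, 120.0), "Thal": (1.0, 25.0),
}


@dataclass(frozen=True)
class ParameterGrid:
    names: tuple[str, ...]
    lowers: tuple[float, ...]
    uppers: tuple[float, ...]
    n_points: int = 30

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grids need at least 2 points")
        for name, lo, hi in zip(self.names, self.lowers, self.uppers):
            if lo >= hi:
                raise ValueError(f"parameter {name}: lower bound must be below upper")

    def values(self, i: int) -> np.ndarray:
        return grid_values(self.lowers[i], self.uppers[i], self.n_points)

    @property
    def n_params(self) -> int:
        return len(self.names)


def grid_values(lower: float, upper: float, n_points: int) -> np.ndarray:
    """Endpoint-inclusive even grid over [lower, upper]."""
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(lower, upper, n_points)


def decode(genome: np.ndarray, grid: ParameterGrid) -> dict[str, float]:
    """Map grid indices to parameter values."""
    genome = np.asarray(genome)
    if genome.size != grid.n_params:
        raise ValueError("genome length does not match the grid")
    out = {}
    for i, name in enumerate(grid.names):
        idx = int(genome[i])
        vals = grid.values(i)
        if not 0 <= idx < len(vals):
            raise IndexError(f"index {idx} out of range for parameter {name}")
        out[name] = float(vals[idx])
    return out


def mate(parent1: np.ndarray, parent2: np.ndarray, point: int) -> tuple[np.ndarray, np.ndarray]:
    """One-point crossover exchanging the index segments before ``point``."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    o1 = np.concatenate([p2[:point], p1[point:]])
    o2 = np.concatenate([p1[:point], p2[point:]])
    return o1, o2


def mutate(
    genome: np.ndarray, p: float = 0.2, rng: np.random.Generator | None = None
) -> np.ndarray:
    """With probability ``p``, permute the genome's index positions."""
    rng = rng or np.random.default_rng()
    genome = np.asarray(genome)
    if rng.random() < p:
        return genome[rng.permutation(genome.size)]
    return genome.copy()


def reset_genes(
    genome: np.ndarray, n_points: int, indpb: float, rng: np.random.Generator
) -> np.ndarray:
    """Redraw each index uniformly with per-gene probability ``indpb``.

    Segment-swap crossover and index shuffling only recombine values
    already present in the population, so without an operator that
    introduces fresh indices the gene pool fixates; this reset keeps the
    search ergodic over the grid.
    """
    genome = genome.copy()
    mask = rng.random(genome.size) < indpb
    if mask.any():
        genome[mask] = rng.integers(0, n_points, size=int(mask.sum()))
    return genome


@dataclass
class FitnessRecord:
    timeout_fraction: float
    cx_striatum_correlation: float
    rate_range_ok: dict[str, bool] = field(default_factory=dict)
    mean_rates: dict[str, float] = field(default_factory=dict)

    def accepted(self, max_timeout: float = 0.01) -> bool:
        return (
            self.timeout_fraction < max_timeout
            and self.cx_striatum_correlation > 0.0
            and all(self.rate_range_ok.values())
        )

    @property
    def key(self) -> tuple[float, float]:
        """Lexicographic minimization key: timeouts first, then -correlation."""
        return (self.timeout_fraction, -self.cx_striatum_correlation)


def cortex_striatum_correlation(res) -> float:
    """Pearson r between binned summed excitatory-cortex and summed SPN
    rates, pooled over trials (bins past each trial's decision excluded)."""
    if res.rate_traces is None:
        raise ValueError("evaluation requires rate traces")
    names = res.pop_names
    idx = {n: i for i, n in enumerate(names)}
    cx = res.rate_traces[:, :, idx["Cx_ch1"]] + res.rate_traces[:, :, idx["Cx_ch2"]]
    spn = sum(
        res.rate_traces[:, :, idx[f"{r}_ch{c}"]]
        for r in ("dSPN", "iSPN") for c in (1, 2)
    )
    n_bins = cx.shape[1]
    bin_ms = res.decision_times_ms.max() / n_bins if n_bins else 1.0
    # use only bins before each trial's decision
    xs, ys = [], []
    for b in range(res.n_trials):
        last = int(np.ceil(res.decision_times_ms[b] / 5.0))
        xs.append(cx[b, :last])
        ys.append(spn[b, :last])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(sps.pearsonr(x, y).statistic)


def evaluate_network(
    params: NetworkParams,
    n_trials: int = 24,
    seed: int | np.random.Generator | None = None,
    rate_ranges: dict[str, tuple[float, float]] | None = None,
) -> FitnessRecord:
    """Screen one candidate: probe trials with plasticity off."""
    ranges = rate_ranges or DEFAULT_RATE_RANGES
    compiled = build(params)
    res = simulate_trials(
        compiled, n_trials=n_trials, seed=seed, collect_traces=True
    )
    timeout = res.timeout_fraction
    corr = cortex_striatum_correlation(res)
    act = res.mean_activity()
    mean_rates: dict[str, float] = {}
    ok: dict[str, bool] = {}
    for region, (lo, hi) in ranges.items():
        keys = [k for k in act if k == region or k.startswith(f"{region}_ch")]
        r = float(np.mean([act[k] for k in keys]))
        mean_rates[region] = r
        ok[region] = lo <= r <= hi
    return FitnessRecord(
        timeout_fraction=timeout,
        cx_striatum_correlation=corr,
        rate_range_ok=ok,
        mean_rates=mean_rates,
    )


def make_network_evaluator(
    base: NetworkParams,
    n_trials: int = 24,
    seed: int = 0,
    rate_ranges: dict[str, tuple[float, float]] | None = None,
):
    """Evaluator closure mapping decoded efficacies to a FitnessRecord."""
    ss = np.random.SeedSequence(seed)

    def _eval(values: dict[str, float]) -> FitnessRecord:
        params = base.with_efficacies(values)
        child = ss.spawn(1)[0]
        return evaluate_network(
            params, n_trials=n_trials, seed=np.random.default_rng(child),
            rate_ranges=rate_ranges,
        )

    return _eval


def default_free_grid(
    base: NetworkParams, frac: float = 0.3, n_points: int = 30
) -> ParameterGrid:
    """Grid over the 14 free efficacies, each spanning default*(1 +/- frac)."""
    lowers, uppers = [], []
    for name in FREE_PARAMETERS:
        e = base.efficacy(name)
        lowers.append(e * (1 - frac))
        uppers.append(e * (1 + frac))
    return ParameterGrid(
        names=tuple(FREE_PARAMETERS), lowers=tuple(lowers), uppers=tuple(uppers),
        n_points=n_points,
    )


@dataclass
class GAResult:
    accepted: list[dict]  # each: {'genome', 'values', 'fitness'}
    n_generations: int
    n_evaluations: int

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def evolve(
    grid: ParameterGrid,
    evaluate_fn,
    population_size: int = 10,
    tournament_size: int = 3,
    mutation_p: float = 0.2,
    crossover_p: float = 0.7,
    reset_indpb: float = 0.4,
    max_iter: int = 2000,
    target_solutions: int = 300,
    max_timeout: float = 0.01,
    seed: int | None = 0,
    dedupe: bool = True,
) -> GAResult:
    """Run the GA until ``target_solutions`` acceptable configurations are
    archived or ``max_iter`` generations elapse.

    ``evaluate_fn`` maps decoded parameter values to a FitnessRecord.
    Finding zero acceptable solutions is reported in the result, not
    raised.
    """
    rng = np.random.default_rng(seed)
    if target_solutions <= 0:
        return GAResult(accepted=[], n_generations=0, n_evaluations=0)

    pop = [rng.integers(0, grid.n_points, size=grid.n_params) for _ in range(population_size)]
    fits: list[FitnessRecord | None] = [None] * population_size
    accepted: list[dict] = []
    seen: set[tuple] = set()
    n_eval = 0

    def eval_and_archive(i: int) -> None:
        nonlocal n_eval
        g = pop[i]
        values = decode(g, grid)
        fit = evaluate_fn(values)
        n_eval += 1
        fits[i] = fit
        key = tuple(int(x) for x in g)
        if fit.accepted(max_timeout) and (not dedupe or key not in seen):
            seen.add(key)
            accepted.append({"genome": g.copy(), "values": values, "fitness": fit})

    for i in range(population_size):
        eval_and_archive(i)
        if len(accepted) >= target_solutions:
            return GAResult(accepted=accepted[:target_solutions], n_generations=0, n_evaluations=n_eval)

    gen = 0
    while len(accepted) < target_solutions and gen < max_iter:
        gen += 1
        # tournament selection, size 3, population_size picks
        new_pop = []
        for _ in range(population_size):
            contenders = rng.integers(0, population_size, size=tournament_size)
            best = min(contenders, key=lambda i: fits[i].key)
            new_pop.append(pop[best].copy())
        # mating: offspring overwrite the mated parents
        for i in range(0, population_size - 1, 2):
            if rng.random() < crossover_p and grid.n_params > 1:
                point = int(rng.integers(1, grid.n_params))
                new_pop[i], new_pop[i + 1] = mate(new_pop[i], new_pop[i + 1], point)
        pop = [
            reset_genes(mutate(g, mutation_p, rng), grid.n_points, reset_indpb, rng)
            for g in new_pop
        ]
        for i in range(population_size):
            eval_and_archive(i)
            if len(accepted) >= target_solutions:
                break

    return GAResult(accepted=accepted, n_generations=gen, n_evaluations=n_eval)
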