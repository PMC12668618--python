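"""Decision-policy manifolds over the (v, a) plane.

RT, accuracy, and reward-rate surfaces are estimated by DDM simulation on
a grid of drift rates and boundary heights (non-decision time and starting
bias held fixed at cohort values).  Learning trajectories — one fitted
(v, a) point per plasticity stage — are scored against each objective by
the cosine distance between the observed displacement and the local
gradient of the objective's surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .ddm import DDMParams, simulate_ddm
from .stats import paired_t, repeated_measures_f

OBJECTIVES = ("rt", "accuracy", "reward_rate")


def reward_rate(accuracy: float | np.ndarray, rt: float | np.ndarray) -> float | np.ndarray:
    """Rewards per second: (1 - p_err) / RT with RT = DT + T0."""
    rt = np.asarray(rt, float)
    if np.any(rt <= 0):
        raise ValueError("reaction time must be positive")
    out = np.asarray(accuracy, float) / rt
    return float(out) if out.ndim == 0 else out


@dataclass
class ManifoldGrid:
    """Behavioral surfaces sampled on a (v, a) grid."""

    v_values: np.ndarray
    a_values: np.ndarray
    rt: np.ndarray  # (len(v), len(a)), seconds
    accuracy: np.ndarray
    rr: np.ndarray
    t_fixed: float
    z_fixed: float
    seeds: int
    trials: int
    smooth_width: int = 3
    _interp: dict = field(default_factory=dict, repr=False)

    def surface(self, objective: str) -> np.ndarray:
        return {"rt": self.rt, "accuracy": self.accuracy, "reward_rate": self.rr}[objective]

    def to_frame(self) -> pd.DataFrame:
        vv, aa = np.meshgrid(self.v_values, self.a_values, indexing="ij")
        return pd.DataFrame({
            "v": vv.ravel(), "a": aa.ravel(),
            "rt": self.rt.ravel(), "acc": self.accuracy.ravel(),
            "rr": self.rr.ravel(),
        })


def build_manifold(
    v_values: np.ndarray,
    a_values: np.ndarray,
    t_fixed: float,
    z_fixed: float = 0.5,
    seeds: int = 15,
    trials: int = 200,
    dt: float = 1e-3,
    base_seed: int = 0,
    smooth_width: int = 3,
) -> ManifoldGrid:
    """Simulate the DDM at every grid node, averaging over seeds.

    Accuracy is the upper-boundary fraction (the upper boundary codes the
    correct/rewarded response), RT the mean reaction time, and reward rate
    their elementwise ratio — exactly accuracy / RT by construction.
    """
    v_values = np.asarray(v_values, float)
    a_values = np.asarray(a_values, float)
    rt = np.empty((v_values.size, a_values.size))
    acc = np.empty_like(rt)
    ss = np.random.SeedSequence(base_seed)
    node_seeds = ss.spawn(rt.size)
    idx = 0
    for i, v in enumerate(v_values):
        for j, a in enumerate(a_values):
            p = DDMParams(v=float(v), a=float(a), t=t_fixed, z=z_fixed)
            child = node_seeds[idx].spawn(seeds)
            idx += 1
            accs, rts = [], []
            for s in range(seeds):
                samp = simulate_ddm(p, n=trials, dt=dt, seed=np.random.default_rng(child[s]))
                accs.append(samp.accuracy)
                rts.append(float(np.mean(samp.rt)))
            acc[i, j] = np.mean(accs)
            rt[i, j] = np.mean(rts)
    return ManifoldGrid(
        v_values=v_values, a_values=a_values, rt=rt, accuracy=acc,
        rr=acc / rt, t_fixed=t_fixed, z_fixed=z_fixed,
        seeds=seeds, trials=trials, smooth_width=smooth_width,
    )


def _smooth(surface: np.ndarray, width: int) -> np.ndarray:
    """Separable moving-average smoothing with edge replication."""
    if width <= 1:
        return surface
    k = width // 2
    padded = np.pad(surface, k, mode="edge")
    kernel = np.ones(width) / width
    tmp = np.apply_along_axis(lambda m: np.convolve(m, kernel, mode="valid"), 0, padded)
    return np.apply_along_axis(lambda m: np.convolve(m, kernel, mode="valid"), 1, tmp)


def gradient_at(
    grid: ManifoldGrid, objective: str, point: tuple[float, float]
) -> np.ndarray:
    """Gradient of the objective's *improvement* direction at (v, a).

    Central finite differences on the smoothed surface, bilinearly
    interpolated to the query point.  RT improves downward, so its gradient
    is negated; accuracy and reward rate improve upward.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    key = (objective, grid.smooth_width)
    if key not in grid._interp:
        surf = _smooth(grid.surface(objective), grid.smooth_width)
        gv, ga = np.gradient(surf, grid.v_values, grid.a_values)
        grid._interp[key] = (
            RegularGridInterpolator((grid.v_values, grid.a_values), gv),
            RegularGridInterpolator((grid.v_values, grid.a_values), ga),
        )
    fv, fa = grid._interp[key]
    pt = np.atleast_2d(np.asarray(point, float))
    g = np.array([float(fv(pt)[0]), float(fa(pt)[0])])
    return -g if objective == "rt" else g


def cosine_distance(step: np.ndarray, reference: np.ndarray) -> float:
    """1 - cos(angle) between the observed step and a reference direction.

    Invariant to positive rescaling of either vector (the display-time
    rescaling of the reference to the observed step length drops out).
    """
    step = np.asarray(step, float)
    reference = np.asarray(reference, float)
    ns, nr = np.linalg.norm(step), np.linalg.norm(reference)
    if ns == 0 or nr == 0:
        raise ValueError("cosine distance requires two nonzero vectors")
    return float(1.0 - np.dot(step, reference) / (ns * nr))


def trajectory_distances(
    trajectories: dict[str, np.ndarray], grid: ManifoldGrid
) -> pd.DataFrame:
    """Per-network, per-step cosine distances to each objective's gradient.

    ``trajectories`` maps network id to an (n_stages, 2) array of fitted
    (v, a) points; each step is scored against the gradient evaluated at
    the step's start point.  Zero-length steps are skipped.
    """
    recs = []
    for nid, pts in trajectories.items():
        pts = np.asarray(pts, float)
        for s in range(len(pts) - 1):
            step = pts[s + 1] - pts[s]
            if np.linalg.norm(step) == 0:
                continue
            for obj in OBJECTIVES:
                ref = gradient_at(grid, obj, tuple(pts[s]))
                if np.linalg.norm(ref) == 0:
                    continue
                recs.append({
                    "network_id": nid, "step": s, "objective": obj,
                    "distance": cosine_distance(step, ref),
                })
    return pd.DataFrame(recs)


def compare_objectives(
    trajectories: dict[str, np.ndarray], grid: ManifoldGrid
) -> tuple[pd.DataFrame, dict]:
    """Score trajectories against all objectives and test for an objective
    effect.

    Returns the per-step distance table and a summary with per-objective
    means, a one-way repeated-measures F across the three objectives (on
    per-network mean distances), and paired t-tests between objective
    pairs.
    """
    dist = trajectory_distances(trajectories, grid)
    if dist.empty:
        raise ValueError("no scorable steps in the supplied trajectories")
    per_net = dist.pivot_table(
        index="network_id", columns="objective", values="distance", aggfunc="mean"
    )[list(OBJECTIVES)].dropna()
    if len(per_net) < 2:
        raise ValueError("need at least 2 networks with complete distances")
    F, p, df1, df2 = repeated_measures_f(per_net.to_numpy())
    summary = {
        "mean_distance": {o: float(per_net[o].mean()) for o in OBJECTIVES},
        "anova": {"F": F, "p": p, "df": (df1, df2)},
        "paired_t": {},
        "n_networks": int(len(per_net)),
    }
    for i, a in enumerate(OBJECTIVES):
        for b in OBJECTIVES[i + 1:]:
            t, pv, df = paired_t(per_net[a].to_numpy(), per_net[b].to_numpy())
            summary["paired_t"][f"{a} vs {b}"] = {"t": t, "p": pv, "df": df}
    return dist, summary
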