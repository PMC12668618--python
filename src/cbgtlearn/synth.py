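"""Synthetic surrogate datasets mirroring the statistical structure of the
study, so every analysis stage is testable without spiking simulation.

Three latent-factor generators cover the downstream pipeline: CCA cohorts
(feature and policy matrices driven by shared latent factors), driver
cohorts (feature-change matrices built from a known driver matrix), and
DDM cohorts (RT/choice samples from known decision-policy parameters).  A
toy spiking network generator provides minimal, optionally hand-biased
network configurations for simulator tests.  All generators are
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import BehaviorSample, DDMParams, simulate_ddm
from .ensembles import FEATURE_COLUMNS, POLICY_COLUMNS
from .network import NetworkParams


def _unit_columns(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    return M / np.linalg.norm(M, axis=0, keepdims=True)


def random_loadings(n_rows: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random orthonormal loading columns (a Haar-random frame).

    Orthonormality keeps the planted factors identifiable: near-collinear
    loadings would let noise swallow the weaker canonical directions.
    """
    Q, _ = np.linalg.qr(rng.standard_normal((n_rows, k)))
    return Q


@dataclass
class SurrogateCohortSpec:
    """Latent-factor cohort for CCA recovery tests.

    ``k`` shared factors drive both the 16 firing-rate features and the 3
    policy parameters; independent Gaussian noise controls the planted
    canonical correlations through the signal-to-noise ratio.
    """

    n_networks: int = 300
    n_factors: int = 3
    factor_scale: float = 1.0
    noise_scale: float = 0.2
    feature_loadings: np.ndarray | None = None  # (16, k), unit-norm columns
    policy_loadings: np.ndarray | None = None  # (3, k), unit-norm columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_factors > 3:
            raise ValueError("at most 3 latent factors (policy side has 3 columns)")


def gen_cca_cohort(spec: SurrogateCohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature and policy matrices sharing ``n_factors`` latent factors."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_factors
    A = (
        _unit_columns(spec.feature_loadings)
        if spec.feature_loadings is not None
        else random_loadings(len(FEATURE_COLUMNS), k, rng)
    )
    B = (
        _unit_columns(spec.policy_loadings)
        if spec.policy_loadings is not None
        else random_loadings(len(POLICY_COLUMNS), k, rng)
    )
    Z = rng.standard_normal((spec.n_networks, k)) * spec.factor_scale
    F = Z @ A.T + spec.noise_scale * rng.standard_normal((spec.n_networks, len(FEATURE_COLUMNS)))
    D = Z @ B.T + spec.noise_scale * rng.standard_normal((spec.n_networks, len(POLICY_COLUMNS)))
    return (
        pd.DataFrame(F, columns=list(FEATURE_COLUMNS)),
        pd.DataFrame(D, columns=list(POLICY_COLUMNS)),
    )


@dataclass
class SurrogateDriverSpec:
    """ΔF generator with a known driver matrix S0.

    Ensemble scores C (n x 3) are i.i.d. normal and the feature change is
    ΔF = C·S0·Vᵀ with V a 16x5 orthonormal basis.  The companion ensemble
    loadings are U = V·S0⁺, so that in the noiseless case ΔF·V = C·S0 and
    ΔF·U = C exactly, and the normal-equation solve returns S0 to machine
    precision.
    """

    n_networks: int = 300
    V: np.ndarray | None = None  # (16, 5), orthonormal columns
    S0: np.ndarray | None = None  # (3, 5), full row rank
    score_scale: float = 1.0
    score_mean: float = 0.0  # nonzero gives the cohort a net change direction
    noise_scale: float = 0.0
    seed: int = 0


def gen_driver_cohort(
    spec: SurrogateDriverSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Returns (delta_F, U, V, S0) with ΔF·U = C and ΔF·V = C·S0."""
    rng = np.random.default_rng(spec.seed)
    p = len(FEATURE_COLUMNS)
    if spec.V is None:
        V, _ = np.linalg.qr(rng.standard_normal((p, 5)))
    else:
        V = np.asarray(spec.V, float)
    S0 = (
        np.asarray(spec.S0, float)
        if spec.S0 is not None
        else rng.standard_normal((3, 5))
    )
    if np.linalg.matrix_rank(S0) < 3:
        raise ValueError("S0 must have full row rank")
    U = V @ np.linalg.pinv(S0)
    C = rng.standard_normal((spec.n_networks, 3)) * spec.score_scale + spec.score_mean
    delta = C @ S0 @ V.T
    if spec.noise_scale > 0:
        delta = delta + spec.noise_scale * rng.standard_normal(delta.shape)
    return delta, U, V, S0


def gen_ddm_cohort(
    param_table: pd.DataFrame,
    trials_per_network: int = 300,
    seed: int = 0,
    dt: float = 1e-3,
) -> dict[str, BehaviorSample]:
    """RT/choice samples from known DDM parameters, one per table row.

    ``param_table`` needs columns v, a, t (optional z); the index provides
    network ids.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(param_table))
    out = {}
    for (nid, row), child in zip(param_table.iterrows(), children):
        p = DDMParams(
            v=float(row["v"]), a=float(row["a"]), t=float(row["t"]),
            z=float(row.get("z", 0.5)),
        )
        samp = simulate_ddm(p, n=trials_per_network, dt=dt, seed=np.random.default_rng(child))
        samp.network_id = str(nid)
        out[str(nid)] = samp
    return out


def gen_toy_network(bias: float = 1.0, seed: int = 0) -> NetworkParams:
    """Minimal symmetric CBGT network (tens of neurons per population);
    ``bias > 1`` scales the channel-1 corticostriatal dSPN efficacy for
    deterministic-choice tests."""
    if bias <= 0:
        raise ValueError("bias must be positive")
    return NetworkParams(seed=seed, channel1_dspn_bias=bias)
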