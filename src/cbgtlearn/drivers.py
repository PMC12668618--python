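"""Ensemble drivers: least-squares decomposition of learning-induced
firing-rate changes into control-ensemble contributions.

Given per-network feature changes ΔF (post- minus pre-learning, expressed
in the standardized baseline feature space), the pipeline is exactly
linear: P = ΔF·V projects onto the top principal components of ΔF,
C = ΔF·U projects onto the baseline control-ensemble loadings, and the
driver matrix S = (CᵀC)⁻¹CᵀP expresses each firing-rate PC as a
combination of ensemble adjustments.  Weighting the columns of S by the
variance fraction of the corresponding PC gives one net 3-vector of
ensemble modulation per cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .stats import two_way_anova

ENSEMBLE_NAMES = ("responsiveness", "pliancy", "choice")


@dataclass
class DriverResult:
    """S (ensembles x PCs), PC loadings V, variance fractions, projections."""

    S: np.ndarray  # (3, k)
    V: np.ndarray  # (16, k)
    variance_fractions: np.ndarray  # (k,)
    P: np.ndarray  # (n, k)
    C: np.ndarray  # (n, 3)
    condition_number: float
    used_pinv: bool = False

    def weighted(self) -> np.ndarray:
        return weighted_driver(self.S, self.variance_fractions)


def pca_delta(delta: np.ndarray, k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of ΔF (columns of V) and their explained
    variance fractions."""
    delta = np.asarray(delta, float)
    if delta.shape[0] <= k:
        raise ValueError(f"need more than {k} networks for {k} PCs, got {delta.shape[0]}")
    pca = PCA(n_components=k)
    pca.fit(delta)
    V = pca.components_.T.copy()
    # anchor each PC's sign along the cohort's mean change, so that driver
    # signs are meaningful (and flip when the direction of change flips)
    mean_dir = delta.mean(axis=0)
    for i in range(k):
        if mean_dir @ V[:, i] < 0:
            V[:, i] *= -1.0
    return V, pca.explained_variance_ratio_


def project(delta: np.ndarray, V: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P = ΔF·V (n x k) and C = ΔF·U (n x 3)."""
    delta = np.asarray(delta, float)
    return delta @ np.asarray(V, float), delta @ np.asarray(U, float)


def solve_drivers(
    P: np.ndarray, C: np.ndarray, cond_limit: float = 1e8
) -> tuple[np.ndarray, float, bool]:
    """Driver matrix from the normal equation S = (CᵀC)⁻¹CᵀP.

    Returns (S, condition number of CᵀC, pinv-fallback flag).  An
    ill-conditioned Gram matrix triggers a pseudo-inverse solve with a
    warning rather than an exception.
    """
    P = np.asarray(P, float)
    C = np.asarray(C, float)
    G = C.T @ C
    cond = float(np.linalg.cond(G))
    if cond > cond_limit or not np.isfinite(cond):
        warnings.warn(
            f"CᵀC ill-conditioned (cond={cond:.3g}); using pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.linalg.pinv(C) @ P, cond, True
    S = np.linalg.solve(G, C.T @ P)
    return S, cond, False


def weighted_driver(S: np.ndarray, variance_fractions: np.ndarray) -> np.ndarray:
    """Variance-weighted sum over PC columns of S — the net modulation of
    the three control ensembles."""
    S = np.asarray(S, float)
    w = np.asarray(variance_fractions, float)
    if S.shape[1] != w.size:
        raise ValueError("one variance fraction per column of S is required")
    return S @ w


def decompose(delta: np.ndarray, U: np.ndarray, k: int = 5) -> DriverResult:
    """Full ΔF → (V, P, C, S) pipeline for one cohort or class."""
    V, frac = pca_delta(delta, k=k)
    P, C = project(delta, V, U)
    S, cond, used_pinv = solve_drivers(P, C)
    return DriverResult(
        S=S, V=V, variance_fractions=frac, P=P, C=C,
        condition_number=cond, used_pinv=used_pinv,
    )


def reconstruction_rank_corr(res: DriverResult) -> np.ndarray:
    """Spearman rank correlation, per PC, between the actual projections P
    and the reconstruction C·S (goodness of the driver fit)."""
    pred = res.C @ res.S
    out = np.empty(res.P.shape[1])
    for i in range(res.P.shape[1]):
        if np.std(res.P[:, i]) == 0 or np.std(pred[:, i]) == 0:
            out[i] = np.nan
        else:
            out[i] = sps.spearmanr(res.P[:, i], pred[:, i]).statistic
    return out


def sequence_drivers(
    delta: np.ndarray,
    sequences: np.ndarray,
    U: np.ndarray,
    delta_rr: np.ndarray | None = None,
    speed_class: np.ndarray | None = None,
    k: int = 5,
    min_group: int = 5,
) -> dict:
    """Per-outcome-sequence driver decomposition after the first 2 learning
    trials, plus reward-rate-change statistics.

    Networks are grouped by their 2-trial outcome label (U-U, U-R, R-U,
    R-R); ΔF, PCA, S and the weighted driver are recomputed per group.
    Groups smaller than ``min_group`` are flagged and skipped.  When
    ``delta_rr`` and ``speed_class`` are given, a two-way ANOVA
    (sequence x class) and pairwise t-tests on ΔRR are included.
    """
    delta = np.asarray(delta, float)
    sequences = np.asarray(sequences)
    order = ["U-U", "U-R", "R-U", "R-R"]
    groups: dict = {}
    flagged: list = []
    for lab in order:
        idx = np.nonzero(sequences == lab)[0]
        if idx.size < min_group or idx.size <= k:
            flagged.append(lab)
            continue
        res = decompose(delta[idx], U, k=k)
        groups[lab] = {
            "n": int(idx.size),
            "result": res,
            "weighted_driver": res.weighted(),
        }
    out: dict = {"groups": groups, "flagged": flagged}

    if delta_rr is not None:
        delta_rr = np.asarray(delta_rr, float)
        df = pd.DataFrame({"delta_rr": delta_rr, "sequence": sequences})
        if speed_class is not None:
            df["speed"] = np.asarray(speed_class)
            out["anova"] = two_way_anova(df, "delta_rr", "sequence", "speed")
        pairs = {}
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                xa = delta_rr[sequences == a]
                xb = delta_rr[sequences == b]
                if xa.size >= 2 and xb.size >= 2:
                    t, p = sps.ttest_ind(xa, xb)
                    pairs[f"{a} vs {b}"] = (float(t), float(p))
        out["pairwise_t"] = pairs
        out["delta_rr_by_sequence"] = {
            lab: float(np.mean(delta_rr[sequences == lab]))
            for lab in order
            if np.any(sequences == lab)
        }
    return out
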