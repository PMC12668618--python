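"""Control ensembles: Sigma/Delta firing-rate features and their canonical
correlation with fitted DDM parameters.

A cohort of networks yields a 16-column feature matrix F (per-region summed
rates across the two action channels, per-region channel differences, and
the two channel-shared populations CxI and FSI) and a 3-column policy
matrix D of fitted (a, t, v).  CCA finds paired low-dimensional projections
u, v maximizing corr(F u, D v); held-out correlations from k-fold
validation are compared against a row-shuffle null to decide how many
components are real.  The retained components are the *control ensembles*,
labelled responsiveness / pliancy / choice from the signs of their (a, t, v)
loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import CCA
from sklearn.model_selection import KFold

CHANNEL_REGIONS = ("Cx", "dSPN", "iSPN", "GPe", "STN", "GPi", "Thal")
SHARED_REGIONS = ("CxI", "FSI")

FEATURE_COLUMNS = (
    tuple(f"{r}_sum" for r in CHANNEL_REGIONS)
    + tuple(f"{r}_diff" for r in CHANNEL_REGIONS)
    + SHARED_REGIONS
)
POLICY_COLUMNS = ("a", "t", "v")


@dataclass
class Scaler:
    """Column standardization (mean/scale) serialized for reuse on ΔF."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, float)
        sd = X.std(axis=0, ddof=0)
        return cls(mean=X.mean(axis=0), scale=np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale

    def scale_only(self, X: np.ndarray) -> np.ndarray:
        """Apply the scale without re-centering (for difference data)."""
        return np.asarray(X, float) / self.scale


@dataclass
class EnsembleSet:
    """CCA loadings, canonical correlations, and validation diagnostics."""

    feature_loadings: pd.DataFrame  # 16 x n_components
    policy_loadings: pd.DataFrame  # 3 x n_components
    rho: np.ndarray  # training canonical correlations
    heldout_rho: np.ndarray  # mean held-out rho per component
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_selected: int
    labels: list = field(default_factory=list)
    feature_scaler: Scaler | None = None
    policy_scaler: Scaler | None = None

    @property
    def U(self) -> np.ndarray:
        """Feature-loading matrix (16 x n_components), unit-norm columns."""
        return self.feature_loadings.to_numpy()


def build_features(
    activity: pd.DataFrame, alignment: pd.Series | str = "channel1"
) -> pd.DataFrame:
    """Assemble the 16-column feature matrix from per-network mean rates.

    ``activity`` must carry columns ``{region}_ch1``/``{region}_ch2`` for
    the seven channel-specific regions plus ``CxI`` and ``FSI``; one row per
    network.  ``alignment`` controls the sign of the Δ features: either the
    fixed convention ``"channel1"`` (ch1 − ch2, used at baseline) or a
    per-network Series of rewarded channels (1 or 2), in which case Δ is
    rewarded-minus-unrewarded.
    """
    rows = {}
    for r in CHANNEL_REGIONS:
        c1 = activity[f"{r}_ch1"].to_numpy(float)
        c2 = activity[f"{r}_ch2"].to_numpy(float)
        rows[f"{r}_sum"] = c1 + c2
        if isinstance(alignment, str):
            if alignment != "channel1":
                raise ValueError(f"unknown alignment {alignment!r}")
            sign = np.ones(len(activity))
        else:
            ch = np.asarray(alignment)
            sign = np.where(ch == 1, 1.0, -1.0)
        rows[f"{r}_diff"] = sign * (c1 - c2)
    for r in SHARED_REGIONS:
        rows[r] = activity[r].to_numpy(float)
    return pd.DataFrame(rows, index=activity.index)[list(FEATURE_COLUMNS)]


def _cca_fit_corr(
    Ftr: np.ndarray, Dtr: np.ndarray, Fte: np.ndarray, Dte: np.ndarray, k: int
) -> np.ndarray:
    """Held-out per-component correlations of a CCA fitted on the train split."""
    cca = CCA(n_components=k, scale=False, max_iter=1000)
    cca.fit(Ftr, Dtr)
    Xt, Yt = cca.transform(Fte, Dte)
    out = np.empty(k)
    for i in range(k):
        if np.std(Xt[:, i]) == 0 or np.std(Yt[:, i]) == 0:
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(Xt[:, i], Yt[:, i])[0, 1]
    return out


def fit_cca(
    F: pd.DataFrame,
    D: pd.DataFrame,
    k_folds: int = 4,
    n_shuffles: int = 100,
    n_components: int = 3,
    seed: int | None = 0,
    null_sd_factor: float = 2.0,
) -> EnsembleSet:
    """Fit CCA between features and DDM parameters with k-fold validation
    and a row-shuffle null for component selection.

    Columns of both matrices are standardized internally; the scalers are
    kept on the result for projecting learning-induced ΔF later.  Loadings
    are sign-fixed so each component's largest-magnitude feature loading is
    positive.
    """
    if len(F) != len(D):
        raise ValueError("feature and policy matrices must be row-aligned")
    Fv = F.to_numpy(float)
    Dv = D.to_numpy(float)
    bad = [c for c, s in zip(F.columns, Fv.std(axis=0)) if s == 0]
    if bad:
        raise ValueError(f"rank-deficient feature columns (zero variance): {bad}")

    fsc = Scaler.fit(Fv)
    dsc = Scaler.fit(Dv)
    Fs = fsc.transform(Fv)
    Ds = dsc.transform(Dv)
    k = min(n_components, Ds.shape[1])

    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=rng.integers(2**31 - 1))
    folds = list(kf.split(Fs))

    held = np.array([
        _cca_fit_corr(Fs[tr], Ds[tr], Fs[te], Ds[te], k) for tr, te in folds
    ])
    null = np.empty((n_shuffles, k))
    for s in range(n_shuffles):
        perm = rng.permutation(len(Ds))
        Dp = Ds[perm]
        null[s] = np.mean(
            [_cca_fit_corr(Fs[tr], Dp[tr], Fs[te], Dp[te], k) for tr, te in folds],
            axis=0,
        )
    held_mean = held.mean(axis=0)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    n_selected = int(np.sum(held_mean > null_mean + null_sd_factor * null_sd))

    cca = CCA(n_components=k, scale=False, max_iter=1000)
    cca.fit(Fs, Ds)
    Xs, Ys = cca.transform(Fs, Ds)
    rho = np.array([np.corrcoef(Xs[:, i], Ys[:, i])[0, 1] for i in range(k)])
    # structure loadings: correlation of each (standardized) variable with
    # its side's canonical scores — the per-region pattern a component
    # represents, and a far less noisy estimate of planted factor loadings
    # than the raw weight vectors
    n = len(Fs)
    U = Fs.T @ Xs / n
    V = Ds.T @ Ys / n
    # unit-norm, sign-fixed loadings
    for i in range(k):
        U[:, i] /= np.linalg.norm(U[:, i])
        V[:, i] /= np.linalg.norm(V[:, i])
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1.0
            V[:, i] *= -1.0

    comp_names = [f"CC{i + 1}" for i in range(k)]
    ens = EnsembleSet(
        feature_loadings=pd.DataFrame(U, index=list(F.columns), columns=comp_names),
        policy_loadings=pd.DataFrame(V, index=list(D.columns), columns=comp_names),
        rho=rho,
        heldout_rho=held_mean,
        null_mean=null_mean,
        null_sd=null_sd,
        n_selected=n_selected,
        feature_scaler=fsc,
        policy_scaler=dsc,
    )
    return label_ensembles(ens)


def label_ensembles(ens: EnsembleSet, rel_tol: float = 0.25) -> EnsembleSet:
    """Attach responsiveness / pliancy / choice labels from policy loadings.

    A component dominated by the drift-rate loading is *choice*; otherwise
    same-signed a and t loadings mean *responsiveness* and opposite-signed
    ones *pliancy*.  Patterns matching none of these are flagged
    ``unresolved`` rather than forced.
    """
    labels = []
    P = ens.policy_loadings
    for c in P.columns:
        la, lt, lv = (float(P.loc[k, c]) for k in ("a", "t", "v"))
        mx = max(abs(la), abs(lt), abs(lv))
        if mx == 0:
            labels.append("unresolved")
            continue
        if abs(lv) >= max(abs(la), abs(lt)):
            labels.append("choice")
        elif abs(la) > rel_tol * mx and abs(lt) > rel_tol * mx:
            labels.append("responsiveness" if la * lt > 0 else "pliancy")
        else:
            labels.append("unresolved")
    ens.labels = labels
    return ens
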