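"""End-to-end study orchestration: sample networks, run learning sessions,
fit the DDM per stage, build policy manifolds, extract control ensembles,
and decompose the learning-induced rate changes into ensemble drivers.

Each stage writes plain CSV/JSON artifacts into its own subdirectory and
is skipped on re-run if its outputs already exist, so a study is resumable
from any completed stage.  All randomness derives from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddm import BehaviorSample, fit_mle, qq_check, regenerate
from .drivers import ENSEMBLE_NAMES, decompose, sequence_drivers
from .ensembles import FEATURE_COLUMNS, build_features, fit_cca
from .ga import default_free_grid, evolve, make_network_evaluator
from .manifold import build_manifold, compare_objectives
from .network import NetworkParams
from .plasticity import PlasticityParams
from .task import SessionConfig, classify_speed, outcome_sequence, run_session

log = logging.getLogger("cbgtlearn")


@dataclass
class StudyConfig:
    cohort_size: int = 10
    outdir: str = "study_out"
    master_seed: int = 0
    # GA settings
    ga_eval_trials: int = 40
    ga_max_iter: int = 200
    grid_points: int = 30
    grid_frac: float = 0.3
    # session settings
    n_learning_trials: int = 15
    freeze_stages: tuple[int, ...] = (2, 4, 6, 15)
    probe_trials_per_stage: int = 100
    reward_prob_optimal: float = 1.0
    reward_prob_suboptimal: float = 0.0
    # DDM / manifold settings
    fit_min_trials: int = 50
    manifold_points: int = 9
    manifold_seeds: int = 5
    manifold_trials: int = 200
    # CCA / drivers settings
    cca_folds: int = 4
    cca_shuffles: int = 50
    n_pcs: int = 5

    def session_config(self, seed: int) -> SessionConfig:
        return SessionConfig(
            n_learning_trials=self.n_learning_trials,
            freeze_stages=tuple(self.freeze_stages),
            probe_trials_per_stage=self.probe_trials_per_stage,
            reward_prob_optimal=self.reward_prob_optimal,
            reward_prob_suboptimal=self.reward_prob_suboptimal,
            seed=seed,
        )


def _seed_for(master: int, stage: str, k: int = 0) -> int:
    import zlib

    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode()), k])
    return int(ss.generate_state(1)[0] % (2**31))


def _done(path: Path) -> bool:
    return path.exists()


def _write_json(path: Path, obj) -> None:
    def convert(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserializable {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=convert))


def sample_networks(config: StudyConfig, base: NetworkParams | None = None) -> pd.DataFrame:
    """GA stage: archive ``cohort_size`` acceptable configurations."""
    out = Path(config.outdir) / "networks"
    index = out / "index.csv"
    if _done(index):
        log.info("networks stage already complete; skipping")
        return pd.read_csv(index)
    out.mkdir(parents=True, exist_ok=True)
    base = base or NetworkParams()
    grid = default_free_grid(base, frac=config.grid_frac, n_points=config.grid_points)
    ev = make_network_evaluator(
        base, n_trials=config.ga_eval_trials, seed=_seed_for(config.master_seed, "ga")
    )
    res = evolve(
        grid, ev, target_solutions=config.cohort_size,
        max_iter=config.ga_max_iter, seed=_seed_for(config.master_seed, "ga-evolve"),
    )
    if res.n_accepted == 0:
        log.warning("GA found no acceptable configurations within the budget")
    rows = []
    for i, a in enumerate(res.accepted[: config.cohort_size]):
        nid = f"net{i:03d}"
        params = base.with_efficacies(a["values"])
        params.save(out / f"{nid}.yaml")
        rows.append({
            "network_id": nid,
            "timeout_fraction": a["fitness"].timeout_fraction,
            "cx_striatum_correlation": a["fitness"].cx_striatum_correlation,
            **{f"eff:{k}": v for k, v in a["values"].items()},
        })
    df = pd.DataFrame(rows)
    df.to_csv(index, index=False)
    return df


def run_sessions(
    config: StudyConfig, plasticity: PlasticityParams | None = None
) -> dict[str, "SessionLogHandle"]:
    """Learning-session stage: one session per archived network."""
    netdir = Path(config.outdir) / "networks"
    outdir = Path(config.outdir) / "sessions"
    index = pd.read_csv(netdir / "index.csv")
    handles = {}
    for _, row in index.iterrows():
        nid = row.network_id
        sdir = outdir / nid
        if _done(sdir / "trials.csv"):
            handles[nid] = SessionLogHandle(sdir, nid)
            continue
        params = NetworkParams.load(netdir / f"{nid}.yaml")
        cfg = config.session_config(
            seed=_seed_for(config.master_seed, "session", int(nid[3:]))
        )
        log.info("running session for %s", nid)
        slog = run_session(params, plasticity, cfg, network_id=nid)
        slog.save(sdir)
        handles[nid] = SessionLogHandle(sdir, nid, slog)
    return handles


@dataclass
class SessionLogHandle:
    """Lazy access to a saved session's tables."""

    path: Path
    network_id: str
    _log: object | None = None

    @property
    def trials(self) -> pd.DataFrame:
        return pd.read_csv(self.path / "trials.csv")

    @property
    def activity(self) -> pd.DataFrame:
        return pd.read_csv(self.path / "rates.csv", index_col="stage")

    def probe_sample(self, stage: int, rewarded_channel: int = 1) -> BehaviorSample:
        t = self.trials
        sel = t[(t.phase == "probe") & (t.stage == stage) & (t.choice > 0)]
        return BehaviorSample(
            rt=sel.decision_time_ms.to_numpy() / 1000.0,
            upper=(sel.choice == rewarded_channel).to_numpy(),
            network_id=self.network_id, stage=str(stage),
        )

    def learning_rewards(self) -> np.ndarray:
        t = self.trials
        lr = t[t.phase == "learning"].sort_values("trial")
        return lr.reward.to_numpy(float)


def fit_stage_ddms(config: StudyConfig) -> pd.DataFrame:
    """DDM stage: per-(network, stage) MLE fits with QQ diagnostics."""
    out = Path(config.outdir) / "ddm_fits.csv"
    if _done(out):
        log.info("ddm stage already complete; skipping")
        return pd.read_csv(out)
    handles = _session_handles(config)
    rows = []
    rng_seed = _seed_for(config.master_seed, "ddm-qq")
    for nid, h in handles.items():
        stages = sorted(h.trials[h.trials.phase == "probe"].stage.unique())
        for stage in stages:
            sample = h.probe_sample(int(stage))
            if sample.n < 10:
                log.warning("%s stage %s: too few decided trials, skipped", nid, stage)
                continue
            fit = fit_mle(sample, min_trials=config.fit_min_trials)
            gen = regenerate(fit, n=max(sample.n, 500), seed=rng_seed)
            qq_r, qq_p = qq_check(sample, gen)
            rows.append({
                "network_id": nid, "stage": int(stage),
                "v": fit.params.v, "a": fit.params.a, "t": fit.params.t,
                "z": fit.params.z, "loglik": fit.loglik,
                "n_trials": fit.n_trials, "qq_r": qq_r,
                "weak_identification": fit.weak_identification,
            })
    df = pd.DataFrame(rows)
    df.to_csv(out, index=False)
    return df


def _session_handles(config: StudyConfig) -> dict[str, SessionLogHandle]:
    outdir = Path(config.outdir) / "sessions"
    return {
        p.name: SessionLogHandle(p, p.name)
        for p in sorted(outdir.iterdir())
        if (p / "trials.csv").exists()
    }


def manifold_stage(config: StudyConfig) -> dict:
    """Manifold stage: surfaces over the fitted (v, a) range, per-step
    cosine distances, and the objective comparison."""
    outdir = Path(config.outdir) / "manifold"
    summary_file = outdir / "summary.json"
    if _done(summary_file):
        log.info("manifold stage already complete; skipping")
        return json.loads(summary_file.read_text())
    outdir.mkdir(parents=True, exist_ok=True)
    fits = pd.read_csv(Path(config.outdir) / "ddm_fits.csv")
    baseline = fits[fits.stage == 0]
    t_fixed = float(baseline.t.mean()) if len(baseline) else float(fits.t.mean())
    pad_v = 0.25 * max(fits.v.max() - fits.v.min(), 0.5)
    pad_a = 0.25 * max(fits.a.max() - fits.a.min(), 0.5)
    v_grid = np.linspace(fits.v.min() - pad_v, fits.v.max() + pad_v, config.manifold_points)
    a_grid = np.linspace(
        max(fits.a.min() - pad_a, 0.05), fits.a.max() + pad_a, config.manifold_points
    )
    grid = build_manifold(
        v_grid, a_grid, t_fixed=t_fixed, seeds=config.manifold_seeds,
        trials=config.manifold_trials,
        base_seed=_seed_for(config.master_seed, "manifold"),
    )
    grid.to_frame().to_csv(outdir / "grid.csv", index=False)
    traj = {
        nid: g.sort_values("stage")[["v", "a"]].to_numpy()
        for nid, g in fits.groupby("network_id")
        if len(g) >= 2
    }
    dist, summary = compare_objectives(traj, grid)
    dist.to_csv(outdir / "distances.csv", index=False)
    _write_json(summary_file, summary)
    return summary


def cca_stage(config: StudyConfig) -> dict:
    """Control-ensemble stage: baseline features vs baseline DDM fits."""
    outdir = Path(config.outdir) / "cca"
    diag_file = outdir / "diagnostics.json"
    if _done(diag_file):
        log.info("cca stage already complete; skipping")
        return json.loads(diag_file.read_text())
    outdir.mkdir(parents=True, exist_ok=True)
    handles = _session_handles(config)
    fits = pd.read_csv(Path(config.outdir) / "ddm_fits.csv")
    act = _activity_table(handles, stage=0)
    F = build_features(act)
    D = (
        fits[fits.stage == 0].set_index("network_id")[["a", "t", "v"]]
        .loc[F.index]
    )
    ens = fit_cca(
        F, D, k_folds=min(config.cca_folds, len(F)), n_shuffles=config.cca_shuffles,
        seed=_seed_for(config.master_seed, "cca"),
    )
    ens.feature_loadings.rename_axis("feature").to_csv(outdir / "feature_loadings.csv")
    ens.policy_loadings.rename_axis("parameter").to_csv(outdir / "policy_loadings.csv")
    pd.DataFrame({
        "mean": ens.feature_scaler.mean, "scale": ens.feature_scaler.scale,
    }, index=list(FEATURE_COLUMNS)).rename_axis("feature").to_csv(outdir / "feature_scaler.csv")
    diag = {
        "rho": ens.rho.tolist(),
        "heldout_rho": ens.heldout_rho.tolist(),
        "null_mean": ens.null_mean.tolist(),
        "null_sd": ens.null_sd.tolist(),
        "n_selected": ens.n_selected,
        "labels": ens.labels,
        "n_networks": int(len(F)),
    }
    _write_json(diag_file, diag)
    return diag


def _activity_table(handles: dict[str, SessionLogHandle], stage: int) -> pd.DataFrame:
    rows = {}
    for nid, h in handles.items():
        a = h.activity
        if stage in a.index:
            r = a.loc[stage]
            rows[nid] = {
                **{f"{reg}_ch{c}": r[f"{reg}_ch{c}"] for reg in
                   ("Cx", "dSPN", "iSPN", "GPe", "STN", "GPi", "Thal") for c in (1, 2)},
                "CxI": r["CxI"], "FSI": r["FSI"],
            }
    return pd.DataFrame(rows).T.sort_index()


def drivers_stage(config: StudyConfig) -> dict:
    """Driver stage: ΔF decomposition per cohort/class plus the 2-trial
    outcome-sequence analysis."""
    outdir = Path(config.outdir) / "drivers"
    stats_file = outdir / "stats.json"
    if _done(stats_file):
        log.info("drivers stage already complete; skipping")
        return json.loads(stats_file.read_text())
    outdir.mkdir(parents=True, exist_ok=True)
    handles = _session_handles(config)
    fits = pd.read_csv(Path(config.outdir) / "ddm_fits.csv")
    cca_dir = Path(config.outdir) / "cca"
    U = pd.read_csv(cca_dir / "feature_loadings.csv", index_col="feature").to_numpy()
    scaler = pd.read_csv(cca_dir / "feature_scaler.csv", index_col="feature")

    final_stage = max(config.freeze_stages)
    act0 = _activity_table(handles, 0)
    act1 = _activity_table(handles, final_stage)
    common = act0.index.intersection(act1.index)
    F0 = build_features(act0.loc[common])
    F1 = build_features(act1.loc[common])
    delta = (F1.to_numpy() - F0.to_numpy()) / scaler["scale"].to_numpy()

    speed = classify_speed(_mean_probe_rt(handles, common, stage=0))

    k = min(config.n_pcs, len(common) - 1)
    results = {}
    res_all = decompose(delta, U, k=k)
    results["all"] = res_all
    for cls in ("fast", "intermediate", "slow"):
        idx = np.nonzero((speed == cls).to_numpy())[0]
        if idx.size > k:
            results[cls] = decompose(delta[idx], U, k=k)

    rows = []
    for cls, r in results.items():
        for e, name in enumerate(ENSEMBLE_NAMES):
            for pc in range(r.S.shape[1]):
                rows.append({"cohort": cls, "ensemble": name, "pc": pc + 1,
                             "S": r.S[e, pc]})
    pd.DataFrame(rows).to_csv(outdir / "S.csv", index=False)
    pd.DataFrame(
        {cls: r.weighted() for cls, r in results.items()}, index=list(ENSEMBLE_NAMES)
    ).rename_axis("ensemble").to_csv(outdir / "weighted_drivers.csv")

    # outcome-sequence analysis at the 2-trial freeze
    seq_stats = {}
    if 2 in config.freeze_stages:
        act2 = _activity_table(handles, 2)
        common2 = act0.index.intersection(act2.index)
        F2 = build_features(act2.loc[common2])
        delta2 = (F2.to_numpy() - build_features(act0.loc[common2]).to_numpy()) \
            / scaler["scale"].to_numpy()
        seqs = np.array([
            "-".join("R" if r == 1 else "U" for r in handles[nid].learning_rewards()[:2])
            for nid in common2
        ])
        drr = np.array([
            _probe_reward_rate(handles[nid], 2) - _probe_reward_rate(handles[nid], 0)
            for nid in common2
        ])
        seq_out = sequence_drivers(
            delta2, seqs, U, delta_rr=drr,
            speed_class=speed.loc[common2].to_numpy(), k=k, min_group=3,
        )
        pd.DataFrame({
            "network_id": common2, "sequence": seqs, "delta_rr": drr,
            "speed_class": speed.loc[common2].to_numpy(),
        }).to_csv(outdir / "sequences.csv", index=False)
        seq_stats = {
            "groups": {
                lab: {"n": g["n"], "weighted_driver": g["weighted_driver"].tolist()}
                for lab, g in seq_out["groups"].items()
            },
            "flagged": seq_out["flagged"],
            "delta_rr_by_sequence": seq_out.get("delta_rr_by_sequence", {}),
            "pairwise_t": seq_out.get("pairwise_t", {}),
        }

    stats = {
        "variance_fractions": {
            cls: r.variance_fractions.tolist() for cls, r in results.items()
        },
        "weighted_drivers": {cls: r.weighted().tolist() for cls, r in results.items()},
        "speed_classes": speed.to_dict(),
        "sequences": seq_stats,
    }
    _write_json(stats_file, stats)
    return stats


def _mean_probe_rt(handles, ids, stage: int) -> pd.Series:
    return pd.Series(
        {nid: float(np.mean(handles[nid].probe_sample(stage).rt)) for nid in ids}
    )


def _probe_reward_rate(h: SessionLogHandle, stage: int) -> float:
    s = h.probe_sample(stage)
    return s.accuracy / float(np.mean(s.rt)) if s.n else float("nan")


def run_study(config: StudyConfig, base: NetworkParams | None = None,
              plasticity: PlasticityParams | None = None) -> dict:
    """Execute all stages in order and assemble the study report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dump = asdict(config)
    _write_json(outdir / "study_config.json", cfg_dump)

    report: dict = {"config": cfg_dump, "version": __version__}
    index = sample_networks(config, base)
    report["cohort"] = {
        "n_networks": int(len(index)),
        "mean_timeout_fraction": float(index.timeout_fraction.mean()) if len(index) else None,
    }
    run_sessions(config, plasticity)
    fits = fit_stage_ddms(config)
    report["ddm"] = {
        "n_fits": int(len(fits)),
        "mean_qq_r": float(fits.qq_r.mean()) if len(fits) else None,
    }
    report["manifold"] = manifold_stage(config)
    report["cca"] = cca_stage(config)
    report["drivers"] = drivers_stage(config)

    probes = _probe_summary(config)
    probes.to_csv(outdir / "probe_summary.csv", index=False)
    report["behavior"] = {
        str(stage): {
            "accuracy": float(g.accuracy.mean()),
            "mean_rt_ms": float(g.mean_rt_ms.mean()),
            "reward_rate": float(g.reward_rate.mean()),
        }
        for stage, g in probes.groupby("stage")
    }
    _write_json(outdir / "report.json", report)
    return report


def _probe_summary(config: StudyConfig) -> pd.DataFrame:
    handles = _session_handles(config)
    rows = []
    for nid, h in handles.items():
        stages = sorted(h.trials[h.trials.phase == "probe"].stage.unique())
        for stage in stages:
            s = h.probe_sample(int(stage))
            if s.n == 0:
                continue
            rows.append({
                "network_id": nid, "stage": int(stage), "n": s.n,
                "accuracy": s.accuracy,
                "mean_rt_ms": float(np.mean(s.rt) * 1000.0),
                "reward_rate": s.accuracy / float(np.mean(s.rt)),
            })
    return pd.DataFrame(rows)
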