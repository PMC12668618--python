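"""Dopamine-dependent eligibility-trace plasticity at corticostriatal
synapses.

Each plastic synapse tracks pre/post spike traces A_PRE and A_POST (jump
by Delta/tau on a spike, exponential decay between spikes), an eligibility
E driven by their pairings::

    dE/dt = (X_POST * A_PRE - X_PRE * A_POST - E) / tau_E

and a bounded weight updated multiplicatively by eligibility times the
dopamine modulation f(K_DA)::

    dw/dt = [alpha_w E f(K_DA) (w_max - w)]_+ + [alpha_w E f(K_DA) (w - w_min)]_-

The phasic dopamine level K_DA jumps toward the reward-prediction error
DA_inc = r - Q at each outcome and decays with tau_DA; action values Q
follow a delta rule with rate alpha_Q.  f(K_DA) is piecewise linear with
opposite conventions for dSPN (learning rate positive) and iSPN
(negative), so positive feedback strengthens eligible direct-pathway
synapses and weakens eligible indirect-pathway ones.

Per-step operator ordering is fixed: spike traces, then eligibility, then
(in the network integrator) conductance, then weight.  Delta-function
terms are discrete jumps at spike times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityParams",
    "SynapseState",
    "DopamineSystem",
    "PlasticityEngine",
    "update_traces",
    "update_eligibility",
    "f_kda",
    "reward_event",
    "update_weight",
    "conductance_step",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Trace, eligibility, dopamine and weight-update constants.

    These defaults are calibrated reconstructions, chosen so that
    action-value learning and the corticostriatal weights saturate within
    roughly 15 trials of deterministic feedback (see the methods note).
    """

    delta_pre: float = 1.0
    delta_post: float = 0.5
    tau_pre_ms: float = 15.0
    tau_post_ms: float = 15.0
    tau_e_ms: float = 80.0
    alpha_w_dspn: float = 450.0
    alpha_w_ispn: float = -450.0
    gamma: float = 1.0
    mu: float = 0.5
    eps: float = 0.8
    c_scale: float = 1.0
    tau_da_ms: float = 150.0
    alpha_q: float = 0.2
    q_init: float = 0.5
    w_min_factor: float = 0.0  # bounds relative to the initial weight
    w_max_factor: float = 2.5
    reward_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_q <= 1.0:
            raise ValueError("alpha_q must lie in [0, 1]")
        for name in ("gamma", "mu", "tau_da_ms", "tau_e_ms", "tau_pre_ms", "tau_post_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.alpha_w_dspn <= 0 or self.alpha_w_ispn >= 0:
            raise ValueError("alpha_w must be positive for dSPN and negative for iSPN")


@dataclass
class SynapseState:
    """Scalar synapse state, mainly for direct testing of the update rules."""

    a_pre: float = 0.0
    a_post: float = 0.0
    e: float = 0.0
    w: float = 0.0
    g: float = 0.0


@dataclass
class DopamineSystem:
    """Global dopamine level and per-action expected rewards."""

    params: PlasticityParams
    k_da: float = 0.0
    q: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.q:
            self.q = {1: self.params.q_init, 2: self.params.q_init}

    def decay(self, dt_ms: float) -> None:
        self.k_da *= np.exp(-dt_ms / self.params.tau_da_ms)


# ---------------------------------------------------------------------------
# elementary update rules (scalar or array-valued)


def update_traces(
    state: SynapseState, pre_spike: bool, post_spike: bool, dt_ms: float,
    params: PlasticityParams,
) -> SynapseState:
    """Advance A_PRE/A_POST one step: exponential decay plus spike jumps."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    state.a_pre *= np.exp(-dt_ms / params.tau_pre_ms)
    state.a_post *= np.exp(-dt_ms / params.tau_post_ms)
    if pre_spike:
        state.a_pre += params.delta_pre / params.tau_pre_ms
    if post_spike:
        state.a_post += params.delta_post / params.tau_post_ms
    return state


def update_eligibility(
    state: SynapseState, pre_spike: bool, post_spike: bool, dt_ms: float,
    params: PlasticityParams,
) -> SynapseState:
    """Advance E one step; post-on-eligible-pre pairings push E up,
    pre-on-eligible-post pairings push it down."""
    state.e *= np.exp(-dt_ms / params.tau_e_ms)
    if post_spike:
        state.e += state.a_pre / params.tau_e_ms
    if pre_spike:
        state.e -= state.a_post / params.tau_e_ms
    return state


def f_kda(k_da, target: str, gamma: float, mu: float, eps: float):
    """Dopamine modulation factor, piecewise linear per target population.

    dSPN: floor at -gamma below -mu, slope gamma/mu above; iSPN: slope
    eps*gamma/mu below mu, ceiling at eps*gamma above.  Continuous at the
    break points.
    """
    if gamma <= 0 or mu <= 0 or eps <= 0:
        raise ValueError("gamma, mu, eps must be positive")
    k = np.asarray(k_da, dtype=float)
    if target == "dSPN":
        out = np.where(k < -mu, -gamma, (gamma / mu) * k)
    elif target == "iSPN":
        out = np.where(k < mu, eps * (gamma / mu) * k, eps * gamma)
    else:
        raise ValueError(f"unknown plasticity target {target!r}")
    return float(out) if out.ndim == 0 else out


def reward_event(
    dopamine: DopamineSystem, action: int, reward: float
) -> tuple[DopamineSystem, float]:
    """Deliver an outcome: compute the RPE, update Q, jump K_DA.

    Returns the system and the dopamine increment DA_inc = r - Q_action.
    """
    lo, hi = dopamine.params.reward_range
    if not lo <= reward <= hi:
        raise ValueError(f"reward {reward} outside configured range [{lo}, {hi}]")
    da_inc = reward - dopamine.q[action]
    dopamine.q[action] += dopamine.params.alpha_q * da_inc
    dopamine.k_da += dopamine.params.c_scale * (da_inc - dopamine.k_da)
    return dopamine, da_inc


def update_weight(
    state: SynapseState, dopamine: DopamineSystem, target: str, dt_ms: float,
    params: PlasticityParams, w_min: float, w_max: float,
) -> SynapseState:
    """One Euler step of the bounded multiplicative weight update."""
    alpha = params.alpha_w_dspn if target == "dSPN" else params.alpha_w_ispn
    drive = alpha * state.e * f_kda(dopamine.k_da, target, params.gamma, params.mu, params.eps)
    dw = np.where(drive > 0, drive * (w_max - state.w), drive * (state.w - w_min)) * dt_ms / 1000.0
    state.w = float(np.clip(state.w + dw, w_min, w_max))
    return state


def conductance_step(
    state: SynapseState, pre_spike: bool, dt_ms: float, tau_ampa_ms: float = 2.0
) -> SynapseState:
    """Conductance: jumps by the current weight on a presynaptic spike and
    decays with the AMPA constant between spikes."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    state.g *= np.exp(-dt_ms / tau_ampa_ms)
    if pre_spike:
        state.g += state.w
    return state


# ---------------------------------------------------------------------------
# vectorized engine for the network integrator


class PlasticityEngine:
    """Vectorized plasticity state across the four corticostriatal blocks
    (Cx->dSPN and Cx->iSPN per channel).

    The engine owns the plastic weight matrices; the network integrator
    reads ``engine.weights`` into its conductance matrix whenever a step
    reports weight changes.  Traces and eligibility are reset at trial
    start (inter-trial intervals are long relative to their decay times);
    action values Q persist across trials.
    """

    def __init__(
        self,
        initial_weights: dict[str, np.ndarray],
        blocks: list[dict],
        params: PlasticityParams | None = None,
    ):
        self.params = params or PlasticityParams()
        self.weights = {k: np.array(v, dtype=np.float64) for k, v in initial_weights.items()}
        self.dopamine = DopamineSystem(params=self.params)
        self._state: dict[str, dict] = {}
        self.enabled = True
        self.last_reward: float | None = None
        for b in blocks:
            key = b["key"]
            w0 = float(np.mean(self.weights[key]))
            self._state[key] = {
                "a_pre": np.zeros(b["pre"].stop - b["pre"].start),
                "a_post": np.zeros(b["post"].stop - b["post"].start),
                "e": np.zeros_like(self.weights[key]),
                "w_min": self.params.w_min_factor * w0,
                "w_max": self.params.w_max_factor * w0,
                "target": b["target"],
            }

    # -- lifecycle -----------------------------------------------------------

    def start_trial(self) -> None:
        for st in self._state.values():
            st["a_pre"][:] = 0.0
            st["a_post"][:] = 0.0
            st["e"][:] = 0.0
        self.dopamine.k_da = 0.0
        self.last_reward = None

    def reward_event(self, action: int, reward: float) -> float:
        self.last_reward = reward
        _, da_inc = reward_event(self.dopamine, action, reward)
        return da_inc

    # -- per-step update -----------------------------------------------------

    def on_step(self, spikes: np.ndarray, blocks: list[dict], dt_ms: float) -> bool:
        """Advance all blocks one step given the network spike vector.

        Returns True when weights changed (so the caller refreshes its
        conductance matrix).
        """
        if not self.enabled:
            return False
        p = self.params
        dec_pre = np.exp(-dt_ms / p.tau_pre_ms)
        dec_post = np.exp(-dt_ms / p.tau_post_ms)
        dec_e = np.exp(-dt_ms / p.tau_e_ms)
        self.dopamine.decay(dt_ms)
        k = self.dopamine.k_da
        active_da = abs(k) > 1e-9
        dirty = False
        for b in blocks:
            st = self._state[b["key"]]
            pre = spikes[b["pre"]]
            post = spikes[b["post"]]
            # traces
            st["a_pre"] *= dec_pre
            st["a_post"] *= dec_post
            if pre.any():
                st["a_pre"][pre] += p.delta_pre / p.tau_pre_ms
            if post.any():
                st["a_post"][post] += p.delta_post / p.tau_post_ms
            # eligibility
            E = st["e"]
            E *= dec_e
            if post.any():
                E[:, post] += st["a_pre"][:, None] / p.tau_e_ms
            if pre.any():
                E[pre, :] -= st["a_post"][None, :] / p.tau_e_ms
            # weight
            if active_da:
                alpha = p.alpha_w_dspn if st["target"] == "dSPN" else p.alpha_w_ispn
                f = f_kda(k, st["target"], p.gamma, p.mu, p.eps)
                drive = alpha * f * E
                w = self.weights[b["key"]]
                dw = np.where(
                    drive > 0,
                    drive * (st["w_max"] - w),
                    drive * (w - st["w_min"]),
                ) * (dt_ms / 1000.0)
                if np.any(dw):
                    np.clip(w + dw, st["w_min"], st["w_max"], out=w)
                    dirty = True
        return dirty

    # -- summaries -----------------------------------------------------------

    def mean_weights(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.weights.items()}

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}
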