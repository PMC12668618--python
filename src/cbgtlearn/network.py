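"""Two-channel spiking cortico-basal-ganglia-thalamic (CBGT) network.

Nine regions are modelled as populations of conductance-based leaky
integrate-and-fire neurons with exponential AMPA/GABA synapses: cortex
(Cx), inhibitory cortical interneurons (CxI), striatal fast-spiking
interneurons (FSI), direct- and indirect-pathway spiny projection neurons
(dSPN, iSPN), external and internal globus pallidus (GPe, GPi),
subthalamic nucleus (STN) and thalamus (Thal).  Each choice option has its
own copy ("action channel") of every region except CxI and FSI, which are
shared.

Every population receives a noisy background conductance implemented as a
mean-reverting random walk (Ornstein-Uhlenbeck diffusion approximation of
filtered Poisson input), with mean ``mu = 0.001 * E * f * N * tau`` and
stationary standard deviation ``sigma = E * sqrt(0.0005 * f * N * tau)``.
Cortical populations additionally receive a ramping evidence signal whose
rate approaches ``f_target`` by the recurrence
``f(t) = f(t-dt) + 0.1 * (f_target - f(t-dt))`` applied per integrator
step.  A choice is registered when the smoothed firing-rate estimate of
either thalamic population first reaches 30 Hz; trials with no crossing
within the window are timeouts.

The integrator is fixed-step Euler for the membrane equation with exact
exponential decay of all conductances, vectorized across simultaneous
trials so that a probe block runs as one batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

CHANNEL_REGIONS = ("Cx", "dSPN", "iSPN", "GPe", "STN", "GPi", "Thal")
SHARED_REGIONS = ("CxI", "FSI")
REGIONS = ("Cx", "CxI", "FSI", "dSPN", "iSPN", "GPe", "STN", "GPi", "Thal")

TAU_AMPA_MS = 2.0
TAU_GABA_MS = 5.0
TIMEOUT = -1


class SimulationDivergence(RuntimeError):
    """Raised when membrane potentials become non-finite."""

    def __init__(self, population: str):
        self.population = population
        super().__init__(f"numerical divergence detected in population {population!r}")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class NeuronConstants:
    tau_m_ms: float = 10.0
    v_leak: float = -70.0
    v_thresh: float = -50.0
    v_reset: float = -56.0
    t_ref_ms: float = 2.0
    v_exc: float = 0.0
    v_inh: float = -80.0


@dataclass(frozen=True)
class ExternalDrive:
    """Background drive to one population through one receptor type."""

    f_ext_hz: float
    efficacy: float
    n_connections: int
    receptor: str = "ampa"  # 'ampa' or 'gaba'

    @property
    def tau_ms(self) -> float:
        return TAU_AMPA_MS if self.receptor == "ampa" else TAU_GABA_MS

    def mu(self, f_hz: float | None = None) -> float:
        f = self.f_ext_hz if f_hz is None else f_hz
        return 0.001 * self.efficacy * f * self.n_connections * self.tau_ms

    def sigma(self, f_hz: float | None = None) -> float:
        f = self.f_ext_hz if f_hz is None else f_hz
        return self.efficacy * math.sqrt(0.0005 * f * self.n_connections * self.tau_ms)


@dataclass(frozen=True)
class Projection:
    """One anatomical projection, expanded per channel at build time.

    ``pattern`` applies when both ends are channel-specific: 'within'
    connects matching channels, 'cross' the opposite ones, and 'diffuse'
    both.  Projections to or from shared populations ignore it.  The
    efficacy is the total conductance jump a postsynaptic neuron receives
    if every presynaptic neuron of one source population fires once.
    """

    src: str
    dst: str
    efficacy: float
    receptor: str
    pattern: str = "within"
    plastic: bool = False


@dataclass(frozen=True)
class RampParams:
    """Evidence ramp: ``f <- f + gain * (f_target - f)`` applied once per
    ``step_ms`` of simulated time.

    The recurrence itself is step-size dependent; updating on a fixed 20 ms
    clock (time constant ~200 ms) keeps the described gradual rise
    independent of the integrator resolution.  Setting ``step_ms`` to the
    integrator dt recovers the literal per-step form.
    """

    f_target: float = 1.0
    gain: float = 0.1
    step_ms: float = 20.0


@dataclass(frozen=True)
class DecisionParams:
    threshold_hz: float = 30.0
    max_duration_ms: float = 1000.0
    rate_tau_ms: float = 20.0


def default_population_sizes() -> dict[str, int]:
    # per channel for channel-specific regions, total for shared ones
    return {
        "Cx": 20, "dSPN": 15, "iSPN": 15, "GPe": 15, "STN": 15,
        "GPi": 15, "Thal": 30, "CxI": 20, "FSI": 15,
    }


def default_neuron_constants() -> dict[str, NeuronConstants]:
    base = NeuronConstants()
    return {r: base for r in REGIONS}


def default_external_drive() -> dict[str, list[ExternalDrive]]:
    """Background drives tuned for a plausible baseline operating point:
    pallidal/nigral/subthalamic populations get strong tonic drive
    (pacemaker-like), striatal populations weak drive, cortex the 2.5 Hz
    baseline that the evidence ramp adds to.  All values are calibrated
    reconstructions; see the methods note.
    """
    return {
        "Cx": [ExternalDrive(2.5, 0.07, 800, "ampa")],
        "CxI": [ExternalDrive(4.0, 0.172, 200, "ampa")],
        "FSI": [ExternalDrive(4.0, 0.179, 200, "ampa")],
        "dSPN": [ExternalDrive(4.0, 0.146, 200, "ampa")],
        "iSPN": [ExternalDrive(4.0, 0.146, 200, "ampa")],
        "GPe": [ExternalDrive(4.0, 0.0613, 800, "ampa")],
        "STN": [ExternalDrive(4.0, 0.0648, 800, "ampa")],
        "GPi": [ExternalDrive(4.0, 0.0746, 800, "ampa")],
        "Thal": [ExternalDrive(4.0, 0.0716, 800, "ampa")],
    }


def default_projections() -> list[Projection]:
    return [
        Projection("Cx", "dSPN", 0.9, "ampa", "within", plastic=True),
        Projection("Cx", "iSPN", 0.9, "ampa", "within", plastic=True),
        Projection("Cx", "FSI", 0.3, "ampa"),
        Projection("Cx", "CxI", 0.3, "ampa"),
        Projection("Cx", "Cx", 0.15, "ampa", "within"),
        Projection("Cx", "STN", 0.15, "ampa", "within"),
        Projection("CxI", "Cx", 0.35, "gaba"),
        Projection("FSI", "dSPN", 0.35, "gaba"),
        Projection("FSI", "iSPN", 0.35, "gaba"),
        Projection("dSPN", "GPi", 2.2, "gaba", "within"),
        Projection("iSPN", "GPe", 1.8, "gaba", "within"),
        Projection("GPe", "STN", 0.5, "gaba", "within"),
        Projection("GPe", "GPi", 0.6, "gaba", "within"),
        Projection("STN", "GPe", 0.35, "ampa", "diffuse"),
        Projection("STN", "GPi", 0.35, "ampa", "diffuse"),
        Projection("GPi", "Thal", 1.6, "gaba", "within"),
        Projection("Thal", "Cx", 0.45, "ampa", "within"),
        Projection("Thal", "dSPN", 0.35, "ampa", "within"),
        Projection("Thal", "iSPN", 0.35, "ampa", "within"),
    ]


#: names of the 14 free (GA-sampled) projection efficacies
FREE_PARAMETERS = (
    "Cx->dSPN", "Cx->iSPN", "Cx->FSI", "FSI->dSPN",
    "dSPN->GPi", "iSPN->GPe", "GPe->STN", "GPe->GPi",
    "STN->GPe", "STN->GPi", "GPi->Thal",
    "Thal->Cx", "Thal->dSPN", "Thal->iSPN",
)


@dataclass
class NetworkParams:
    """Full parameterization of one CBGT network instance."""

    population_sizes: dict[str, int] = field(default_factory=default_population_sizes)
    neuron_constants: dict[str, NeuronConstants] = field(default_factory=default_neuron_constants)
    projections: list[Projection] = field(default_factory=default_projections)
    external_drive: dict[str, list[ExternalDrive]] = field(default_factory=default_external_drive)
    ramp: RampParams = field(default_factory=RampParams)
    decision: DecisionParams = field(default_factory=DecisionParams)
    baseline_mean_hz: float = 2.5
    baseline_sd_hz: float = 0.06
    dt_ms: float = 0.25
    warmup_ms: float = 150.0
    seed: int = 0
    #: multiplier on the channel-1 corticostriatal dSPN efficacy; 1.0 keeps
    #: the network channel-symmetric (hand-biased fixtures use > 1)
    channel1_dspn_bias: float = 1.0

    def validate(self) -> None:
        for r, n in self.population_sizes.items():
            if n < 1:
                raise ValueError(f"population {r} must have at least one neuron")
        for r, drives in self.external_drive.items():
            for d in drives:
                if d.f_ext_hz < 0:
                    raise ValueError(f"negative external frequency for {r}")
        if self.ramp.f_target < 0 or self.baseline_mean_hz < 0:
            raise ValueError("frequencies must be non-negative")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")

    def efficacy(self, name: str) -> float:
        src, dst = name.split("->")
        for p in self.projections:
            if p.src == src and p.dst == dst:
                return p.efficacy
        raise KeyError(name)

    def with_efficacies(self, updates: dict[str, float]) -> "NetworkParams":
        """Return a copy with the named projection efficacies replaced."""
        new_proj = []
        for p in self.projections:
            key = f"{p.src}->{p.dst}"
            new_proj.append(replace(p, efficacy=updates[key]) if key in updates else p)
        return replace(self, projections=new_proj)

    # -- config round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "population_sizes": dict(self.population_sizes),
            "neuron_constants": {
                r: vars(c).copy() for r, c in self.neuron_constants.items()
            },
            "projections": [
                {"src": p.src, "dst": p.dst, "efficacy": p.efficacy,
                 "receptor": p.receptor, "pattern": p.pattern, "plastic": p.plastic}
                for p in self.projections
            ],
            "external_drive": {
                r: [{"f_ext_hz": d.f_ext_hz, "efficacy": d.efficacy,
                     "n_connections": d.n_connections, "receptor": d.receptor}
                    for d in ds]
                for r, ds in self.external_drive.items()
            },
            "ramp": {"f_target": self.ramp.f_target, "gain": self.ramp.gain},
            "decision": {
                "threshold_hz": self.decision.threshold_hz,
                "max_duration_ms": self.decision.max_duration_ms,
                "rate_tau_ms": self.decision.rate_tau_ms,
            },
            "baseline_mean_hz": self.baseline_mean_hz,
            "baseline_sd_hz": self.baseline_sd_hz,
            "dt_ms": self.dt_ms,
            "warmup_ms": self.warmup_ms,
            "seed": self.seed,
            "channel1_dspn_bias": self.channel1_dspn_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            population_sizes=dict(d["population_sizes"]),
            neuron_constants={r: NeuronConstants(**c) for r, c in d["neuron_constants"].items()},
            projections=[Projection(**p) for p in d["projections"]],
            external_drive={
                r: [ExternalDrive(**e) for e in ds] for r, ds in d["external_drive"].items()
            },
            ramp=RampParams(**d["ramp"]),
            decision=DecisionParams(**d["decision"]),
            baseline_mean_hz=d["baseline_mean_hz"],
            baseline_sd_hz=d["baseline_sd_hz"],
            dt_ms=d["dt_ms"],
            warmup_ms=d.get("warmup_ms", 150.0),
            seed=d.get("seed", 0),
            channel1_dspn_bias=d.get("channel1_dspn_bias", 1.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NetworkParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# elementary updates (exposed for direct testing)


def ramp_step(f_ramp_prev: float, f_target: float, gain: float = 0.1) -> float:
    """One step of the linear-rise recurrence toward ``f_target``."""
    if f_ramp_prev < 0 or f_target < 0:
        raise ValueError("ramp frequencies must be non-negative")
    return f_ramp_prev + gain * (f_target - f_ramp_prev)


def external_drive_step(
    S: float | np.ndarray,
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
    tau_ms: float,
    dt_ms: float,
    noise_draw: float | np.ndarray,
) -> float | np.ndarray:
    """One Euler-Maruyama step of the mean-reverting background conductance.

    ``dS = (mu - S)/tau dt + sigma sqrt(2/tau) dW``; the stationary
    distribution has mean ``mu`` and standard deviation ``sigma``.
    """
    if tau_ms <= 0 or dt_ms <= 0:
        raise ValueError("tau and dt must be positive")
    return S + (mu - S) * (dt_ms / tau_ms) + sigma * math.sqrt(2.0 * dt_ms / tau_ms) * noise_draw


# ---------------------------------------------------------------------------
# compiled network


@dataclass
class CompiledNetwork:
    params: NetworkParams
    pop_names: list[str]
    pop_slices: dict[str, slice]
    n_total: int
    tau_m: np.ndarray
    v_leak: np.ndarray
    v_thresh: np.ndarray
    v_reset: np.ndarray
    v_exc: np.ndarray
    v_inh: np.ndarray
    ref_steps: np.ndarray
    W_ampa: np.ndarray  # (N, N) float32, row = presynaptic neuron
    W_gaba: np.ndarray
    mu_a: np.ndarray
    sig_a: np.ndarray
    mu_g: np.ndarray
    sig_g: np.ndarray
    cx_cols: np.ndarray  # neuron indices of both cortical populations
    cx_drive: ExternalDrive
    plastic_blocks: list[dict]  # src/dst slices + metadata per plastic projection

    def initial_weights(self) -> dict[str, np.ndarray]:
        """Per-synapse weight matrices for the plastic corticostriatal blocks,
        keyed ``'{target}_ch{channel}'``; each initialized at efficacy/n_pre."""
        out = {}
        for b in self.plastic_blocks:
            n_pre = b["pre"].stop - b["pre"].start
            n_post = b["post"].stop - b["post"].start
            out[b["key"]] = np.full((n_pre, n_post), b["efficacy"] / n_pre, dtype=np.float64)
        return out


def _instances(params: NetworkParams) -> list[tuple[str, str, int]]:
    inst = []
    for r in CHANNEL_REGIONS:
        for ch in (1, 2):
            inst.append((f"{r}_ch{ch}", r, params.population_sizes[r]))
    for r in SHARED_REGIONS:
        inst.append((r, r, params.population_sizes[r]))
    return inst


def build(params: NetworkParams) -> CompiledNetwork:
    """Expand a parameter set into flat per-neuron arrays and weight matrices."""
    params.validate()
    inst = _instances(params)
    pop_names = [name for name, _, _ in inst]
    slices: dict[str, slice] = {}
    offset = 0
    for name, _, n in inst:
        slices[name] = slice(offset, offset + n)
        offset += n
    N = offset

    def fill(region_of: dict, attr: str) -> np.ndarray:
        arr = np.empty(N)
        for name, region, _ in inst:
            arr[slices[name]] = getattr(params.neuron_constants[region], attr)
        return arr

    region_map = {name: region for name, region, _ in inst}
    tau_m = fill(region_map, "tau_m_ms")
    v_leak = fill(region_map, "v_leak")
    v_thresh = fill(region_map, "v_thresh")
    v_reset = fill(region_map, "v_reset")
    v_exc = fill(region_map, "v_exc")
    v_inh = fill(region_map, "v_inh")
    ref_ms = fill(region_map, "t_ref_ms")
    ref_steps = np.maximum(np.round(ref_ms / params.dt_ms), 1).astype(np.int32)

    W_ampa = np.zeros((N, N), dtype=np.float32)
    W_gaba = np.zeros((N, N), dtype=np.float32)
    plastic_blocks: list[dict] = []

    def pairs(p: Projection) -> list[tuple[str, str]]:
        src_ch = p.src in CHANNEL_REGIONS
        dst_ch = p.dst in CHANNEL_REGIONS
        if src_ch and dst_ch:
            if p.pattern == "within":
                return [(f"{p.src}_ch1", f"{p.dst}_ch1"), (f"{p.src}_ch2", f"{p.dst}_ch2")]
            if p.pattern == "cross":
                return [(f"{p.src}_ch1", f"{p.dst}_ch2"), (f"{p.src}_ch2", f"{p.dst}_ch1")]
            if p.pattern == "diffuse":
                return [
                    (f"{p.src}_ch{i}", f"{p.dst}_ch{j}") for i in (1, 2) for j in (1, 2)
                ]
            raise ValueError(f"unknown pattern {p.pattern!r}")
        if src_ch:
            return [(f"{p.src}_ch1", p.dst), (f"{p.src}_ch2", p.dst)]
        if dst_ch:
            return [(p.src, f"{p.dst}_ch1"), (p.src, f"{p.dst}_ch2")]
        return [(p.src, p.dst)]

    for p in params.projections:
        W = W_ampa if p.receptor == "ampa" else W_gaba
        for s_name, d_name in pairs(p):
            s_sl, d_sl = slices[s_name], slices[d_name]
            n_pre = s_sl.stop - s_sl.start
            eff = p.efficacy
            if p.plastic and p.dst == "dSPN" and d_name.endswith("_ch1"):
                eff *= params.channel1_dspn_bias
            w = eff / n_pre
            if s_name == d_name:  # no autapses in recurrent blocks
                block = np.full((n_pre, n_pre), w, dtype=np.float32)
                np.fill_diagonal(block, 0.0)
                W[s_sl, d_sl] += block
            else:
                W[s_sl, d_sl] += w
            if p.plastic:
                ch = d_name.rsplit("_ch", 1)[-1]
                plastic_blocks.append({
                    "key": f"{p.dst}_ch{ch}",
                    "pre": s_sl, "post": d_sl,
                    "target": p.dst, "channel": int(ch),
                    "efficacy": eff, "receptor": p.receptor,
                })

    mu_a = np.zeros(N)
    sig_a = np.zeros(N)
    mu_g = np.zeros(N)
    sig_g = np.zeros(N)
    cx_drive = params.external_drive["Cx"][0]
    for name, region, _ in inst:
        for d in params.external_drive.get(region, []):
            if d.receptor == "ampa":
                mu_a[slices[name]] += d.mu()
                sig_a[slices[name]] += d.sigma()
            else:
                mu_g[slices[name]] += d.mu()
                sig_g[slices[name]] += d.sigma()
    cx_cols = np.concatenate([
        np.arange(slices["Cx_ch1"].start, slices["Cx_ch1"].stop),
        np.arange(slices["Cx_ch2"].start, slices["Cx_ch2"].stop),
    ])

    return CompiledNetwork(
        params=params, pop_names=pop_names, pop_slices=slices, n_total=N,
        tau_m=tau_m, v_leak=v_leak, v_thresh=v_thresh, v_reset=v_reset,
        v_exc=v_exc, v_inh=v_inh, ref_steps=ref_steps,
        W_ampa=W_ampa, W_gaba=W_gaba,
        mu_a=mu_a, sig_a=sig_a, mu_g=mu_g, sig_g=sig_g,
        cx_cols=cx_cols, cx_drive=cx_drive, plastic_blocks=plastic_blocks,
    )


# ---------------------------------------------------------------------------
# results


@dataclass
class TrialBatchResult:
    """Choices, decision times and per-population mean rates of a batch.

    ``choices`` holds 1/2 for the winning channel and -1 for timeouts;
    ``decision_times_ms`` is the time of the first threshold crossing (or
    the window length for timeouts); ``pop_rates_hz`` is
    (n_trials, n_populations) mean rates over each trial's duration, in the
    order of ``pop_names``; ``rate_traces`` (optional) holds binned rates
    (n_trials, n_bins, n_populations) at 5 ms resolution.
    """

    choices: np.ndarray
    decision_times_ms: np.ndarray
    pop_rates_hz: np.ndarray
    pop_names: list[str]
    final_thal_rates_hz: np.ndarray
    rate_traces: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return int(self.choices.size)

    @property
    def timeout_fraction(self) -> float:
        return float(np.mean(self.choices == TIMEOUT))

    def mean_activity(self) -> dict[str, float]:
        """Mean rate per population instance averaged across trials."""
        m = self.pop_rates_hz.mean(axis=0)
        return dict(zip(self.pop_names, m.tolist()))


def summarize_activity(results: list[TrialBatchResult] | TrialBatchResult) -> dict[str, float]:
    """Per-region, per-channel mean rates across one or more trial batches.

    Returns a flat mapping with ``{region}_ch1/2`` keys for channel regions
    and single keys for CxI and FSI, ready for feature building.  At least
    one decided (non-timeout) trial is required.
    """
    if isinstance(results, TrialBatchResult):
        results = [results]
    if not results or sum(r.n_trials for r in results) == 0:
        raise ValueError("summarize_activity requires at least one trial")
    if all(np.all(r.choices == TIMEOUT) for r in results):
        raise ValueError("summarize_activity requires at least one decided trial")
    all_rates = np.vstack([r.pop_rates_hz for r in results])
    names = results[0].pop_names
    mean = all_rates.mean(axis=0)
    return dict(zip(names, mean.tolist()))


# ---------------------------------------------------------------------------
# simulation core


def simulate_trials(
    compiled: CompiledNetwork,
    weights: dict[str, np.ndarray] | None = None,
    n_trials: int = 1,
    seed: int | np.random.Generator | None = None,
    plasticity=None,
    reward_fn=None,
    post_window_ms: float = 300.0,
    collect_traces: bool = False,
    trace_bin_ms: float = 5.0,
) -> TrialBatchResult:
    """Simulate ``n_trials`` independent trials with fixed synaptic weights,
    or a single learning trial when a plasticity engine is supplied.

    Each trial is warmed up (ramp off, no decision detection) before the
    evidence ramp starts.  With ``plasticity`` set (requires
    ``n_trials == 1``), spike pairs feed the eligibility traces on every
    step, ``reward_fn(choice)`` is evaluated at the moment of decision, the
    dopamine transient is injected, and the simulation continues for
    ``post_window_ms`` so that the weight update can integrate the
    eligibility against the decaying dopamine level.  The engine's weight
    matrices are written into the conductance matrix as they change.
    """
    if plasticity is not None and n_trials != 1:
        raise ValueError("plasticity requires single-trial simulation")
    p = compiled.params
    rng = np.random.default_rng(seed)
    dt = p.dt_ms
    N = compiled.n_total
    B = n_trials

    W_ampa = compiled.W_ampa
    if weights is not None or plasticity is not None:
        W_ampa = W_ampa.copy()
        w_src = plasticity.weights if plasticity is not None else weights
        for b in compiled.plastic_blocks:
            W_ampa[b["pre"], b["post"]] = w_src[b["key"]]

    decay_a = math.exp(-dt / TAU_AMPA_MS)
    decay_g = math.exp(-dt / TAU_GABA_MS)
    rate_tau = p.decision.rate_tau_ms
    decay_r = math.exp(-dt / rate_tau)

    tau_m = compiled.tau_m.astype(np.float32)
    v_leak = compiled.v_leak.astype(np.float32)
    v_exc = compiled.v_exc.astype(np.float32)
    v_inh = compiled.v_inh.astype(np.float32)
    v_th = compiled.v_thresh.astype(np.float32)
    v_re = compiled.v_reset.astype(np.float32)

    mu_a = np.tile(compiled.mu_a.astype(np.float32), (B, 1))
    sig_a = np.tile(compiled.sig_a.astype(np.float32), (B, 1))
    mu_g = compiled.mu_g.astype(np.float32)
    sig_g = compiled.sig_g.astype(np.float32)
    has_gaba_drive = bool(np.any(sig_g > 0) or np.any(mu_g > 0))

    cx = compiled.cx_cols
    d = compiled.cx_drive
    f_base = np.maximum(
        rng.normal(p.baseline_mean_hz, p.baseline_sd_hz, size=B), 0.0
    ).astype(np.float32)
    k_mu = 0.001 * d.efficacy * d.n_connections * d.tau_ms
    k_sig2 = 0.0005 * d.n_connections * d.tau_ms * d.efficacy**2

    thal_sl = (compiled.pop_slices["Thal_ch1"], compiled.pop_slices["Thal_ch2"])
    n_thal = np.array([s.stop - s.start for s in thal_sl], dtype=np.float32)

    # state
    V = (v_leak + rng.uniform(0, 10, size=(B, N)).astype(np.float32))
    ref = np.zeros((B, N), dtype=np.int32)
    s_a = np.zeros((B, N), dtype=np.float32)
    s_g = np.zeros((B, N), dtype=np.float32)
    S_ea = mu_a.copy()
    S_eg = np.tile(mu_g, (B, 1)) if has_gaba_drive else None
    thal_rate = np.zeros((B, 2), dtype=np.float32)

    sqa = np.float32(math.sqrt(2.0 * dt / TAU_AMPA_MS))
    sqg = np.float32(math.sqrt(2.0 * dt / TAU_GABA_MS))
    dt_over_tau = (dt / tau_m).astype(np.float32)

    choices = np.full(B, TIMEOUT, dtype=np.int64)
    dtimes = np.full(B, p.decision.max_duration_ms)
    spike_counts = np.zeros((B, N), dtype=np.float32)
    elapsed = np.zeros(B)
    final_thal = np.zeros((B, 2), dtype=np.float32)

    n_bins = int(math.ceil(p.decision.max_duration_ms / trace_bin_ms)) if collect_traces else 0
    traces = (
        np.zeros((B, n_bins, len(compiled.pop_names)), dtype=np.float32)
        if collect_traces else None
    )
    pop_sl = [compiled.pop_slices[nm] for nm in compiled.pop_names]
    pop_n = np.array([s.stop - s.start for s in pop_sl], dtype=np.float32)

    active = np.arange(B)

    n_warm = int(round(p.warmup_ms / dt))
    n_steps = int(round(p.decision.max_duration_ms / dt))
    n_post = int(round(post_window_ms / dt))

    f_ramp = 0.0
    phase = "warmup"
    decided_choice = None
    step_in_phase = 0
    plan = [("warmup", n_warm), ("trial", n_steps)]

    def _step(sel: np.ndarray, f_ext_cx: np.ndarray) -> np.ndarray:
        """Advance the selected trials one dt; returns the spike matrix."""
        nonlocal V, ref, s_a, s_g, S_ea, S_eg
        b = sel.size
        mu_cx = np.float32(k_mu) * f_ext_cx[:, None]
        sig_cx = np.sqrt(np.float32(k_sig2) * f_ext_cx)[:, None]
        mu_a[np.ix_(sel, cx)] = mu_cx
        sig_a[np.ix_(sel, cx)] = sig_cx
        S_ea[sel] += (mu_a[sel] - S_ea[sel]) * np.float32(dt / TAU_AMPA_MS) \
            + sig_a[sel] * sqa * rng.standard_normal((b, N), dtype=np.float32)
        g_a = s_a[sel] + S_ea[sel]
        if has_gaba_drive:
            S_eg[sel] += (mu_g - S_eg[sel]) * np.float32(dt / TAU_GABA_MS) \
                + sig_g * sqg * rng.standard_normal((b, N), dtype=np.float32)
            g_g = s_g[sel] + S_eg[sel]
        else:
            g_g = s_g[sel]
        Vs = V[sel]
        dV = dt_over_tau * (-(Vs - v_leak) - g_a * (Vs - v_exc) - g_g * (Vs - v_inh))
        Vs = Vs + dV
        in_ref = ref[sel] > 0
        Vs[in_ref] = np.broadcast_to(v_re, Vs.shape)[in_ref]
        spk = Vs >= v_th
        Vs[spk] = np.broadcast_to(v_re, Vs.shape)[spk]
        V[sel] = Vs
        ref_s = ref[sel]
        ref_s[in_ref] -= 1
        ref_s[spk] = np.broadcast_to(compiled.ref_steps, spk.shape)[spk]
        ref[sel] = ref_s
        spk_f = spk.astype(np.float32)
        s_a[sel] = s_a[sel] * np.float32(decay_a) + spk_f @ W_ampa
        s_g[sel] = s_g[sel] * np.float32(decay_g) + spk_f @ compiled.W_gaba
        return spk

    # --- warmup -------------------------------------------------------------
    for _ in range(n_warm):
        _step(active, f_base)
        if not np.all(np.isfinite(V)):
            raise SimulationDivergence(_diverging_population(compiled, V))

    # --- trial --------------------------------------------------------------
    check_every = 200
    ramp_every = max(1, int(round(p.ramp.step_ms / dt)))
    for step in range(1, n_steps + 1):
        if (step - 1) % ramp_every == 0:
            f_ramp = ramp_step(f_ramp, p.ramp.f_target, p.ramp.gain)
        spk = _step(active, f_base[active] + np.float32(f_ramp))
        spike_counts[active] += spk
        if collect_traces:
            bin_idx = min(int((step - 1) * dt / trace_bin_ms), n_bins - 1)
            for k, sl in enumerate(pop_sl):
                traces[active, bin_idx, k] += spk[:, sl].sum(axis=1)
        for c in (0, 1):
            cnt = spk[:, thal_sl[c]].sum(axis=1)
            thal_rate[active, c] = (
                thal_rate[active, c] * np.float32(decay_r)
                + cnt * np.float32(1000.0 / (n_thal[c] * rate_tau))
            )
        if plasticity is not None:
            dirty = plasticity.on_step(spk[0], compiled.plastic_blocks, dt)
            if dirty:
                for b in compiled.plastic_blocks:
                    W_ampa[b["pre"], b["post"]] = plasticity.weights[b["key"]]
        crossed = thal_rate[active] >= p.decision.threshold_hz
        any_crossed = crossed.any(axis=1)
        if np.any(any_crossed):
            done_local = np.nonzero(any_crossed)[0]
            done = active[done_local]
            both = crossed[done_local, 0] & crossed[done_local, 1]
            pick = np.where(
                both,
                np.argmax(thal_rate[done], axis=1),
                np.argmax(crossed[done_local], axis=1),
            )
            choices[done] = pick + 1
            dtimes[done] = step * dt
            elapsed[done] = step * dt
            final_thal[done] = thal_rate[done]
            keep = ~any_crossed
            active = active[keep]
            if plasticity is not None:
                decided_choice = int(choices[done[0]])
                break
            if active.size == 0:
                break
        if step % check_every == 0 and not np.all(np.isfinite(V)):
            raise SimulationDivergence(_diverging_population(compiled, V))

    if active.size:  # timeouts
        elapsed[active] = n_steps * dt
        final_thal[active] = thal_rate[active]

    # --- reward delivery and post-decision window (learning mode) ------------
    if plasticity is not None and decided_choice is not None and reward_fn is not None:
        reward = reward_fn(decided_choice)
        plasticity.reward_event(decided_choice, float(reward))
        sel = np.array([0])
        for post_step in range(n_post):
            if post_step % ramp_every == 0:
                f_ramp = ramp_step(f_ramp, p.ramp.f_target, p.ramp.gain)
            spk = _step(sel, f_base + np.float32(f_ramp))
            dirty = plasticity.on_step(spk[0], compiled.plastic_blocks, dt)
            if dirty:
                for b in compiled.plastic_blocks:
                    W_ampa[b["pre"], b["post"]] = plasticity.weights[b["key"]]

    dur_s = np.maximum(elapsed, dt) / 1000.0
    pop_rates = np.empty((B, len(pop_sl)), dtype=np.float64)
    for k, sl in enumerate(pop_sl):
        pop_rates[:, k] = spike_counts[:, sl].sum(axis=1) / (pop_n[k] * dur_s)
    if collect_traces:
        traces /= pop_n[None, None, :] * (trace_bin_ms / 1000.0)

    return TrialBatchResult(
        choices=choices,
        decision_times_ms=dtimes,
        pop_rates_hz=pop_rates,
        pop_names=list(compiled.pop_names),
        final_thal_rates_hz=final_thal,
        rate_traces=traces,
    )


def _diverging_population(compiled: CompiledNetwork, V: np.ndarray) -> str:
    bad = ~np.isfinite(V)
    cols = np.nonzero(bad.any(axis=0))[0]
    if cols.size == 0:
        return "unknown"
    c = cols[0]
    for name, sl in compiled.pop_slices.items():
        if sl.start <= c < sl.stop:
            return name
    return "unknown"


def simulate_probe_block(
    compiled: CompiledNetwork,
    weights: dict[str, np.ndarray] | None,
    n_trials: int,
    seed: int | np.random.Generator | None,
    collect_traces: bool = False,
) -> TrialBatchResult:
    """Probe trials: plasticity off, weights frozen."""
    return simulate_trials(
        compiled, weights=weights, n_trials=n_trials, seed=seed,
        collect_traces=collect_traces,
    )
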