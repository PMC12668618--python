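# Methods

This note documents the models implemented in `cbgtlearn`, the choices
made where the design was genuinely open, and what the tests do and do
not establish.

## Spiking CBGT network

Each of nine regions is a population of conductance-based leaky
integrate-and-fire neurons; cortex (Cx), dSPN, iSPN, GPe, STN, GPi and
thalamus exist once per action channel, CxI and FSI are shared. The
membrane equation is

    τ_m dV/dt = −(V − V_L) − g_AMPA (V − V_E) − g_GABA (V − V_I),

with conductances in units of the leak conductance, V_L = −70 mV,
threshold −50 mV, reset −56 mV, refractory 2 ms, V_E = 0, V_I = −80 mV,
τ_m = 10 ms for all cell types. Synapses are exponential with τ = 2 ms
(AMPA) and 5 ms (GABA). A projection's efficacy is the total conductance
jump a postsynaptic neuron receives if every presynaptic neuron fires
once (per-synapse weight = efficacy / n_pre), which makes efficacies
independent of population size.

**Background drive.** Every population receives an Ornstein–Uhlenbeck
conductance (the diffusion approximation of filtered Poisson input) with
mean μ = 0.001·E·f·N·τ and stationary standard deviation
σ = E·√(0.0005·f·N·τ), advanced as
dS = (μ − S)/τ·dt + σ·√(2/τ)·dW. The √(2/τ) diffusion scaling is the
standard mean-reverting normalization that gives exactly this stationary
variance.

**Evidence ramp.** Cortical input frequency is f_baseline + f_ramp(t)
with f_baseline ~ Normal(2.5, 0.06) Hz drawn per trial (clipped at 0) and
the recurrence f_ramp ← f_ramp + 0.1·(f_target − f_ramp), f_target = 1 Hz,
applied on its own 20 ms update clock (a ~200 ms rise). The recurrence is
step-size dependent as written: applied per integrator step at
sub-millisecond dt the ramp would complete within a millisecond, evidence
onset would be instantaneous, and the reaction-time distribution would
lose its onset-delay mass entirely (per-stage DDM fits then degenerate
toward t = 0 with inflated drift). The update clock is a config
parameter; setting it to the integrator dt recovers the literal per-step
form. Both channels receive identical input; any choice asymmetry is
downstream of cortex. The cortical background arrives through many weak
contacts (800 connections), which keeps the relative background noise
small enough that decisions are evidence-locked rather than
noise-driven; this is what lets slow networks keep their timeout rate
under the acceptance screen's 1%.

**Decision rule.** Each thalamic population's firing rate is estimated
with an exponential filter (time constant 20 ms; with tens of neurons per
population a shorter window holds only 1–2 spikes and the crossing
becomes noise-dominated). The first channel whose estimate reaches 30 Hz
wins; 1000 ms without a crossing is a timeout.

**Numerics.** Fixed-step Euler for the membrane equation with exact
exponential decay of all conductances, dt = 0.25 ms, 150 ms warm-up per
trial (ramp off, no decision detection). Probe blocks are vectorized
across trials; results are bit-reproducible given (parameters, weights,
seed). Non-finite membrane potentials raise an error naming the
offending population.

**Reconstructed constants.** The quantitative tables behind the original
circuit (external-drive settings, plasticity constants, free-parameter
ranges, physiological rate ranges) are not available, so every such
value here is a reconstruction, calibrated once against the intended
operating points: all baseline rates inside broad physiological
ranges (pallidal/nigral populations tonically active near 50 Hz, SPNs
near 2–3 Hz), heterogeneous baseline reaction times within the 1000 ms
window, chance baseline accuracy, and learning that saturates within
about 15 deterministic-feedback trials at roughly 90% accuracy. They are
all exposed in configuration and none is hard-coded into the analyses.

## Dopamine-dependent corticostriatal plasticity

Spike traces A_PRE/A_POST jump by Δ/τ at spikes and decay exponentially;
eligibility integrates post-on-pre minus pre-on-post pairings with
τ_E = 80 ms; the weight update is multiplicative and bounded,

    dw/dt = [α_w E f(K_DA)(w_max − w)]₊ + [α_w E f(K_DA)(w − w_min)]₋,

with α_w > 0 for dSPN targets and < 0 for iSPN targets, and f(K_DA)
piecewise linear (dSPN floored at −γ below −μ; iSPN capped at εγ above
μ). Phasic dopamine K_DA jumps toward the reward-prediction error
r − Q_action at each outcome (K ← K + C_scale·(RPE − K), a literal
reading of the impulse equation) and decays with τ_DA = 150 ms. Action
values follow a delta rule, Q ← Q + α_Q·(r − Q), initialized at 0.5 so
that early unrewarded choices produce genuine dopamine dips (with Q₀ = 0
an unrewarded novel option has zero prediction error and errors would
teach nothing).

Operator ordering within a step is traces → eligibility → conductance →
weight; traces and eligibility reset at trial start (inter-trial
intervals are long relative to their decay constants) while Q persists.
After the decision, the reward is delivered and the simulation continues
for a 300 ms window in which the decaying dopamine transient is
integrated against the remaining eligibility.

Two calibration observations shaped the defaults. First, learning
strength (α_w = ±450, γ = 1, μ = 0.5, ε = 0.8, w_max = 2.5× the initial
weight) is set so that cohort accuracy rises gradually and saturates
near ~90% around trial 15 — not within the first two trials — with
corticostriatal weights approaching but not piling up at their bounds.
Second, α_Q = 0.2: with fast action-value learning the rewarded option's
RPE collapses to zero after a few trials while occasional errors retain
finite negative RPE, and because the multiplicative rule makes strong
weights fragile (the (w − w_min) factor is largest for them), the
learned asymmetry then erodes; a slower α_Q keeps positive RPEs alive
long enough to balance error-driven unlearning, giving stable
saturation.

## Task protocol

Two-armed bandit, deterministic feedback by default (P(reward) = 1 for
the optimal option, 0 otherwise). Learning trials run singly with
plasticity on; at stages 2, 4, 6 and 15 trials the weights are frozen
and a probe block (300 trials by default; reduced in desk-scale runs) is
simulated with plasticity off, plus a naive probe block before any
learning. Probe blocks read a weight snapshot and cannot touch the
plasticity engine, so freezing is exact by construction. Timeout trials
are excluded from all RT/choice fitting. Networks are classed fast /
intermediate / slow by an equal-count tertile split of naive probe mean
RTs, ties broken by network order. Δ (between-channel) features are
aligned rewarded-minus-unrewarded after learning and channel1 − channel2
at baseline.

## DDM fitting

First-passage densities use the small-time/large-time series with the
standard automatic truncation rule; the simulator is Euler–Maruyama with
a Brownian-bridge within-step crossing correction (without it,
absorption is detected late at order √dt and fitted drifts are biased).
Fits are per-(network, stage) penalized maximum likelihood over
(v, a, t) with σ = 1 and z = 0.5 (networks are built unbiased; a flag
enables free z): Nelder–Mead from several heuristic starts followed by a
bounded polish, t constrained below the minimum observed RT. A weak
Gaussian prior on the drift (scale 8) regularizes probe blocks with
zero errors, where the plain likelihood is flat in v and the estimate
would otherwise run to the box bound — the role hierarchical shrinkage
plays in group-level Bayesian fits; for identified samples the penalty
is negligible (parameter-recovery tests pass at the same tolerances with
and without it). Fewer than 50 decided trials or a single-choice sample
flags weak identification. Goodness of
fit is the Pearson correlation of choice-signed RT percentiles
(5, 10, …, 95) between observed and refitted-model-simulated samples.

## Policy manifolds

RT, accuracy and reward-rate surfaces are estimated by simulating the
DDM on a (v, a) grid spanning the fitted range (averaged over seeds; t
and z fixed at the cohort's baseline means), smoothed with a 3-node
moving average before central differencing. Gradients point in the
direction of objective improvement (the RT gradient is negated). Each
learning step (consecutive fitted (v, a) points) is scored by the cosine
distance to each objective's gradient evaluated at the step's start
point; distances are invariant to positive rescaling of either vector.
The objective comparison uses per-network mean distances: a one-way
repeated-measures F across the three objectives (closed-form sums of
squares) and paired t-tests between objective pairs.

## Control ensembles and drivers

The feature matrix has 16 columns in fixed order: Σ (channel-summed) and
Δ (channel-difference) rates for Cx, dSPN, iSPN, GPe, STN, GPi, Thal,
plus CxI and FSI. Features and the policy matrix (a, t, v) are
standardized; the scalers are serialized and reused for projecting
learning-induced changes. CCA components are validated by 4-fold
held-out canonical correlations against a row-shuffle null; components
whose mean held-out ρ exceeds the null mean + 2 SD are retained. The
reported loadings are *structure loadings* — correlations of each
standardized variable with its side's canonical scores — which are what
per-region loading plots display and which recover planted factor
loadings far more accurately than raw weight vectors; each component is
sign-fixed so its largest-magnitude feature loading is positive. Labels
follow the policy-side pattern: same-signed a and t loadings →
responsiveness, opposite-signed → pliancy, v-dominated → choice;
anything else is flagged unresolved rather than forced.

ΔF (post- minus pre-learning rates, in the baseline standardized space)
is decomposed as P = ΔF·V (top-5 PCs of ΔF) and C = ΔF·U (baseline
ensemble loadings, always from the full baseline cohort, also for
class-restricted ΔF); the driver matrix solves the normal equation
S = (CᵀC)⁻¹CᵀP (condition number checked; pseudo-inverse fallback with a
warning). PC signs are anchored along the cohort's mean change —
without an anchor S is invariant to a global sign flip of ΔF and
opposite-outcome cohorts (U-U vs R-R) could not show opposite drivers.
Five PCs are always used for comparability across classes. The net
modulation per cohort is the variance-fraction-weighted sum of S's
columns. The outcome-sequence analysis regroups networks by the reward
pattern of the first two trials at the 2-trial freeze and recomputes the
full decomposition per group, with ΔRR measured against the naive
baseline probe block; groups smaller than the minimum size are flagged
and skipped.

## Genetic algorithm

Free projection efficacies (14 by default: corticostriatal,
striatopallidal, pallidal, subthalamic, nigrothalamic, thalamocortical
and intrastriatal inhibition) are discretized into endpoint-inclusive
30-point grids spanning default ± 30%; genomes are index vectors, so any
genome decodes inside its ranges. Variation is one-point segment-swap
crossover, index-shuffle mutation (p = 0.2), and a per-gene uniform
index reset (p = 0.4): segment swap and shuffling only recombine values
already in the population, so without a reset the gene pool fixates and
the acceptance region cannot be covered. Selection is tournament of
size 3 on the lexicographic key (timeout fraction, then −correlation).
A candidate is screened on a probe block with plasticity off: timeout
fraction below 1%, positive Pearson correlation between binned summed
excitatory-cortex and summed SPN rates over pre-decision bins (the
basal-ganglia-driven regime check), and mean rates inside the configured
physiological table. Every acceptable candidate is archived; the run
stops at the target count or the generation cap, and finding nothing is
reported, not raised.

## Synthetic surrogates

Latent-factor cohorts drive the CCA and driver tests without any spiking
simulation: orthonormal planted loading frames (near-collinear frames
make weaker factors statistically unidentifiable), factor scale 1 and
noise 0.2 (signal-to-noise 5) by default, 300 rows. Driver cohorts plant
ΔF = C·S0·Vᵀ with orthonormal V and U = V·S0⁺ so the noiseless pipeline
recovers S0 exactly; an optional nonzero score mean gives the cohort a
net change direction (needed to exercise the PC sign anchoring). DDM
cohorts simulate known parameter tables. All generators are
seed-deterministic.

What these surrogates do not emulate: the joint distribution of real
spiking-cohort features (correlated noise across regions, class
structure, nonlinear feature/parameter couplings). Tests that pass on
them establish the correctness of the estimators, not that the spiking
model's cohort statistics match any particular empirical population.

## Problem sizes

Desk-scale defaults keep a full study on one CPU: cohorts of ~10
networks with tens of neurons per population, 80–100-trial probe blocks,
7–9-point manifold grids with 3–5 seeds of 150–200 trials, 4-fold CCA
with tens of shuffles. These sizes are the package's own defaults for
interactive use; all of them scale up in configuration.

## Known limitations

- Cohort-level population statistics (exact t/F values of a 300-network
  study) are out of reach at desk scale; the analyses assert signs,
  orderings and recovery accuracy instead.
- The spiking model omits NMDA currents, multi-compartment structure,
  and more than two action channels.
- All quantitative constants are reconstructions (see above); absolute
  firing rates and RT scales should be read as qualitative.
- Per-component CCA loadings are identified only up to rotation when
  canonical correlations are nearly equal; subspace-level statements are
  the robust ones.
- The cohort's reaction-time variance stays high even once networks are
  accurate, which per-network DDM fits absorb into the boundary height:
  fitted a tends to rise over learning here, so pooled learning steps
  track the accuracy gradient at the first stage more closely than the
  reward-rate gradient (later steps favor reward rate). Cohorts whose RT
  distributions tighten with learning would not show this; it should be
  read as a property of the reconstructed circuit constants, not of the
  analysis pipeline.
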