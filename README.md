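# cbgtlearn

Spiking cortico-basal-ganglia-thalamic (CBGT) decision circuits,
dopamine-dependent corticostriatal plasticity, and the decomposition of
learned decision policies into low-dimensional *control ensembles*.

## The scientific problem

When an animal learns which of two options pays off, its choices become
both more accurate and faster — the decision *policy* shifts. At the
algorithmic level a policy can be summarized by drift-diffusion model
(DDM) parameters: evidence accumulates at drift rate *v* toward one of two
boundaries separated by *a*, after an onset delay *t*, from a starting
fraction *z*,

    dx = v·dt + σ·dW,    RT = first-passage time + t.

At the implementation level the same behaviour is produced by CBGT
circuits: two "action channels" of cortex (Cx), direct- and
indirect-pathway striatal neurons (dSPN/iSPN), GPe, STN, GPi and thalamus,
with shared inhibitory pools (CxI, FSI). This package simulates that loop
with conductance-based integrate-and-fire neurons, lets reward prediction
errors gate eligibility-trace plasticity at the corticostriatal synapses,

    dE/dt = (X_POST·A_PRE − X_PRE·A_POST − E)/τ_E,
    dw/dt = [α_w·E·f(K_DA)·(w_max−w)]₊ + [α_w·E·f(K_DA)·(w−w_min)]₋,

and asks *which objective the learning trajectory actually climbs*: speed,
accuracy, or reward rate RR = (1 − p_err)/RT. The answer is assembled
from four analyses:

1. **Policy manifolds** — RT/accuracy/RR surfaces over the (v, a) plane,
   and the cosine distance between each network's learning step and each
   objective's gradient.
2. **Control ensembles** — canonical correlation analysis (CCA) between
   16 firing-rate features (per-region channel sums Σ and differences Δ,
   plus CxI and FSI) and the fitted DDM parameters (a, t, v), yielding the
   *responsiveness*, *pliancy* and *choice* ensembles.
3. **Ensemble drivers** — the least-squares matrix S = (CᵀC)⁻¹CᵀP that
   expresses the principal components of learning-induced firing-rate
   change (P = ΔF·V) as combinations of ensemble projections (C = ΔF·U).
4. **Outcome sequences** — the same driver decomposition grouped by the
   reward pattern of the first two trials (U-U, U-R, R-U, R-R).

Cohorts of valid networks are sampled with a binned-index genetic
algorithm under two acceptance criteria: fewer than 1% trial timeouts and
a positive correlation between cortical and striatal activity.

## Worked example

```python
import numpy as np
from cbgtlearn import network as nw, ddm
from cbgtlearn.task import SessionConfig, run_session

net = nw.NetworkParams()                  # channel-symmetric default circuit
log = run_session(net, config=SessionConfig(
    n_learning_trials=15, freeze_stages=(2, 4, 6, 15),
    probe_trials_per_stage=100, seed=7))

for stage in (0, 2, 15):
    s = log.probe_sample(stage)
    fit = ddm.fit_mle(s, min_trials=50)
    print(f"stage {stage:2d}: acc={s.accuracy:.2f} "
          f"RT={1000*np.mean(s.rt):.0f} ms  "
          f"v={fit.params.v:.2f} a={fit.params.a:.2f} t={fit.params.t*1000:.0f} ms")
```

Output (seed 7):

```
stage  0: acc=0.58 RT=380 ms  v=0.27 a=1.18 t=49 ms
stage  2: acc=0.81 RT=354 ms  v=1.26 a=1.26 t=44 ms
stage 15: acc=0.95 RT=207 ms  v=3.10 a=1.37 t=8 ms
```

The naive network is near chance; fifteen rewarded trials raise the
drift rate more than tenfold and shorten reaction times by nearly half
while the boundary moves little — accuracy and speed improve together,
the joint improvement that raises reward rate.

The full study — GA cohort sampling, sessions, DDM fits, manifolds, CCA
and drivers — runs from one command and is resumable:

```bash
cbgtlearn run-study --out study_out --seed 7
```

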