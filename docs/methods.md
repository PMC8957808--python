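# Methods

## Model

Every unit represents a neural population by a single voltage `V` and a
firing rate `F(V) = [tanh(V)]+` (positive part), so rates live in
[0, 1) and inhibition can hyperpolarize the voltage below zero without
producing negative rates. Voltages follow the leaky-integrator equation

    tau dV/dt = -V + I + sum_pre w[post, pre] * F(V_pre)

discretized with the explicit Euler method. Updates are synchronous
(every unit's new voltage uses the previous step's rates), which makes
the integration independent of unit ordering. There is no noise and no
random initialization anywhere in the simulator: identical
configurations produce byte-identical traces.

Plastic connections follow a simplified BCM rule applied once per
timestep immediately after the voltage update,

    dW = alpha * (F_post - theta) * F_pre,

hard-clipped to a per-edge range `[Wmin, Wmax]`. The threshold `theta`
is fixed (no sliding-threshold dynamics); the configuration supports
per-edge overrides of both `alpha` and `theta`. Inhibitory units are
never presynaptic to a plastic edge.

## Integration parameters

| parameter      | default | meaning                                        |
|----------------|---------|------------------------------------------------|
| `dt`           | 0.1     | Euler step (dimensionless time)                |
| `tau`          | 1.0     | membrane time constant; `dt/tau <= 1` required |
| `trial_length` | 500     | steps per behavioral trial                     |
| `alpha`        | 0.002   | global learning rate per step                  |
| `theta`        | 0.5     | global BCM threshold (rate units)              |

With `dt/tau = 0.1` the network settles well within a 500-step trial, so
each trial approximates one behavioral exposure at quasi-steady state
while the within-trial plasticity still produces the gradual weight
drifts visible across the protocol. Voltages are reset at every trial
onset (trials model separate exposures); weights persist. All weights,
rates, bounds and amplitudes are the package's own calibration (below);
no external parameter set is transcribed.

## Protocol and manipulations

The default protocol is baseline (1 trial, conspecific + context 1),
conditioning (3 trials, adding the defeat input that drives lPBN and the
prefrontal Som1 interneuron), extinction (11 trials). Input channels
drive their target units with gain x amplitude added to `I`; an active
channel's default amplitude is 1.0, a natural scale given the tanh
saturation.

Manipulations emulate opto-/pharmacogenetic interventions and are
strictly windowed (phases, trials, optional step ranges):
`silence_unit` clamps the rate to zero (an output block — leak dynamics
continue), `stimulate_unit` adds a tonic input term,
`block_connection`/`scale_connection` modify the effective weight used
by the dynamics while the stored weight stays untouched, and
`freeze_plasticity` disables learning on targeted edges. Outside its
window a manipulation has exactly zero effect.

High- and low-frequency stimulation of the MDT are modelled as tonic
exogenous drives (defaults 2.5 and 0.25) in a dedicated stimulation
phase of 18 trials inserted after conditioning, with plasticity enabled
only on the MDT efferents for its duration. The HFS amplitude must push
the Pv and Pyr2 rates above `theta` — verified at the end of the block,
because the potentiation it induces is cumulative — while the LFS
amplitude must hold them strictly between 0 and `theta`, verified at the
end of the first block trial, i.e. in the regime the amplitude itself
sets before the induced depression reshapes the circuit.

## Architecture conventions

- HypIN1 is the interneuron inhibiting Hyp1 (driven by Hyp2); HypIN2
  inhibits Hyp2 (driven by Hyp1): each interneuron is indexed by the
  unit it inhibits.
- Pyr2 -> dPag1 is a direct negative weight despite the glutamatergic
  presynaptic unit: the prefrontal top-down control is modelled as
  direct inhibition, abstracting over its (likely metabotropic,
  long-latency) mechanism. It is the single documented exception to the
  rule that weight signs match the presynaptic transmitter.
- Pyr1 has no direct dPAG projection; its fear-promoting action runs
  through Som2-mediated suppression of Pyr2 (disinhibition of dPag1),
  so the output unit has exactly two afferents.
- Both context populations project with identical initial weights, so
  context specificity after conditioning is a learned difference.

## Calibration

Weights were calibrated by coordinate-wise manual/grid adjustment until
the full qualitative checklist passes: baseline quiet, conditioning
drives the avoidance output above threshold, extinction completes
within 11 trials, VMHvl weights stable during extinction, and all five
reproduction experiments pass against matched controls. Structural
choices that make the calibration robust rather than knife-edged:

- Plastic edges whose target is silent in the naive state start at
  their lower clip bound, so the depression they receive before
  conditioning is absorbed by the clip instead of eroding the circuit.
- The baseline activity of the threat unit Hyp1 is a small direct drive
  with only weak interneuron inhibition, not a near-cancellation of two
  large terms; the winner-take-all branch that crushes Hyp2 during
  conditioning (Hyp1 -> HypIN2 -> Hyp2) is strong and saturating.
- Hypothalamic afferents learn faster (`alpha = 0.004`) than
  thalamocortical ones (Pyr1 0.002, Pyr2 0.0012, Pv 0.0009), so the
  three defeat trials saturate the VMHvl reorganization while the mPFC
  reorganization paces the slow extinction.

Extinction in the basic model is a prefrontal hand-over: after
conditioning has depressed MDT->Pv and MDT->Pyr2 and potentiated
MDT->Pyr1, the Pv rate sits just above `theta`, so MDT->Pv slowly
repotentiates across extinction trials; rising Pv inhibition pushes the
fear-ON unit Pyr1 below threshold, its thalamic afferent depresses, the
Som2 brake on Pyr2 releases, and MDT->Pyr2 repotentiates until Pyr2
silences dPag1. Low-frequency MDT stimulation depresses MDT->Pv below
the level from which this recovery can bootstrap, locking the circuit
in the fear configuration — which is why extinction is genuinely
fragile to weakening MDT->Pv or the Pv -> Pyr1 inhibition.

### Alternative model

The alternative configuration is the same topology plus the LS unit and
its inhibitory LS -> Hyp1 edge, but is calibrated separately: the dPAG
drive is dominated by Hyp1 (4.0 versus -2.0 for Pyr2), the Hyp1
afferents have tighter potentiation ceilings, the VMHvl learns slightly
faster (0.005), the local interneurons are stronger, and the Hyp2
afferents use a lower BCM threshold (0.25) so they potentiate while
Hyp2 regains control during extinction. Identical weights in both
variants cannot produce the septal-inhibition brackets: the
mPFC extinction path would be unchanged by construction, so dPag1 would
always extinguish at least as fast as in the basic model no matter how
much LS output is removed.

In this variant extinction runs through trial-onset competitions
between the conditioned threat unit and the recovering interaction
unit: each exposure depotentiates the Hyp1 afferents a little, until
Hyp2 wins the onset race and shuts Hyp1 down. Scaling the LS output
down during extinction delays the losing race; the shipped calibration
places the first slowing at a 30% reduction and the loss of extinction
(within the 11-trial horizon) at 38%.

## Thresholds and metrics

- Avoidance threshold: a trial counts as avoidant when the trial-mean
  dPag1 rate is at least 0.1; extinction completes at the first
  extinction trial below it. Avoidance is identified with dPAG
  activation; the 0.1 cutoff is a package choice and configurable.
- Responsiveness threshold for unit classification: 0.15 was considered
  first, but the alternative model's first-extinction-trial threat
  response sits near 0.12 under the calibration that reproduces the
  30%/38% brackets, so the shipped default is 0.10. At 0.10 every class
  assignment in both models is clean (quiet units stay below 0.09,
  responsive ones above 0.10 with margin).
- Classification reads responsiveness on the first and last extinction
  trials: (yes, no) fear, (no, yes) extinction, (yes, yes) persistent.
- "Impairment" criteria for the plasticity-block and lPBN-block
  predictions are relative to the matched control (manipulated
  first-extinction-trial avoidance at most 0.35x the control's) — a
  drastic drop rather than absolute silence; an absolute
  sub-threshold criterion would contradict the Pyr2-output-block
  reproduction, since both compare dPag1 driven by the same
  baseline-level Hyp1.
- "Acceleration" in the interneuron-manipulation reproductions means
  the extinction curve shifts down as a whole: completion no later than
  control and cumulative extinction-phase avoidance strictly lower
  (by more than 0.05). An integer completion-trial comparison aliases
  under small parameter changes; at the shipped calibration the Pv
  stimulation also completes strictly earlier (2 versus 4 trials),
  while the Som inhibition halves the cumulative avoidance and
  completes at the same trial.

## Sensitivity analysis

Each connection weight (and, for plastic edges, its clip bounds) is
rescaled over a multiplicative grid (default 0 to 2 in steps of 0.05)
and the full qualitative checklist is rerun at every point. An edge's
robustness is the distance from 1.0 to the nearest failing scale; edges
tied in the two smallest coarse buckets are re-resolved at 1% steps.
Under the shipped calibration the two least robust edges are MDT->Pyr1
(~12% margin; roughly a -25%..+13% tolerated range) and lPBN->Hyp1
(~18%), followed by Pv->Pyr1 (~19%); most edges tolerate the entire
grid. Either hypothalamic interneuron, and the Som1->Pyr2 edge, can be
deleted outright without breaking the checklist.

## What the simulations do and do not show

All validation is qualitative reproduction of population-level
findings. The model abstracts over spiking, conduction delays, noise,
oscillations, cortical layering, and every brain area not listed; the
input "defeat" is a single tonic channel rather than a structured
nociceptive event. Passing the checklist therefore shows that the
hypothesized circuit logic is sufficient to generate the observed
phenomenology under the stated protocol — not that the real circuit
uses these weights, rates or thresholds, nor that the calibration is
unique. The sensitivity analysis quantifies how special the shipped
weights are, one edge at a time; it does not explore correlated
parameter changes.

## Numerical notes

- Explicit Euler with `dt/tau = 0.1` is well inside the stable region;
  the leak term alone contracts voltages by 0.9 per step.
- Weight clipping is applied after every per-step update, so a clipped
  weight is exactly at its bound (no overshoot).
- Silencing clamps the rate after the activation is computed; the
  plasticity update sees the clamped rate, so a silenced unit neither
  learns on its efferents (presynaptic gating) nor potentiates its
  afferents.
- Trial traces are recorded after silencing, so recorded rates always
  reflect what downstream units actually received.
- Degenerate inputs: a phase with no active channels integrates the
  leak alone from the reset state and stays identically zero.
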