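# socialfear

A firing-rate model of the rodent social-fear circuit: conditioning and
extinction of social avoidance in the network formed by the medial
amygdala (MeA), ventral hippocampus (vHIP), lateral parabrachial nucleus
(lPBN), mediodorsal thalamus (MDT), ventrolateral ventromedial
hypothalamus (VMHvl), medial prefrontal cortex (mPFC) and dorsal
periaqueductal gray (dPAG). The package is aimed at computational
neuroscientists and systems-neuroscience labs who want to run in-silico
lesion, stimulation and plasticity-block experiments on this circuit, or
to extend it.

## The model

Each unit is a neural population with voltage `V` and firing rate
`F(V) = [tanh V]+`, integrated with the explicit Euler method:

    tau dV/dt = -V + I + sum_pre w[post,pre] * F(V_pre)

Designated connections learn by a simplified Bienenstock–Cooper–Munro
(BCM) rule with hard clipping:

    dW = alpha * (F_post - theta) * F_pre,   W in [Wmin, Wmax]

so postsynaptic activity above the threshold `theta` potentiates an
active synapse and activity below it depresses it.

Social avoidance is read out as the activation of the dPAG output unit,
which receives excitation from the VMHvl threat population (Hyp1) and
inhibition from the prefrontal fear-OFF population (Pyr2). The standard
protocol is one baseline trial (conspecific + context), three
conditioning trials (adding a defeat input that drives lPBN and the
prefrontal Som1 interneuron), and eleven extinction trials; each trial
is 500 timesteps. Two calibrated circuit variants ship with the package:
the 16-unit **basic** model, and the 17-unit **alternative** model that
adds a lateral-septum (LS) unit inhibiting Hyp1, which relocates part of
extinction learning into the VMHvl.

## Worked example

```python
import socialfear as sf

spec = sf.build_basic_model()
result = sf.run_protocol(spec)                    # baseline -> conditioning -> extinction

print([round(x, 3) for x in result.trial_means("dPag1")])
print("trials to extinction:", sf.trials_to_extinction(result))
cls = sf.classify_all(result)
print({u: cls[u].cls for u in ("Pyr1", "Pyr2", "Hyp1")})
```

prints

```
[0.0, 0.907, 0.949, 0.962, 0.949, 0.837, 0.207, 0.06, 0.03, 0.017, 0.009, 0.005, 0.004, 0.004, 0.004]
trials to extinction: 4
{'Pyr1': 'fear', 'Pyr2': 'extinction', 'Hyp1': 'persistent'}
```

The avoidance index (trial-mean dPag1 rate) is silent at baseline, jumps
above 0.9 during the three defeat trials, stays high early in extinction
and collapses below the 0.1 avoidance threshold at extinction trial 4.
Classifying units by their responses on the first and last extinction
trials recovers the three population types described in fear
physiology: prefrontal Pyr1 behaves as a fear unit, Pyr2 as an
extinction unit, and the hypothalamic threat unit Hyp1 remains
persistently responsive.

The same library exposes the named in-silico lesion, stimulation and plasticity-block experiments:

```python
sf.reproduce_experiment("franklin_pyr2_block")    # naive dPAG disinhibition
sf.run_prediction("mdt_lfs")                      # low-frequency MDT stimulation
sf.run_prediction("ls_scaling")                   # septal-output reduction sweep
```

or from the shell:

```bash
socialfear check                       # qualitative criteria on the shipped config
socialfear reproduce krzywkowski_context
socialfear predict mdt_hfs --out out/
socialfear sweep --model basic         # sensitivity analysis
socialfear simulate my_run.yaml        # any YAML-configured protocol
```

Exit codes: 0 success, 1 criteria failure, 2 configuration error.

## Layout

- `src/socialfear/dynamics.py` — leaky firing-rate integration
- `src/socialfear/plasticity.py` — BCM rule with clipping
- `src/socialfear/circuits.py` — the two calibrated architectures
- `src/socialfear/protocol.py` — trials, phases, timed manipulations
- `src/socialfear/experiments.py` — metrics, unit classes, the named
  reproduction/prediction suites, sensitivity analysis
- `src/socialfear/io.py`, `cli.py` — YAML configs, CSV/JSON output, CLI
- `src/socialfear/configs/` — the shipped calibrations as YAML
- `docs/methods.md` — modelling choices, parameters, and limitations
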