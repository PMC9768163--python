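# soam

Agent-based simulation of **opinion amplification** on directed social
networks, for researchers in opinion dynamics and computational social
science who want to study how *extreme polarization* — opinions
diverging beyond their initial range — can arise without external
shocks, and how platform-style interventions curb it.

## The model

`n` agents hold continuous opinions, initialized i.i.d. uniform on
[−1, 1], on a directed network (edge *j → i* means *i* follows *j*).
A proportion π of agents are *amplifiers*: each timestep, with
probability *p*, an amplifier's **expressed** opinion is its actual
opinion pushed away from zero by σ ~ U[0, *s*]:

    SO_i = O_i − σ   if amplifying and O_i < 0
           O_i + σ   if amplifying and O_i ≥ 0
           O_i       otherwise

Everyone updates synchronously by bounded-confidence averaging over the
expressed opinions of in-neighbors within the confidence threshold ε of
their own opinion:

    O_i(t) = ( O_i(t−1) + Σ_{j ∈ I_i} SO_j ) / ( 1 + |I_i| ),
    I_i = { j → i : |O_i(t−1) − SO_j| ≤ ε }

With π = 0 on a complete graph this is exactly the Hegselmann–Krause
model. Population **conflict** is the standard deviation of actual
opinions, ΔO_t = SD(O_i,t); a fresh uniform population has
ΔO_0 = 1/√3 ≈ 0.577.

Two interventions are modeled: a **strike rule** (an agent may amplify
at most 5 times before being replaced by a fresh agent with a random
opinion) and **balanced dissemination** (5 uniform opinions on [−1, 1]
broadcast to everyone every other timestep, subject to the same
confidence gate).

## Worked example

Strong amplification (π = 0.5, p = 0.5, s = 0.5, ε = 0.8) with and
without the strike rule, same seed so both runs start from the
identical population:

```python
import numpy as np, soam

p = soam.ModelParams(n=100, k=5, epsilon=0.8, pi=0.5, p=0.5, s=0.5,
                     t_max=400, seed=1)
base  = soam.run(p)
cured = soam.run(p, interventions=soam.five_strike(5))
print("baseline   final conflict:", round(base.conflict[-1], 3),
      " max |opinion|:", round(np.abs(base.opinions).max(), 2))
print("five-strike final conflict:", round(cured.conflict[-1], 3),
      " max |opinion|:", round(np.abs(cured.opinions).max(), 2))
```

prints

```
baseline   final conflict: 2.847  max |opinion|: 20.11
five-strike final conflict: 0.001  max |opinion|: 1.09
```

Read: starting from conflict ≈ 0.577, unchecked amplification drives
opinions to twenty times the initial range (extreme polarization, high
conflict); capping every agent at five amplifications keeps the whole
population inside [−1.1, 1.1] and the run ends in consensus.

The command line mirrors the library — figure-style presets, YAML
configs, sweeps, and network generation:

```bash
soam run --preset fig2f --replicates 5 --out out/
soam sweep --config experiment.yaml --out out/
soam net --kind erdos_renyi --n 100 --k 5 --out net.edgelist
```

Trajectories and conflict series are written as long-format CSV, run
summaries as JSON.

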