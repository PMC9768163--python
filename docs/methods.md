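# Model and methods

## The model

`soam` simulates continuous opinion formation on a directed social
network. Each of `n` agents holds an *actual* opinion, initialized
i.i.d. uniform on [−1, 1] (−1 very negative on the topic, +1 very
positive) and unbounded afterwards. A fixed fraction `pi` of agents are
*amplifiers*. Each timestep:

1. **Amplification draws.** Every amplifier amplifies this timestep with
   probability `p`. An amplifying agent's *expressed* opinion is its
   actual opinion pushed away from zero by an amount drawn uniformly on
   `[0, s]` (negative opinions become more negative, nonnegative ones —
   including exactly 0 — more positive). Everyone else expresses their
   actual opinion. Amplification never changes the actual opinion
   directly; it only changes what others see.
2. **Confidence-gated averaging.** Agent *i* collects the expressed
   opinions of its in-neighbors *j* (edges *j → i*, "i follows j") whose
   expressed opinion lies within the confidence threshold `epsilon` of
   *i*'s own previous opinion (boundary inclusive), and replaces its
   opinion with the arithmetic mean of its own previous opinion and that
   set. An agent with an empty influence set keeps its opinion. The
   update is synchronous: one expressed-opinion vector computed from the
   previous timestep's opinions is used for both the gate and the
   average, for all agents at once.

With `pi = 0` on a complete graph the update is exactly the classic
Hegselmann–Krause bounded-confidence model (the agent's own opinion
always qualifies for its own average); the unit tests assert this
reduction against an independently coded oracle.

The headline phenomenon is *extreme polarization*: because expressed
opinions can exceed the actual ones, the population mean-of-neighbors
update can drag actual opinions outside the initial [−1, 1] hull —
impossible without amplification (a hull-containment property test
covers the `pi = 0` case).

## Networks

The default network is a directed Erdős–Rényi graph: every ordered pair
(i, j), i ≠ j, is an edge independently with probability `k/(n−1)`, so
expected in-degree and out-degree both equal `k`. The network is built
once per run and held fixed. No component filtering occurs; isolated
nodes and disconnected subgraphs participate as-is. A consequence worth
knowing: at `k = 5`, `n = 100` about 0.6 nodes per run have in-degree 0
and therefore never update. Those frozen agents put a floor of roughly
0.05 on the seed-averaged final conflict in otherwise-consensus regimes,
even though the majority of individual runs reach conflict 0 exactly.

`barabasi_albert` grows an undirected preferential-attachment graph with
attachment count `round(k/2)` and symmetrizes each edge into both
directions; `scale_free` symmetrizes a directed preferential-attachment
growth process. Both are provided for robustness experiments; no
published parameterization exists for them, so defaults are the
generators' standard ones. `symmetrized()` converts any network to its
undirected (bidirectional) variant.

## Conflict and other metrics

Conflict is the population standard deviation (denominator *n*) of the
*actual* opinions at a timestep. The population form is used so that the
infinite-population uniform[−1, 1] baseline is exactly 1/√3 ≈ 0.577.
Auxiliary metrics: opinion range, extremity fraction (share of agents
with |opinion| beyond a bound; bound 1 = outside the initial range), and
a descriptive cluster count (sort opinions, split at gaps larger than
0.1 — the gap default is our choice; the metric feeds no quantitative
claims).

## Interventions

**Strike rule** (`max_amplify`, default 5): each amplification attempt
counts as a strike. An agent already at the limit that draws another
amplification has it suppressed — it expresses its actual opinion that
timestep — and is replaced at the end of the timestep. Replacement keeps
the node and all its edges, redraws the opinion uniform on [−1, 1],
redraws amplifier status with the population default probability `pi`,
and resets strikes; population size is constant. The invariant "no agent
expresses more than `max_amplify` amplified opinions per lifetime" holds
literally. Alternatives we considered and rejected: letting the
over-limit amplification through before replacement (breaks the literal
lifetime bound), and inheriting the removed agent's amplifier flag
(the replacement is a *new* individual with default probabilities).

**Balanced dissemination**: at timesteps `period, 2·period, …` (default
period 2, i.e. every other timestep, starting after the run begins so
the initial state is untouched) the same `message_count` (default 5)
i.i.d. uniform draws on `[low, high]` (default [−1, 1]) are shown to all
agents. Each external opinion passes the same confidence gate against
the agent's own opinion and, when admitted, enters the average exactly
like a neighbor's expressed opinion (counted in the denominator).

## Randomness and reproducibility

One master seed drives four named substreams (network construction,
initial population, per-timestep amplification draws, interventions) via
`numpy` `SeedSequence` spawn keys. Per-timestep draws consume
fixed-shape arrays regardless of state, so enabling an intervention
reproduces the base run's dynamics draws bit-for-bit — paired
intervention/no-intervention comparisons share identical initial
populations and amplification histories up to the first intervention
effect. Two runs with the same parameters and seed are bit-identical.

## Experiment scale and observed behavior

All experiments run at the published scale, n = 100 agents for 400
timesteps; a single run takes ~70 ms on one core, so the 20-replicate
ensembles used throughout the tests and the acceptance script take a few
seconds. Replicate seeds are consecutive integers from a base seed.

Seed-ensemble behavior at the standard settings, as recomputed by the
test suite and `scripts/acceptance.py`:

* no amplifiers, ε = 0.8, k = 5: most seeds reach consensus (conflict
  exactly 0); the seed mean stays ≈ 0.05 because of the frozen
  in-degree-0 agents described above;
* no amplifiers, ε = 0.8, k = 2: conflict plateaus near 0.35
  (fragmented consensus on a very sparse graph);
* π = 0.2, p = 0.5, s = 0.2: conflict grows over the run to ≈ 1.1 at
  ε = 0.2 and ≈ 1.0 at ε = 0.5 — the distribution over seeds is
  bimodal (most runs polarize, a minority converge);
* π = 0.5, p = 0.5, s = 0.5, ε = 0.8: runaway polarization; |opinion|
  exceeds 2 in essentially every seed;
* the strike rule keeps the final opinion range inside [−1.5, 1.5] in
  20/20 seeds at both ε; dissemination is highly effective at ε = 0.8
  but only partially at ε = 0.2, where agents that drift beyond ε-reach
  of the [−1, 1] broadcasts can no longer be pulled back.

## What the generator does and does not emulate

All inputs are synthetic: random directed graphs and uniform initial
opinions. The simulator captures the *mechanism* of interest —
amplified expression under bounded confidence — but none of the texture
of real social platforms: no degree–activity correlation, no content or
topic structure, no agent heterogeneity in `epsilon`, no dynamic
(re-forming) networks, no external events. Passing tests therefore
validate the model's internal claims, not predictions about any real
network.

## Numerical notes

* The confidence gate is inclusive (`<= epsilon`), and an actual opinion
  of exactly 0 amplifies positively; both follow the model definition.
* Opinions are never clipped; float64 throughout. Runaway regimes reach
  |opinion| ~ 20 at t = 400, far from overflow.
* `round(pi * n)` amplifiers are assigned exactly (banker's rounding at
  .5), rather than per-agent Bernoulli, for reproducibility at small n.
* Degenerate inputs: `t_max = 0` returns only the initial state; `k = 0`
  yields an empty edge set (every agent frozen); empty influence sets
  leave opinions unchanged by construction.
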