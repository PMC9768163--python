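"""Core opinion-update engine.

The model is a bounded-confidence (Hegselmann–Krause style) process on a
directed network in which a fixed subset of agents are *amplifiers*: each
timestep, with probability ``p``, an amplifier publishes an expressed
opinion pushed away from zero by a uniform draw on ``[0, s]``, while its
actual opinion is unchanged. Every agent then averages its own previous
opinion with the expressed opinions of in-neighbors that lie within the
confidence threshold ``epsilon`` of its own opinion:

    O_i(t) = ( O_i(t-1) + sum_{j in I_i} SO_j ) / ( 1 + |I_i| )

where I_i = { j -> i : |O_i(t-1) - SO_j| <= epsilon }. A single expressed
vector, computed from the t-1 opinions, is used both for the confidence
gate and for the average (synchronous update). Actual opinions are never
clipped and may leave the initial [-1, 1] range.

With no amplifiers and a complete network the update reduces exactly to
the classic Hegselmann–Krause model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import conflict
from .networks import NETWORK_KINDS, DirectedNetwork, generate_network


@dataclass(frozen=True)
class ModelParams:
    """System-level parameters of one simulation run.

    Attributes
    ----------
    n : population size.
    k : mean links per node of the generated network.
    epsilon : confidence threshold in [0, 1]; an expressed opinion can
        influence an agent only if it lies within ``epsilon`` of the
        agent's own opinion.
    pi : proportion of the population who are amplifiers, in [0, 1].
    p : per-timestep probability that an amplifier amplifies, in [0, 1].
    s : amplification strength in [0, 1]; the amplified amount is drawn
        uniformly on [0, s] each time.
    t_max : number of timesteps to run.
    network_kind : one of "erdos_renyi", "barabasi_albert", "scale_free",
        "complete".
    seed : master seed; all randomness (network, initial opinions,
        per-step draws, interventions) derives from it.
    """

    n: int = 100
    k: float = 5.0
    epsilon: float = 0.8
    pi: float = 0.0
    p: float = 0.5
    s: float = 0.5
    t_max: int = 400
    network_kind: str = "erdos_renyi"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.k <= self.n):
            raise ValueError("k must be in [0, n]")
        for name in ("epsilon", "pi", "p", "s"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.network_kind not in NETWORK_KINDS:
            raise ValueError(f"unknown network kind {self.network_kind!r}")


@dataclass
class PopulationState:
    """Per-agent state at one timestep.

    ``opinions`` are the actual (internal) opinions, unbounded after t=0.
    ``is_amplifier`` is the fixed amplifier trait. ``strikes`` counts an
    agent's lifetime amplification events (reset on replacement).
    """

    opinions: np.ndarray
    is_amplifier: np.ndarray
    strikes: np.ndarray
    t: int = 0

    @property
    def n(self) -> int:
        return len(self.opinions)

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.opinions.copy(), self.is_amplifier.copy(), self.strikes.copy(), self.t
        )


@dataclass(frozen=True)
class StepDraws:
    """Per-timestep random draws: who amplifies now and by how much."""

    amplify_now: np.ndarray  # bool; implies is_amplifier
    sigma: np.ndarray  # in [0, s]; zero where not amplifying


@dataclass(frozen=True)
class RngStreams:
    """Named substreams spawned from one master seed.

    Keeping streams separate means enabling an intervention does not
    perturb the network, initialization, or per-step dynamics draws.
    """

    network: np.random.Generator
    init: np.random.Generator
    dynamics: np.random.Generator
    interventions: np.random.Generator
    network_seed: int


def make_streams(seed: int) -> RngStreams:
    def sub(label: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))

    return RngStreams(
        network=np.random.default_rng(sub("network")),
        init=np.random.default_rng(sub("init")),
        dynamics=np.random.default_rng(sub("dynamics")),
        interventions=np.random.default_rng(sub("interventions")),
        network_seed=int(sub("network").generate_state(1)[0] % 2**31),
    )


def init_population(params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Draw initial opinions i.i.d. uniform on [-1, 1] and assign exactly
    round(pi * n) amplifiers uniformly without replacement."""
    n = params.n
    opinions = rng.uniform(-1.0, 1.0, size=n)
    is_amplifier = np.zeros(n, dtype=bool)
    n_amp = int(round(params.pi * n))
    if n_amp > 0:
        is_amplifier[rng.choice(n, size=n_amp, replace=False)] = True
    return PopulationState(opinions, is_amplifier, np.zeros(n, dtype=np.int64), t=0)


def draw_step(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> StepDraws:
    """Fresh per-timestep draws.

    Each amplifier amplifies with probability ``p``; the amplified amount
    is uniform on [0, s]. Fixed-shape arrays are always consumed from the
    stream so the draw sequence does not depend on the current state.
    """
    n = state.n
    p_draw = rng.uniform(size=n)
    sigma_draw = rng.uniform(0.0, params.s, size=n)
    amplify_now = state.is_amplifier & (p_draw <= params.p)
    sigma = np.where(amplify_now, sigma_draw, 0.0)
    return StepDraws(amplify_now=amplify_now, sigma=sigma)


def expressed_opinions(state: PopulationState, draws: StepDraws) -> np.ndarray:
    """Expressed opinion vector: the actual opinion, pushed away from zero
    by sigma for agents amplifying this timestep (zero counts as
    nonnegative, so an agent at exactly 0 amplifies positively)."""
    o = state.opinions
    sign = np.where(o >= 0, 1.0, -1.0)
    return np.where(draws.amplify_now, o + sign * draws.sigma, o)


def influence_set(
    i: int,
    own_opinion: float,
    expressed: np.ndarray,
    net: DirectedNetwork,
    epsilon: float,
) -> set[int]:
    """In-neighbors of ``i`` whose expressed opinion is within ``epsilon``
    of ``own_opinion`` (boundary inclusive). Self is never included — the
    agent's own previous opinion enters the update separately."""
    return {
        j
        for j in net.in_neighbors(i)
        if abs(own_opinion - expressed[j]) <= epsilon
    }


def _advance(
    state: PopulationState,
    adjacency: np.ndarray,
    params: ModelParams,
    draws: StepDraws,
    externals: np.ndarray,
    strike_limit: int | None,
) -> tuple[PopulationState, np.ndarray]:
    """One synchronous update. Returns (new state, expressed-amplification
    mask). ``adjacency[j, i]`` is True iff j's expressed opinion is visible
    to i. When ``strike_limit`` is set, an agent already at the limit has
    its amplification suppressed (expresses its actual opinion) though the
    attempt still counts as a strike."""
    o = state.opinions
    attempted = draws.amplify_now
    if strike_limit is not None:
        expressed_mask = attempted & (state.strikes < strike_limit)
        eff = StepDraws(expressed_mask, np.where(expressed_mask, draws.sigma, 0.0))
    else:
        expressed_mask = attempted
        eff = draws
    so = expressed_opinions(state, eff)

    # gate[j, i]: |O_i - SO_j| <= eps and edge j -> i
    gate = adjacency & (np.abs(o[np.newaxis, :] - so[:, np.newaxis]) <= params.epsilon)
    sums = (so[:, np.newaxis] * gate).sum(axis=0)
    counts = gate.sum(axis=0)

    if externals.size:
        ext_gate = np.abs(o[np.newaxis, :] - externals[:, np.newaxis]) <= params.epsilon
        sums += (externals[:, np.newaxis] * ext_gate).sum(axis=0)
        counts = counts + ext_gate.sum(axis=0)

    new_opinions = (o + sums) / (1.0 + counts)
    new_state = PopulationState(
        opinions=new_opinions,
        is_amplifier=state.is_amplifier.copy(),
        strikes=state.strikes + attempted,
        t=state.t + 1,
    )
    return new_state, expressed_mask


def step(
    state: PopulationState,
    net: DirectedNetwork,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    externals: "list[float] | np.ndarray" = (),
    draws: StepDraws | None = None,
    strike_limit: int | None = None,
) -> PopulationState:
    """Advance the population by one timestep.

    Draws may be supplied explicitly (for testing against hand-computed
    values); otherwise they are taken from ``rng``.
    """
    if draws is None:
        if rng is None:
            raise ValueError("provide either rng or draws")
        draws = draw_step(state, params, rng)
    new_state, _ = _advance(
        state, net.adjacency(), params, draws, np.asarray(externals, dtype=float),
        strike_limit,
    )
    return new_state


@dataclass
class Trajectory:
    """Full record of one run.

    ``opinions`` has shape (t_max+1, n); row t holds the actual opinions
    after t updates. ``amplified`` and ``replaced`` mark, per timestep and
    agent, an expressed amplification and a replacement event (row 0 is
    all False). ``conflict`` is the population opinion SD per timestep.
    ``externals`` lists the broadcast opinions injected at each timestep
    (empty when dissemination is off).
    """

    params: ModelParams
    opinions: np.ndarray
    amplified: np.ndarray
    replaced: np.ndarray
    conflict: np.ndarray
    externals: list[np.ndarray] = field(default_factory=list)

    @property
    def t_max(self) -> int:
        return self.opinions.shape[0] - 1

    def to_long_dataframe(self):
        """Long-format (timestep, agent_id, opinion, amplified_flag,
        replaced_flag) table."""
        import pandas as pd

        t_max1, n = self.opinions.shape
        t_idx = np.repeat(np.arange(t_max1), n)
        a_idx = np.tile(np.arange(n), t_max1)
        return pd.DataFrame(
            {
                "timestep": t_idx,
                "agent_id": a_idx,
                "opinion": self.opinions.ravel(),
                "amplified_flag": self.amplified.ravel(),
                "replaced_flag": self.replaced.ravel(),
            }
        )

    def conflict_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"timestep": np.arange(len(self.conflict)), "conflict": self.conflict}
        )


def run(
    params: ModelParams,
    net: DirectedNetwork | None = None,
    interventions=None,
) -> Trajectory:
    """Run the full simulation, fully reproducible from ``params.seed``.

    ``interventions`` is an :class:`soam.interventions.InterventionConfig`
    or None. Balanced-opinion dissemination supplies external opinions
    before each step; the strike-rule replacement wave runs after each
    step.
    """
    from .interventions import apply_five_strike, external_opinions

    if net is not None and net.n_nodes != params.n:
        raise ValueError(
            f"network has {net.n_nodes} nodes but params.n={params.n}"
        )
    streams = make_streams(params.seed)
    if net is None:
        net = generate_network(
            params.network_kind, params.n, params.k, seed=streams.network_seed
        )
    adjacency = net.adjacency()
    state = init_population(params, streams.init)

    strike_limit = getattr(interventions, "max_amplify", None)
    dissemination = getattr(interventions, "dissemination", None)

    n = params.n
    opinions = np.empty((params.t_max + 1, n))
    amplified = np.zeros((params.t_max + 1, n), dtype=bool)
    replaced = np.zeros((params.t_max + 1, n), dtype=bool)
    conflict_series = np.empty(params.t_max + 1)
    externals_log: list[np.ndarray] = [np.empty(0)]
    opinions[0] = state.opinions
    conflict_series[0] = conflict(state.opinions)

    for t in range(1, params.t_max + 1):
        draws = draw_step(state, params, streams.dynamics)
        if dissemination is not None:
            ext = external_opinions(t, interventions, streams.interventions)
        else:
            ext = np.empty(0)
        state, expressed_mask = _advance(
            state, adjacency, params, draws, np.asarray(ext, dtype=float),
            strike_limit,
        )
        if strike_limit is not None:
            state, replaced_mask = apply_five_strike(
                state, params, interventions, streams.interventions
            )
            replaced[t] = replaced_mask
        opinions[t] = state.opinions
        amplified[t] = expressed_mask
        conflict_series[t] = conflict(state.opinions)
        externals_log.append(np.asarray(ext, dtype=float))

    return Trajectory(
        params=params,
        opinions=opinions,
        amplified=amplified,
        replaced=replaced,
        conflict=conflict_series,
        externals=externals_log,
    )
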