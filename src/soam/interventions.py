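"""Polarization-countering interventions.

Two mechanisms modeled after moderation practices on real platforms:

* **Strike rule** — an agent may amplify at most ``max_amplify`` times
  (default 5, echoing account-suspension policies); one further attempt
  is suppressed and the agent is replaced at the end of that timestep by
  a fresh agent with a random opinion on [-1, 1], keeping the population
  size and the network constant.
* **Balanced dissemination** — on a fixed schedule (default: 5 messages
  every other timestep) the same set of uniform draws on [-1, 1] is
  broadcast to every agent, subject to the usual confidence gating; this
  models institutions publishing opinions in the normal range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DisseminationConfig:
    message_count: int = 5
    period: int = 2
    low: float = -1.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.message_count < 0:
            raise ValueError("message_count must be >= 0")
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.low > self.high:
            raise ValueError("low must be <= high")


@dataclass(frozen=True)
class InterventionConfig:
    """Enable either or both countering mechanisms.

    ``max_amplify`` is None to disable the strike rule; ``dissemination``
    is None to disable broadcasting.
    """

    max_amplify: int | None = None
    dissemination: DisseminationConfig | None = None

    def __post_init__(self) -> None:
        if self.max_amplify is not None and self.max_amplify < 1:
            raise ValueError("max_amplify must be >= 1 when set")


def five_strike(max_amplify: int = 5) -> InterventionConfig:
    return InterventionConfig(max_amplify=max_amplify)


def balanced_dissemination(
    message_count: int = 5, period: int = 2, low: float = -1.0, high: float = 1.0
) -> InterventionConfig:
    return InterventionConfig(
        dissemination=DisseminationConfig(message_count, period, low, high)
    )


def external_opinions(
    t: int, cfg: InterventionConfig, rng: np.random.Generator
) -> np.ndarray:
    """External opinions broadcast at timestep ``t``.

    Non-empty only on the schedule t = period, 2*period, ...; every agent
    sees the same list that timestep. Values are i.i.d. uniform on
    [low, high].
    """
    d = cfg.dissemination
    if d is None:
        raise ValueError("dissemination is not enabled in this config")
    if t >= d.period and t % d.period == 0 and d.message_count > 0:
        return rng.uniform(d.low, d.high, size=d.message_count)
    return np.empty(0)


def apply_five_strike(state, params, cfg: InterventionConfig, rng: np.random.Generator):
    """Replace every agent whose strike count exceeds the limit.

    The replacement keeps the node id and all its network edges; the new
    agent gets a fresh uniform[-1, 1] opinion, amplifier status redrawn
    with the population default probability ``pi``, and zero strikes.
    Returns (new state, boolean mask of replaced agents). Population size
    is unchanged.
    """
    if cfg.max_amplify is None:
        raise ValueError("max_amplify is not enabled in this config")
    over = state.strikes > cfg.max_amplify
    if not over.any():
        return state, over
    new_state = state.copy()
    n_over = int(over.sum())
    new_state.opinions[over] = rng.uniform(-1.0, 1.0, size=n_over)
    new_state.is_amplifier[over] = rng.uniform(size=n_over) <= params.pi
    new_state.strikes[over] = 0
    return new_state, over
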