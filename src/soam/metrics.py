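"""Summary statistics of population opinion.

Conflict is the population standard deviation of actual opinions at a
timestep; for an infinite uniform[-1, 1] population it equals
1/sqrt(3) ~ 0.577, the natural reference level for a freshly initialized
run.
"""

from __future__ import annotations

import numpy as np


def conflict(opinions: np.ndarray) -> float:
    """Population standard deviation (denominator n) of actual opinions.

    Raises on an empty vector.
    """
    opinions = np.asarray(opinions, dtype=float)
    if opinions.size == 0:
        raise ValueError("conflict of an empty opinion vector is undefined")
    return float(np.std(opinions, ddof=0))


def opinion_range(opinions: np.ndarray) -> tuple[float, float]:
    """(min, max) of the opinion vector."""
    opinions = np.asarray(opinions, dtype=float)
    if opinions.size == 0:
        raise ValueError("range of an empty opinion vector is undefined")
    return float(opinions.min()), float(opinions.max())


def extremity_fraction(opinions: np.ndarray, bound: float) -> float:
    """Fraction of agents with |opinion| strictly beyond ``bound``.

    With bound=1 this is the fraction outside the initial opinion range.
    """
    if bound <= 0:
        raise ValueError("bound must be positive")
    opinions = np.asarray(opinions, dtype=float)
    if opinions.size == 0:
        return 0.0
    return float(np.mean(np.abs(opinions) > bound))


def count_clusters(opinions: np.ndarray, gap: float = 0.1) -> int:
    """Number of opinion clusters: sort and split where consecutive values
    differ by more than ``gap``. Permutation-invariant by construction."""
    if gap <= 0:
        raise ValueError("gap must be positive")
    opinions = np.asarray(opinions, dtype=float)
    if opinions.size == 0:
        return 0
    srt = np.sort(opinions)
    return int(1 + np.sum(np.diff(srt) > gap))


def summarize(trajectory) -> dict:
    """Per-run summary: final conflict, max |opinion| over the whole run,
    extremity fractions at bounds 1 and 2 (final timestep), cluster count,
    and the number of replacement events."""
    final = trajectory.opinions[-1]
    return {
        "final_conflict": float(trajectory.conflict[-1]),
        "max_abs_opinion": float(np.abs(trajectory.opinions).max()),
        "final_max_abs_opinion": float(np.abs(final).max()),
        "extremity_fraction_1": extremity_fraction(final, 1.0),
        "extremity_fraction_2": extremity_fraction(final, 2.0),
        "cluster_count": count_clusters(final),
        "replacement_count": int(trajectory.replaced.sum()),
    }
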