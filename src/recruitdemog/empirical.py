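"""Transition matrix estimated by direct counting of observed fates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .scheme import HeightRecord, SizeClassScheme, TransitionMatrix

__all__ = [
    "TransitionTally",
    "UnestimableClassError",
    "EmptyTallyWarning",
    "tally_transitions",
    "empirical_matrix",
]


class UnestimableClassError(ValueError):
    """A transient class has no at-risk observations."""


class EmptyTallyWarning(UserWarning):
    """No records survived the interval filter."""


@dataclass(frozen=True)
class TransitionTally:
    """Counts of observed per-step fates.

    ``counts[dest, source]`` counts survivors moving source -> dest,
    ``deaths[source]`` counts deaths, ``at_risk[source]`` the total
    observations starting in the class.  For each source column
    ``counts.sum(axis=0) + deaths == at_risk``.
    """

    scheme: SizeClassScheme
    counts: np.ndarray
    deaths: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        k = self.scheme.n_transient
        n = self.scheme.n_classes
        counts = np.asarray(self.counts, dtype=int)
        deaths = np.asarray(self.deaths, dtype=int)
        at_risk = np.asarray(self.at_risk, dtype=int)
        if counts.shape != (n, k):
            raise ValueError(f"counts must be {n}x{k}")
        if deaths.shape != (k,) or at_risk.shape != (k,):
            raise ValueError(f"deaths and at_risk must have length {k}")
        if (counts < 0).any() or (deaths < 0).any() or (at_risk < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.array_equal(counts.sum(axis=0) + deaths, at_risk):
            raise ValueError("per-source counts + deaths must equal at_risk")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "at_risk", at_risk)


def tally_transitions(
    records: Iterable[HeightRecord],
    scheme: SizeClassScheme,
    interval_filter_mo: float = 6,
) -> TransitionTally:
    """Count 6-month fate transitions.

    Only records whose interval length equals ``interval_filter_mo`` exactly
    contribute (census intervals are nominal months; there is no tolerance
    window).  Observations, not colonies, are the counting unit.  Records
    that start in the absorbing class are excluded.
    """
    k = scheme.n_transient
    counts = np.zeros((scheme.n_classes, k), dtype=int)
    deaths = np.zeros(k, dtype=int)
    used = 0
    for rec in records:
        if rec.interval_length_mo != interval_filter_mo:
            continue
        src = scheme.classify(rec.height_start_cm)
        if src == scheme.absorbing_index:
            continue
        used += 1
        if rec.died:
            deaths[src] += 1
        else:
            counts[scheme.classify(rec.height_end_cm), src] += 1
    if used == 0:
        warnings.warn(
            f"no records with interval_length_mo == {interval_filter_mo}; "
            "tally is empty",
            EmptyTallyWarning,
            stacklevel=2,
        )
    return TransitionTally(
        scheme=scheme,
        counts=counts,
        deaths=deaths,
        at_risk=counts.sum(axis=0) + deaths,
    )


def empirical_matrix(tally: TransitionTally,
                     step_length_y: float = 0.5) -> TransitionMatrix:
    """Transition probabilities as ratios of counted fates to at-risk totals.

    Raises
    ------
    UnestimableClassError
        If any transient class has no at-risk observations.
    """
    scheme = tally.scheme
    k = scheme.n_transient
    empty = [scheme.labels[j] for j in range(k) if tally.at_risk[j] == 0]
    if empty:
        raise UnestimableClassError(
            f"no observations at risk in class(es): {', '.join(empty)}"
        )
    n = scheme.n_classes
    entries = np.zeros((n, n))
    entries[:, :k] = tally.counts / tally.at_risk
    entries[scheme.absorbing_index, scheme.absorbing_index] = 1.0
    return TransitionMatrix(scheme=scheme, entries=entries,
                            step_length_y=step_length_y)
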