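"""Cohort projection, absorption statistics, and age-structured censuses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .scheme import TransitionMatrix

__all__ = [
    "PopulationState",
    "AgeStructuredState",
    "AbsorptionSummary",
    "project_cohort",
    "absorption_summary",
    "constant_settlement",
    "census_summaries",
    "compare_distributions",
]


@dataclass(frozen=True)
class PopulationState:
    """Abundance per class at one step index."""

    abundances: np.ndarray
    time: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundances, dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "abundances", arr)


@dataclass(frozen=True)
class AgeStructuredState:
    """Independent settlement cohorts observed at a common census time.

    Each entry pairs the cohort's settlement time (years) with its population
    state at the census.  The generating matrix is retained so census
    summaries can project forward (e.g., first-year escape fractions).
    """

    cohorts: tuple[tuple[float, PopulationState], ...]
    census_time_y: float
    matrix: TransitionMatrix | None = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.cohorts]
        if len(set(times)) != len(times):
            raise ValueError("cohort settlement times must be distinct")

    def ages_y(self) -> np.ndarray:
        return np.array([self.census_time_y - t for t, _ in self.cohorts])


@dataclass(frozen=True)
class AbsorptionSummary:
    """Per-step absorbed increments and derived absorption statistics.

    ``mean_time_y`` weights each step's newly absorbed *abundance*;
    ``living_weighted_mean_time_y`` weights each step's newly absorbed
    *share of the colonies then alive* (transient + absorbed).  The two
    differ because the living pool shrinks as the cohort dies off.
    """

    increments: np.ndarray
    cumulative_fraction: np.ndarray
    mean_time_y: float | None
    living_weighted_mean_time_y: float | None
    surviving_transient_fraction: float


def project_cohort(
    matrix: TransitionMatrix,
    n0: Sequence[float],
    steps: int,
) -> list[PopulationState]:
    """Iterate ``n_{t+1} = M n_t`` for ``steps`` steps; exact linear algebra."""
    n = np.asarray(n0, dtype=float)
    if n.shape != (matrix.scheme.n_classes,):
        raise ValueError(
            f"initial vector must have length {matrix.scheme.n_classes}, "
            f"got {n.shape}"
        )
    if steps < 0:
        raise ValueError("steps must be >= 0")
    out = [PopulationState(abundances=n.copy(), time=0)]
    for t in range(1, steps + 1):
        n = matrix.entries @ n
        out.append(PopulationState(abundances=n.copy(), time=t))
    return out


def absorption_summary(
    states: Sequence[PopulationState],
    horizon_steps: int | None = None,
) -> AbsorptionSummary:
    """Summarize absorption from a projected state sequence.

    The mean time to absorption is taken over steps ``1..horizon`` (default:
    the whole sequence) and is ``None`` when no mass is absorbed.
    """
    arr = np.array([s.abundances for s in states])
    total0 = arr[0].sum()
    if total0 <= 0:
        raise ValueError("initial cohort is empty")
    horizon = len(states) - 1 if horizon_steps is None else horizon_steps
    if horizon > len(states) - 1:
        raise ValueError("horizon exceeds the projected sequence")
    absorbed = arr[:, -1]
    transient = arr[:, :-1].sum(axis=1)
    inc = np.diff(absorbed)[:horizon]
    t = np.arange(1, horizon + 1)
    step_y = 0.5

    mean_time = None
    living_weighted = None
    if inc.sum() > 0:
        mean_time = float((t * step_y * inc).sum() / inc.sum())
        living = transient[1 : horizon + 1] + absorbed[1 : horizon + 1]
        w = np.divide(inc, living, out=np.zeros_like(inc), where=living > 0)
        if w.sum() > 0:
            living_weighted = float((t * step_y * w).sum() / w.sum())

    return AbsorptionSummary(
        increments=inc,
        cumulative_fraction=absorbed[: horizon + 1] / total0,
        mean_time_y=mean_time,
        living_weighted_mean_time_y=living_weighted,
        surviving_transient_fraction=float(transient[horizon] / total0),
    )


def constant_settlement(
    matrix: TransitionMatrix,
    settlers_per_event: float,
    event_interval_y: float,
    total_years: float,
    census_offset_y: float = 0.0,
) -> AgeStructuredState:
    """Settle repeated cohorts and census their joint state.

    Cohorts of ``settlers_per_event`` recruits enter the smallest class at
    ``t = 0, interval, 2*interval, ...`` strictly before ``total_years``;
    each is projected independently (the model is linear) to the census at
    ``total_years + census_offset_y``.
    """
    step_y = matrix.step_length_y
    ratio = event_interval_y / step_y
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("event interval must be a multiple of the step length")
    census = total_years + census_offset_y
    if census < 0:
        raise ValueError("census precedes the first settlement event")
    n0 = np.zeros(matrix.scheme.n_classes)
    n0[0] = settlers_per_event
    cohorts = []
    t_settle = 0.0
    while t_settle < total_years - 1e-9:
        steps = (census - t_settle) / step_y
        if steps < -1e-9:
            break
        steps_i = int(round(steps))
        if abs(steps - steps_i) > 1e-9:
            raise ValueError(
                f"census at {census} y is not a whole number of steps after "
                f"settlement at {t_settle} y"
            )
        state = project_cohort(matrix, n0, steps_i)[-1]
        cohorts.append((t_settle, state))
        t_settle += event_interval_y
    if not cohorts:
        raise ValueError("no settlement event precedes the census")
    return AgeStructuredState(
        cohorts=tuple(cohorts), census_time_y=census, matrix=matrix
    )


def census_summaries(
    state: AgeStructuredState,
    recruit_upper_bound_cm: float | None = None,
) -> dict:
    """Summaries of a multi-cohort census.

    Returns the transient size distribution, the abundance-weighted mean age
    of transient colonies, the fraction of transient colonies older than one
    year, and -- when ``recruit_upper_bound_cm`` is given -- the fraction of
    settlers exceeding that bound within one year, reported both as a
    fraction of the initial cohort and of its one-year survivors.
    """
    scheme = (state.matrix.scheme if state.matrix is not None
              else None)
    arr = np.array([s.abundances for _, s in state.cohorts])
    transient = arr[:, :-1]
    per_cohort = transient.sum(axis=1)
    total = per_cohort.sum()
    if total <= 0:
        raise ValueError("no transient colonies at the census")
    ages = state.ages_y()
    dist = transient.sum(axis=0) / total

    out = {
        "size_distribution": dist,
        "mean_age_y": float((ages * per_cohort).sum() / total),
        "fraction_older_than_1y": float(per_cohort[ages > 1 + 1e-9].sum() / total),
    }

    if recruit_upper_bound_cm is not None:
        if state.matrix is None:
            raise ValueError("state carries no matrix; cannot project settlers")
        uppers = scheme.upper_bounds
        matches = np.isclose(uppers, recruit_upper_bound_cm)
        if not matches.any():
            raise ValueError(
                f"bound {recruit_upper_bound_cm} cm is not a class boundary "
                f"(boundaries: {uppers.tolist()})"
            )
        j_bound = int(np.argmax(matches))
        steps_1y = int(round(1.0 / state.matrix.step_length_y))
        n0 = np.zeros(scheme.n_classes)
        n0[0] = 1.0
        n1 = project_cohort(state.matrix, n0, steps_1y)[-1].abundances
        above = n1[j_bound + 1 :].sum()
        alive = n1.sum()
        out["fraction_exceeding_bound_within_1y_of_settlers"] = float(above)
        out["fraction_exceeding_bound_within_1y_of_survivors"] = float(
            above / alive if alive > 0 else 0.0
        )
    return out


def compare_distributions(
    predicted_proportions: Sequence[float],
    observed_counts: Sequence[int],
) -> tuple[float, float]:
    """Pearson chi-square of observed counts against predicted proportions.

    Expected counts are ``total_observed * predicted``; returns the statistic
    and p-value.
    """
    pred = np.asarray(predicted_proportions, dtype=float)
    obs = np.asarray(observed_counts)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need >= 2 matching categories")
    if (obs < 0).any() or not np.issubdtype(obs.dtype, np.integer):
        raise ValueError("observed counts must be non-negative integers")
    if ((pred == 0) & (obs > 0)).any():
        raise ValueError("observed count in a category with zero predicted mass")
    if abs(pred.sum() - 1) > 1e-9:
        raise ValueError("predicted proportions must sum to 1")
    expected = obs.sum() * pred
    keep = pred > 0
    res = stats.chisquare(obs[keep], expected[keep])
    return float(res.statistic), float(res.pvalue)
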