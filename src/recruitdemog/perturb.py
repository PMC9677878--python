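"""Sensitivity and elasticity of absorption outcomes to model parameters.

Single-entry perturbations add probability mass to one transition without
renormalizing the rest of the column: the added mass is additional survival,
which is why even shrinkage entries can raise the escape proportion.
Uniform perturbations rescale survival, growth-rate medians, or the
probability of partial mortality across all classes and refit a straight
line through the outcomes (the slope plays the role of an elasticity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import ClassMix, GrowthModelParams, growth_matrix
from .projection import absorption_summary, project_cohort
from .scheme import TransitionMatrix

__all__ = [
    "PerturbationResult",
    "OUTCOMES",
    "outcome_value",
    "perturb_entry",
    "entry_sensitivity",
    "sensitivity_table",
    "uniform_perturbation_curve",
]

OUTCOMES = ("escape_proportion_5y", "mean_escape_time")
KNOBS = ("survival", "growth_rate", "partial_mortality")

#: Steps used for the "within 5 years" escape horizon (6-month steps).
ESCAPE_HORIZON_STEPS = 10


@dataclass(frozen=True)
class PerturbationResult:
    """Effect of one perturbation on one absorption outcome."""

    quantity: str
    outcome: str
    baseline_quantity: float
    baseline_outcome: float
    sensitivity: float
    elasticity: float | None


def outcome_value(
    matrix: TransitionMatrix,
    outcome: str,
    horizon_steps: int = ESCAPE_HORIZON_STEPS,
) -> float:
    """Evaluate an absorption outcome for a cohort of 100 smallest-class settlers.

    ``escape_proportion_5y`` is the percent of the cohort absorbed by the
    horizon; ``mean_escape_time`` the absorbed-increment-weighted mean years
    to absorption among those absorbed by the horizon.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; one of {OUTCOMES}")
    n0 = np.zeros(matrix.scheme.n_classes)
    n0[0] = 100.0
    states = project_cohort(matrix, n0, horizon_steps)
    if outcome == "escape_proportion_5y":
        return float(states[-1].abundances[-1])
    summ = absorption_summary(states, horizon_steps)
    if summ.mean_time_y is None:
        raise ValueError("no absorbed mass; mean escape time undefined")
    return summ.mean_time_y


def perturb_entry(
    matrix: TransitionMatrix, dest: int, source: int, delta: float
) -> TransitionMatrix:
    """Copy of ``matrix`` with ``delta`` added to one entry, no renormalization."""
    scheme = matrix.scheme
    if source >= scheme.n_transient:
        raise ValueError("source must be a transient class")
    if not 0 <= dest < scheme.n_classes:
        raise ValueError("dest out of range")
    entries = matrix.entries.copy()
    entries[dest, source] += delta
    colsum = entries[:, source].sum()
    if colsum > 1 + 1e-9:
        raise ValueError(
            f"perturbation pushes column {scheme.labels[source]!r} sum to "
            f"{colsum:.6g} > 1"
        )
    if entries[dest, source] < -1e-12:
        raise ValueError("perturbation makes the entry negative")
    return TransitionMatrix(scheme=scheme, entries=entries,
                            step_length_y=matrix.step_length_y)


def entry_sensitivity(
    matrix: TransitionMatrix,
    dest: int,
    source: int,
    outcome: str = "escape_proportion_5y",
    delta: float = 0.01,
    relative_delta: float = 0.01,
    horizon_steps: int = ESCAPE_HORIZON_STEPS,
) -> PerturbationResult:
    """Forward-difference sensitivity and elasticity of one matrix entry.

    Sensitivity uses an additive step ``delta``; elasticity a proportional
    step of ``relative_delta`` of the entry (undefined when the entry is 0).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    base_q = float(matrix.entries[dest, source])
    base_o = outcome_value(matrix, outcome, horizon_steps)
    pert_o = outcome_value(
        perturb_entry(matrix, dest, source, delta), outcome, horizon_steps
    )
    sensitivity = (pert_o - base_o) / delta

    elasticity = None
    if base_q > 0 and base_o != 0:
        d_rel = relative_delta * base_q
        o_rel = outcome_value(
            perturb_entry(matrix, dest, source, d_rel), outcome, horizon_steps
        )
        elasticity = ((o_rel - base_o) / base_o) / relative_delta

    labels = matrix.scheme.labels
    return PerturbationResult(
        quantity=f"p[{labels[dest]}, {labels[source]}]",
        outcome=outcome,
        baseline_quantity=base_q,
        baseline_outcome=base_o,
        sensitivity=float(sensitivity),
        elasticity=None if elasticity is None else float(elasticity),
    )


def sensitivity_table(
    matrix: TransitionMatrix,
    outcome: str = "escape_proportion_5y",
    delta: float = 0.01,
    horizon_steps: int = ESCAPE_HORIZON_STEPS,
) -> pd.DataFrame:
    """Long-format sensitivity/elasticity for every transient-source entry."""
    rows = []
    labels = matrix.scheme.labels
    for source in range(matrix.scheme.n_transient):
        for dest in range(matrix.scheme.n_classes):
            r = entry_sensitivity(
                matrix, dest, source, outcome, delta, horizon_steps=horizon_steps
            )
            rows.append(
                {
                    "dest": labels[dest],
                    "source": labels[source],
                    "entry": r.baseline_quantity,
                    "outcome": outcome,
                    "baseline": r.baseline_outcome,
                    "sensitivity": r.sensitivity,
                    "elasticity": r.elasticity,
                }
            )
    return pd.DataFrame(rows)


def _scaled_params(params: GrowthModelParams, knob: str, m: float) -> GrowthModelParams:
    if knob == "survival":
        surv = {}
        for label, s in params.survival.items():
            s2 = s * m
            if s2 > 1:
                raise ValueError(f"survival multiplier {m} makes s > 1 for {label!r}")
            surv[label] = s2
        return replace(params, survival=surv)
    if knob == "growth_rate":
        # scale both increment medians: shift log-normal log-means by log m
        shift = np.log(m)
        dists = {}
        for key, d in params.distributions.items():
            if d.family != "lognormal":
                raise ValueError("growth_rate knob requires lognormal fits")
            dists[key] = replace(d, params=(d.params[0] + shift, d.params[1]))
        return replace(params, distributions=dists)
    if knob == "partial_mortality":
        mix = {}
        for label, mx in params.mix.items():
            p_neg = mx.p_neg * m
            if p_neg > 1:
                raise ValueError(
                    f"partial-mortality multiplier {m} makes p_neg > 1 for {label!r}"
                )
            rest = mx.p_pos + mx.p_zero
            scale = (1 - p_neg) / rest if rest > 0 else 0.0
            mix[label] = ClassMix(mx.p_pos * scale, mx.p_zero * scale, p_neg)
        return replace(params, mix=mix)
    raise ValueError(f"unknown knob {knob!r}; one of {KNOBS}")


def uniform_perturbation_curve(
    params: GrowthModelParams,
    knob: str,
    multipliers: Sequence[float],
    outcome: str = "escape_proportion_5y",
    horizon_steps: int = ESCAPE_HORIZON_STEPS,
) -> dict:
    """Outcome curve over uniform multipliers of one global knob.

    Rebuilds the growth matrix per multiplier, evaluates the outcome, and
    fits an ordinary-least-squares line; the slope is the curve's elasticity
    analogue.
    """
    ms = np.asarray(multipliers, dtype=float)
    if ms.size < 2:
        raise ValueError("need at least two multipliers")
    values = []
    for m in ms:
        matrix = growth_matrix(_scaled_params(params, knob, float(m)))
        values.append(outcome_value(matrix, outcome, horizon_steps))
    values = np.array(values)
    slope, intercept = np.polyfit(ms, values, 1)
    return {
        "knob": knob,
        "outcome": outcome,
        "multipliers": ms,
        "values": values,
        "slope": float(slope),
        "intercept": float(intercept),
    }
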