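"""Packaged reference matrices and growth-model parameters.

``table1`` is the directly counted (empirical) transition matrix and
``table2`` the growth-rate-distribution matrix, both published at
three-decimal precision.  The reference growth parameters are a mixture /
log-normal configuration calibrated so that the assembled kernel matrix
reproduces ``table2`` closely; they serve as defaults for simulation and
uniform-perturbation analyses when raw field records are unavailable.
"""

from __future__ import annotations

import numpy as np

from .growth import ClassMix, FittedGrowthDistribution, GrowthModelParams
from .scheme import SizeClassScheme, TransitionMatrix, default_scheme

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "default_survival",
    "reference_growth_params",
]

_TABLE1 = np.array(
    [
        [0.198, 0.054, 0.011, 0.019, 0.0],
        [0.208, 0.240, 0.126, 0.077, 0.0],
        [0.050, 0.109, 0.161, 0.038, 0.0],
        [0.040, 0.098, 0.230, 0.442, 0.0],
        [0.000, 0.000, 0.000, 0.077, 1.0],
    ]
)

_TABLE2 = np.array(
    [
        [0.417, 0.072, 0.024, 0.031, 0.0],
        [0.095, 0.374, 0.099, 0.024, 0.0],
        [0.054, 0.084, 0.356, 0.059, 0.0],
        [0.019, 0.076, 0.146, 0.469, 0.0],
        [0.002, 0.016, 0.051, 0.207, 1.0],
    ]
)

FIXTURE_NAMES = ("table1", "table2")


def load_fixture(name: str, scheme: SizeClassScheme | None = None) -> TransitionMatrix:
    """Load a packaged transition matrix by name (``table1`` or ``table2``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURE_NAMES)}"
        )
    scheme = scheme or default_scheme()
    entries = _TABLE1 if name == "table1" else _TABLE2
    return TransitionMatrix(scheme=scheme, entries=entries.copy())


def default_survival(scheme: SizeClassScheme | None = None) -> dict[str, float]:
    """Per-step survival schedule: the growth-model fixture's column sums.

    The underlying proportional-hazards estimates are not published, so the
    fixture's column sums (0.587, 0.622, 0.676, 0.790) stand in for them.
    """
    scheme = scheme or default_scheme()
    sums = _TABLE2[:, : scheme.n_transient].sum(axis=0)
    return {scheme.labels[j]: float(round(sums[j], 3)) for j in range(scheme.n_transient)}


# Calibrated per class: (p_pos, p_zero, mu_pos, sigma_pos, mu_neg, sigma_neg).
# Log-normal parameters are on the log scale, increments in cm per step.
_REFERENCE_PARAMS = (
    (0.300721240010797, 0.6499999859137648,
     -0.5270344770178637, 0.8334719895892082,
     -0.18288700777384115, 0.3003215064611226),
    (0.30939416943987635, 0.05000001613096661,
     0.07445500998508914, 0.9728014752960124,
     -2.0504704524715756, 0.6912291383923859),
    (0.3781942403791423, 0.05,
     0.03827631674499665, 1.3999997159538293,
     -1.3449669392276418, 1.2314337269591331),
    (0.5756296071260762, 0.05,
     0.24298132379321258, 0.3000000000000006,
     0.2999999999999994, 1.4),
)


def reference_growth_params(scheme: SizeClassScheme | None = None) -> GrowthModelParams:
    """Reference growth-model parameters (mixtures + log-normal increments)."""
    scheme = scheme or default_scheme()
    if scheme.n_transient != len(_REFERENCE_PARAMS):
        raise ValueError("reference parameters cover exactly four transient classes")
    mix: dict[str, ClassMix] = {}
    dists: dict[tuple[str, str], FittedGrowthDistribution] = {}
    for j, (p_pos, p_zero, mu_p, sg_p, mu_n, sg_n) in enumerate(_REFERENCE_PARAMS):
        label = scheme.labels[j]
        mix[label] = ClassMix(p_pos, p_zero, 1.0 - p_pos - p_zero)
        dists[(label, "positive")] = FittedGrowthDistribution(
            size_class=label, sign="positive", family="lognormal",
            params=(mu_p, sg_p),
        )
        dists[(label, "negative")] = FittedGrowthDistribution(
            size_class=label, sign="negative", family="lognormal",
            params=(mu_n, sg_n),
        )
    return GrowthModelParams(
        scheme=scheme, mix=mix, distributions=dists,
        survival=default_survival(scheme),
    )
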