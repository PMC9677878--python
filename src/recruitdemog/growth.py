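"""Growth-rate-distribution transition model.

Surviving observations are partitioned into positive, zero, and negative
height changes.  Increment magnitudes are fitted to parametric families by
maximum likelihood, and per-class transition probabilities are assembled by
integrating class-boundary crossing probabilities over each class's
within-class height grid.

Conventions
-----------
* Increments are cm per step (the census interval); no annualization.
* A continuous height ``h`` belongs to class ``j`` when
  ``upper_{j-1} < h <= upper_j``; crossing the absorbing boundary means
  strictly exceeding the last transient upper bound.
* Negative-growth magnitudes are truncated at the current height and
  renormalized, so a surviving colony cannot shrink to zero or below;
  shrinkage past the first class's bounds lands in the first class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .scheme import HeightRecord, SizeClassScheme, TransitionMatrix

__all__ = [
    "ClassMix",
    "GrowthClassMix",
    "FittedGrowthDistribution",
    "SurvivalSchedule",
    "GrowthModelParams",
    "GrowthFitError",
    "GrowthConfigError",
    "partition_growth",
    "fit_increment_distribution",
    "crossing_probabilities",
    "growth_matrix",
]

FAMILIES = ("normal", "lognormal", "gamma", "weibull")


class GrowthFitError(ValueError):
    """Sample cannot be fitted (too small or degenerate)."""


class GrowthConfigError(ValueError):
    """Growth-model configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class ClassMix:
    """Probabilities of positive, zero, and negative growth in one class."""

    p_pos: float
    p_zero: float
    p_neg: float

    def __post_init__(self) -> None:
        for name, p in (("p_pos", self.p_pos), ("p_zero", self.p_zero),
                        ("p_neg", self.p_neg)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        if abs(self.p_pos + self.p_zero + self.p_neg - 1) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_pos, self.p_zero, self.p_neg)


#: Per-class growth-class mixture, keyed by transient class label.
GrowthClassMix = Mapping[str, ClassMix]

#: Per-class per-step survival probability, keyed by transient class label.
SurvivalSchedule = Mapping[str, float]


@dataclass(frozen=True)
class FittedGrowthDistribution:
    """A fitted increment-magnitude distribution for one class and sign.

    ``params`` are family parameters: ``(mu, sigma)`` on the log scale for
    ``lognormal``, ``(mean, sd)`` for ``normal``, ``(shape, scale)`` for
    ``gamma`` and ``weibull``.  ``gof_p`` is a one-sample KS p-value against
    the fitted distribution (conservative, since parameters are estimated
    from the same sample).
    """

    size_class: str
    sign: str  # "positive" | "negative"
    family: str
    params: tuple[float, ...]
    n_obs: int = 0
    gof_p: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        if self.family == "lognormal" and self.params[1] <= 0:
            raise ValueError("lognormal sigma must be positive")
        if self.family in ("gamma", "weibull") and (
            self.params[0] <= 0 or self.params[1] <= 0
        ):
            raise ValueError(f"{self.family} shape and scale must be positive")
        if self.family == "normal" and self.params[1] <= 0:
            raise ValueError("normal sd must be positive")

    def frozen(self):
        """The scipy frozen distribution for this fit."""
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm(sigma, scale=np.exp(mu))
        if self.family == "normal":
            return stats.norm(*self.params)
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma(shape, scale=scale)
        shape, scale = self.params
        return stats.weibull_min(shape, scale=scale)

    def cdf(self, x) -> np.ndarray:
        """CDF clipped to positive support (magnitudes are positive)."""
        x = np.asarray(x, dtype=float)
        if self.family == "lognormal":
            # fast path used heavily by the kernel
            mu, sigma = self.params
            out = np.zeros(x.shape)
            pos = x > 0
            out[pos] = ndtr((np.log(x[pos]) - mu) / sigma)
            return out
        out = self.frozen().cdf(np.maximum(x, 0.0))
        return np.where(x > 0, out, 0.0)

    def ppf(self, q) -> np.ndarray:
        return self.frozen().ppf(q)


def partition_growth(
    records: Iterable[HeightRecord],
    scheme: SizeClassScheme,
    interval_filter_mo: float | None = 6,
) -> tuple[dict[str, ClassMix], dict[tuple[str, str], np.ndarray]]:
    """Split surviving observations into growth classes per size class.

    Returns the per-class mixture proportions and the increment samples:
    positive increments under ``(label, "positive")`` and magnitudes of
    negative increments under ``(label, "negative")``.  Zero increments
    count toward ``p_zero`` but are excluded from the fitting samples.

    Raises
    ------
    GrowthConfigError
        If a transient class has no surviving observations.
    """
    k = scheme.n_transient
    pos: dict[int, list[float]] = {j: [] for j in range(k)}
    neg: dict[int, list[float]] = {j: [] for j in range(k)}
    zero = np.zeros(k, dtype=int)
    for rec in records:
        if interval_filter_mo is not None and rec.interval_length_mo != interval_filter_mo:
            continue
        if rec.died:
            continue
        src = scheme.classify(rec.height_start_cm)
        if src == scheme.absorbing_index:
            continue
        inc = rec.height_end_cm - rec.height_start_cm
        if inc > 0:
            pos[src].append(inc)
        elif inc < 0:
            neg[src].append(-inc)
        else:
            zero[src] += 1

    mix: dict[str, ClassMix] = {}
    samples: dict[tuple[str, str], np.ndarray] = {}
    missing = []
    for j in range(k):
        label = scheme.labels[j]
        n = len(pos[j]) + len(neg[j]) + int(zero[j])
        if n == 0:
            missing.append(label)
            continue
        mix[label] = ClassMix(len(pos[j]) / n, int(zero[j]) / n, len(neg[j]) / n)
        samples[(label, "positive")] = np.array(pos[j])
        samples[(label, "negative")] = np.array(neg[j])
    if missing:
        raise GrowthConfigError(
            f"no surviving observations in class(es): {', '.join(missing)}"
        )
    return mix, samples


def fit_increment_distribution(
    sample: np.ndarray,
    family: str = "lognormal",
    size_class: str = "",
    sign: str = "positive",
) -> FittedGrowthDistribution:
    """Maximum-likelihood fit of an increment-magnitude distribution.

    The goodness-of-fit p-value is a one-sample Kolmogorov-Smirnov test of
    the sample against the fitted distribution.  Because the parameters are
    estimated from the same sample the test is conservative; it is reported,
    not acted on.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 3:
        raise GrowthFitError(f"need at least 3 observations, got {sample.size}")
    if (sample <= 0).any():
        raise GrowthFitError("increment magnitudes must be positive")
    if np.ptp(sample) == 0:
        raise GrowthFitError("degenerate sample: zero variance")

    if family == "lognormal":
        logs = np.log(sample)
        mu = logs.mean()
        sigma = logs.std(ddof=0)  # MLE
        if sigma == 0:
            raise GrowthFitError("degenerate sample: zero log-variance")
        params: tuple[float, ...] = (mu, sigma)
    elif family == "normal":
        params = (sample.mean(), sample.std(ddof=0))
    elif family == "gamma":
        shape, _, scale = stats.gamma.fit(sample, floc=0)
        params = (shape, scale)
    elif family == "weibull":
        shape, _, scale = stats.weibull_min.fit(sample, floc=0)
        params = (shape, scale)
    else:
        raise ValueError(f"unknown family {family!r}; one of {FAMILIES}")

    fit = FittedGrowthDistribution(
        size_class=size_class, sign=sign, family=family,
        params=params, n_obs=int(sample.size),
    )
    gof = stats.kstest(sample, fit.frozen().cdf)
    return FittedGrowthDistribution(
        size_class=size_class, sign=sign, family=family,
        params=params, n_obs=int(sample.size), gof_p=float(gof.pvalue),
    )


def crossing_probabilities(
    height_cm: float,
    mix: ClassMix,
    dist_pos: FittedGrowthDistribution | None,
    dist_neg: FittedGrowthDistribution | None,
    scheme: SizeClassScheme,
) -> np.ndarray:
    """Destination probabilities for one height, conditional on survival.

    Positive growth crosses upper class boundaries according to the fitted
    increment CDF; zero growth stays; negative growth uses the magnitude
    distribution truncated at the current height.  The returned vector is a
    probability distribution over all classes (absorbing last).
    """
    j0 = scheme.classify(height_cm)
    if j0 == scheme.absorbing_index:
        raise ValueError(f"height {height_cm} is in the absorbing class")
    p_pos, p_zero, p_neg = mix.as_tuple()
    if p_pos > 0 and dist_pos is None:
        raise GrowthConfigError("positive-growth mass with no positive distribution")
    if p_neg > 0 and dist_neg is None:
        raise GrowthConfigError("negative-growth mass with no negative distribution")

    uppers = scheme.upper_bounds
    k = scheme.n_transient
    out = np.zeros(scheme.n_classes)
    out[j0] += p_zero

    if p_pos > 0:
        # increment G > 0; destination j >= j0 when U_{j-1} - h < G <= U_j - h
        cdf_at_uppers = dist_pos.cdf(uppers - height_cm)
        prev = 0.0
        for j in range(j0, k):
            out[j] += p_pos * (cdf_at_uppers[j] - prev)
            prev = cdf_at_uppers[j]
        out[k] += p_pos * (1.0 - cdf_at_uppers[-1])

    if p_neg > 0:
        if j0 == 0:
            # already in the smallest class: any surviving shrinkage stays
            out[0] += p_neg
        else:
            total = float(dist_neg.cdf(np.array([height_cm]))[0])
            if total <= 0:
                # truncation removes all mass; treat as no effective shrinkage
                out[j0] += p_neg
            else:
                def trunc_cdf(x: float) -> float:
                    x = min(max(x, 0.0), height_cm)
                    return float(dist_neg.cdf(np.array([x]))[0]) / total

                # stay: magnitude < h - U_{j0-1}
                out[j0] += p_neg * trunc_cdf(height_cm - uppers[j0 - 1])
                # intermediate lower classes j = 1..j0-1
                for j in range(1, j0):
                    out[j] += p_neg * (
                        trunc_cdf(height_cm - uppers[j - 1])
                        - trunc_cdf(height_cm - uppers[j])
                    )
                # smallest class absorbs everything at or below its upper bound
                out[0] += p_neg * (1.0 - trunc_cdf(height_cm - uppers[0]))

    return out


@dataclass(frozen=True)
class GrowthModelParams:
    """Everything needed to assemble a growth-model transition matrix."""

    scheme: SizeClassScheme
    mix: Mapping[str, ClassMix]
    distributions: Mapping[tuple[str, str], FittedGrowthDistribution]
    survival: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, s in self.survival.items():
            if not 0 <= s <= 1:
                raise ValueError(f"survival for {label!r} = {s} outside [0, 1]")

    def dist(self, label: str, sign: str) -> FittedGrowthDistribution | None:
        return self.distributions.get((label, sign))

    @classmethod
    def from_records(
        cls,
        records: Iterable[HeightRecord],
        scheme: SizeClassScheme,
        survival: Mapping[str, float],
        family: str = "lognormal",
        interval_filter_mo: float | None = 6,
    ) -> "GrowthModelParams":
        """Fit mixture and distributions from observation records."""
        mix, samples = partition_growth(records, scheme, interval_filter_mo)
        dists: dict[tuple[str, str], FittedGrowthDistribution] = {}
        for (label, sign), sample in samples.items():
            m = mix[label]
            mass = m.p_pos if sign == "positive" else m.p_neg
            if mass == 0:
                continue
            dists[(label, sign)] = fit_increment_distribution(
                sample, family=family, size_class=label, sign=sign
            )
        return cls(scheme=scheme, mix=mix, distributions=dists, survival=survival)


def growth_matrix(
    params: GrowthModelParams,
    grid_cm: float | None = None,
) -> TransitionMatrix:
    """Assemble the growth-model transition matrix.

    Each transient column is the survival probability times the mean of the
    crossing-probability vectors over the class's within-class height grid
    (both bounds inclusive, uniform weights), so column sums equal the
    survival schedule exactly.
    """
    scheme = params.scheme
    n = scheme.n_classes
    entries = np.zeros((n, n))
    entries[scheme.absorbing_index, scheme.absorbing_index] = 1.0
    for j in range(scheme.n_transient):
        label = scheme.labels[j]
        if label not in params.mix:
            raise GrowthConfigError(f"no growth mix for class {label!r}")
        if label not in params.survival:
            raise GrowthConfigError(f"no survival for class {label!r}")
        mix = params.mix[label]
        heights = scheme.grid_heights(j)
        if grid_cm is not None and grid_cm != scheme.resolution_cm:
            lo, hi = scheme.classes[j][1], scheme.classes[j][2]
            m = int(round((hi - lo) / grid_cm))
            heights = np.round(lo + grid_cm * np.arange(m + 1), 10)
        vectors = [
            crossing_probabilities(
                h, mix, params.dist(label, "positive"),
                params.dist(label, "negative"), scheme,
            )
            for h in heights
        ]
        col = np.mean(vectors, axis=0)
        col /= col.sum()  # remove float drift; exact conservation
        entries[:, j] = params.survival[label] * col
    return TransitionMatrix(scheme=scheme, entries=entries)
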