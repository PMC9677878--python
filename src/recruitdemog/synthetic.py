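"""Individual-based generator of recruit observation records.

Colonies carry a latent continuous height; each 6-month step they survive
with their current class's probability, draw a growth class from the class
mixture, and a magnitude from the class/sign distribution (negative growth
truncated at the current height).  Records report heights either rounded to
the measurement grid (``measurement="rounded"``, mirroring field
measurement -- latent changes smaller than half the grid register as zero
growth) or at full precision (``measurement="latent"``, for exact
distributional oracles).  Colonies whose latent height exceeds the absorbing
boundary emit a final record and leave the observed population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth import GrowthModelParams
from .scheme import HeightRecord

__all__ = ["SimulationConfig", "SimulationResult", "simulate_colonies",
           "simulate_escape_fraction"]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of an individual-based simulation.

    ``dynamics="latent"`` lets each colony keep its continuous height across
    steps (heights drift within classes, so multi-step aggregates deviate
    from the stage-structured matrix).  ``dynamics="stage"`` re-draws the
    height uniformly from the destination class's grid after every step,
    which is exactly the within-class assumption of the matrix model and
    therefore agrees with it at any horizon.
    """

    params: GrowthModelParams
    n_colonies: int = 1000
    n_steps: int = 6
    seed: int = 0
    initial_class_weights: tuple[float, ...] | None = None
    measurement: str = "rounded"  # "rounded" | "latent"
    dynamics: str = "latent"  # "latent" | "stage"

    def __post_init__(self) -> None:
        if self.n_colonies <= 0 or self.n_steps < 0:
            raise ValueError("n_colonies must be positive and n_steps >= 0")
        if self.measurement not in ("rounded", "latent"):
            raise ValueError("measurement must be 'rounded' or 'latent'")
        if self.dynamics not in ("latent", "stage"):
            raise ValueError("dynamics must be 'latent' or 'stage'")
        k = self.params.scheme.n_transient
        w = self.initial_class_weights
        if w is not None:
            w = tuple(float(x) for x in w)
            if len(w) != k or any(x < 0 for x in w) or sum(w) <= 0:
                raise ValueError(f"initial_class_weights must be {k} non-negative weights")
            object.__setattr__(self, "initial_class_weights", w)


@dataclass
class SimulationResult:
    """Records plus bookkeeping from one simulation run."""

    records: list[HeightRecord]
    seed: int
    absorbed_step: np.ndarray  # step of absorption per colony, -1 if never
    death_step: np.ndarray  # step of death per colony, -1 if never
    latent_mix_counts: dict[str, np.ndarray]  # label -> (pos, zero, neg)
    observed_mix_counts: dict[str, np.ndarray]

    def mix_proportions(self, which: str = "observed") -> dict[str, np.ndarray]:
        counts = (self.observed_mix_counts if which == "observed"
                  else self.latent_mix_counts)
        return {lab: c / c.sum() for lab, c in counts.items() if c.sum() > 0}


def _classify_vec(h: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    # class j when h <= U_j (continuous rule, with below-minimum in class 0)
    return np.searchsorted(uppers, h - 1e-9, side="left")


def _round_grid(h: np.ndarray, res: float) -> np.ndarray:
    # a living colony measures at least one grid unit
    return np.round(np.maximum(np.round(h / res), 1) * res, 10)


def _run(config: SimulationConfig, emit_records: bool = True) -> SimulationResult:
    params = config.params
    scheme = params.scheme
    k = scheme.n_transient
    uppers = scheme.upper_bounds
    boundary = uppers[-1]
    res = scheme.resolution_cm
    rng = np.random.default_rng(config.seed)

    surv = np.array([params.survival[scheme.labels[j]] for j in range(k)])
    mixes = [params.mix[scheme.labels[j]].as_tuple() for j in range(k)]
    p_pos = np.array([m[0] for m in mixes])
    p_zero = np.array([m[1] for m in mixes])
    dist_pos = [params.dist(scheme.labels[j], "positive") for j in range(k)]
    dist_neg = [params.dist(scheme.labels[j], "negative") for j in range(k)]

    n = config.n_colonies
    weights = (np.full(k, 1.0 / k) if config.initial_class_weights is None
               else np.array(config.initial_class_weights, float))
    weights = weights / weights.sum()
    init_class = rng.choice(k, size=n, p=weights)
    heights = np.empty(n)
    for j in range(k):
        grid = scheme.grid_heights(j)
        sel = init_class == j
        heights[sel] = rng.choice(grid, size=int(sel.sum()))

    alive = np.ones(n, dtype=bool)
    absorbed_step = np.full(n, -1, dtype=int)
    death_step = np.full(n, -1, dtype=int)
    latent_counts = {scheme.labels[j]: np.zeros(3, dtype=int) for j in range(k)}
    observed_counts = {scheme.labels[j]: np.zeros(3, dtype=int) for j in range(k)}
    records: list[HeightRecord] = []

    def observe(h: np.ndarray) -> np.ndarray:
        return _round_grid(h, res) if config.measurement == "rounded" else h

    for step in range(1, config.n_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        h = heights[idx]
        cls = np.clip(_classify_vec(h, uppers), 0, k - 1)

        u_surv = rng.random(idx.size)
        dies = u_surv >= surv[cls]

        u_mix = rng.random(idx.size)
        u_mag = rng.random(idx.size)
        new_h = h.copy()
        grew_pos = (~dies) & (u_mix < p_pos[cls])
        grew_neg = (~dies) & (u_mix >= p_pos[cls] + p_zero[cls])
        for j in range(k):
            sel = grew_pos & (cls == j)
            if sel.any():
                if dist_pos[j] is None:
                    raise ValueError(
                        f"positive growth drawn with no distribution for class "
                        f"{scheme.labels[j]!r}"
                    )
                new_h[sel] = h[sel] + dist_pos[j].ppf(u_mag[sel])
            sel = grew_neg & (cls == j)
            if sel.any():
                if dist_neg[j] is None:
                    raise ValueError(
                        f"negative growth drawn with no distribution for class "
                        f"{scheme.labels[j]!r}"
                    )
                cap = dist_neg[j].cdf(h[sel])
                new_h[sel] = h[sel] - dist_neg[j].ppf(u_mag[sel] * cap)

        obs_start = observe(h)
        obs_end = observe(new_h)
        surv_mask = ~dies
        lat_inc = np.sign(new_h - h)
        obs_inc = np.sign(obs_end - obs_start)
        for j in range(k):
            sel = surv_mask & (cls == j)
            latent_counts[scheme.labels[j]] += np.array([
                int((lat_inc[sel] > 0).sum()),
                int((lat_inc[sel] == 0).sum()),
                int((lat_inc[sel] < 0).sum()),
            ])
            observed_counts[scheme.labels[j]] += np.array([
                int((obs_inc[sel] > 0).sum()),
                int((obs_inc[sel] == 0).sum()),
                int((obs_inc[sel] < 0).sum()),
            ])

        if emit_records:
            for pos_in_idx, colony in enumerate(idx):
                end = None if dies[pos_in_idx] else float(obs_end[pos_in_idx])
                records.append(
                    HeightRecord(
                        colony_id=f"c{colony:06d}",
                        interval_index=step,
                        interval_length_mo=6,
                        height_start_cm=float(obs_start[pos_in_idx]),
                        height_end_cm=end,
                    )
                )

        death_step[idx[dies]] = step
        alive[idx[dies]] = False
        crossed = surv_mask & (new_h > boundary + 1e-12)
        absorbed_step[idx[crossed]] = step
        alive[idx[crossed]] = False  # absorbed colonies leave the observed pool

        if config.dynamics == "stage":
            # forget the within-class position: re-draw from the class grid
            still = surv_mask & ~crossed
            new_cls = np.clip(_classify_vec(new_h, uppers), 0, k - 1)
            for j in range(k):
                sel = still & (new_cls == j)
                if sel.any():
                    grid = scheme.grid_heights(j)
                    new_h[sel] = rng.choice(grid, size=int(sel.sum()))
        heights[idx] = new_h

    return SimulationResult(
        records=records,
        seed=config.seed,
        absorbed_step=absorbed_step,
        death_step=death_step,
        latent_mix_counts=latent_counts,
        observed_mix_counts=observed_counts,
    )


def simulate_colonies(config: SimulationConfig) -> list[HeightRecord]:
    """Generate one observation record per colony per step (see module docs)."""
    return _run(config).records


def simulate_escape_fraction(
    config: SimulationConfig,
    horizon_steps: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo fraction of colonies crossing the absorbing boundary.

    Returns the fraction absorbed by ``horizon_steps`` (default: all
    simulated steps) and its binomial standard error.
    """
    horizon = config.n_steps if horizon_steps is None else horizon_steps
    if horizon > config.n_steps:
        raise ValueError("horizon exceeds simulated steps")
    result = _run(config, emit_records=False)
    hit = (result.absorbed_step > 0) & (result.absorbed_step <= horizon)
    p = hit.mean()
    se = float(np.sqrt(p * (1 - p) / config.n_colonies))
    return float(p), se
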