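"""Size-class schemes, observation records, and stage transition matrices.

The state space is an ordered set of height classes on a fixed measurement
grid (default 0.1 cm), closed by a single absorbing class with an open upper
bound.  Transition matrices are column-substochastic: columns index the
source class, rows the destination class, and the column-sum deficit is the
per-step mortality of the source class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SizeClassScheme",
    "HeightRecord",
    "TransitionMatrix",
    "default_scheme",
    "classify_height",
    "validate_matrix",
    "class_survival",
    "DEAD",
]

#: Sentinel for a colony that died during an observation interval.
DEAD = "DEAD"

_GRID_ATOL = 1e-9


@dataclass(frozen=True)
class SizeClassScheme:
    """Ordered height classes with one absorbing final class.

    Parameters
    ----------
    classes
        Transient classes as ``(label, lower_cm, upper_cm)`` with closed
        bounds on the measurement grid, contiguous and strictly increasing.
    absorbing_label
        Label of the absorbing class (open upper bound, above the last
        transient class).
    resolution_cm
        Measurement grid spacing.
    """

    classes: tuple[tuple[str, float, float], ...]
    absorbing_label: str = ">5 cm"
    resolution_cm: float = 0.1

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("scheme needs at least one transient class")
        res = self.resolution_cm
        if res <= 0:
            raise ValueError("resolution_cm must be positive")
        prev_upper = None
        for label, lo, hi in self.classes:
            if lo <= 0 or hi <= 0:
                raise ValueError(f"class {label!r}: bounds must be positive")
            if hi <= lo:
                raise ValueError(f"class {label!r}: upper bound must exceed lower")
            for b in (lo, hi):
                if abs(b / res - round(b / res)) > _GRID_ATOL / res:
                    raise ValueError(
                        f"class {label!r}: bound {b} is not a multiple of {res}"
                    )
            if prev_upper is not None and abs(lo - (prev_upper + res)) > _GRID_ATOL:
                raise ValueError(
                    f"class {label!r}: lower bound {lo} does not follow the "
                    f"previous upper bound {prev_upper} at resolution {res}"
                )
            prev_upper = hi

    # -- derived views -------------------------------------------------

    @property
    def labels(self) -> list[str]:
        """All class labels, absorbing last."""
        return [c[0] for c in self.classes] + [self.absorbing_label]

    @property
    def n_classes(self) -> int:
        return len(self.classes) + 1

    @property
    def n_transient(self) -> int:
        return len(self.classes)

    @property
    def absorbing_index(self) -> int:
        return len(self.classes)

    @property
    def upper_bounds(self) -> np.ndarray:
        """Upper bounds of the transient classes (class partition points)."""
        return np.array([c[2] for c in self.classes])

    def grid_heights(self, class_index: int) -> np.ndarray:
        """Nominal grid heights of a transient class, both bounds inclusive."""
        label, lo, hi = self.classes[class_index]
        n = int(round((hi - lo) / self.resolution_cm)) + 1
        return np.round(lo + self.resolution_cm * np.arange(n), 10)

    # -- classification ------------------------------------------------

    def classify(self, height_cm: float) -> int:
        """Class index for a height.

        Grid heights fall in the closed nominal intervals; intermediate
        (continuous) heights use the partition ``(upper_{j-1}, upper_j]``.
        Heights below the first lower bound stay in the first class (partial
        mortality can shrink a colony below the nominal minimum; death is
        handled by survival, not classification).  Heights strictly above the
        last transient upper bound are absorbing.
        """
        if not np.isfinite(height_cm) or height_cm <= 0:
            raise ValueError(f"height must be positive and finite, got {height_cm}")
        uppers = self.upper_bounds
        for j, up in enumerate(uppers):
            if height_cm <= up + _GRID_ATOL:
                return j
        return self.absorbing_index

    def label_of(self, height_cm: float) -> str:
        return self.labels[self.classify(height_cm)]


def default_scheme() -> SizeClassScheme:
    """The four recruit height classes with a >5 cm absorbing class."""
    return SizeClassScheme(
        classes=(
            ("0.3-0.5", 0.3, 0.5),
            ("0.6-1.1", 0.6, 1.1),
            ("1.2-2.0", 1.2, 2.0),
            ("2.1-5.0", 2.1, 5.0),
        ),
        absorbing_label=">5 cm",
        resolution_cm=0.1,
    )


def classify_height(height_cm: float, scheme: SizeClassScheme) -> str:
    """Label of the class containing ``height_cm`` (see ``SizeClassScheme.classify``)."""
    return scheme.label_of(height_cm)


@dataclass(frozen=True)
class HeightRecord:
    """One observation interval for one colony.

    ``height_end_cm`` is ``None`` when the colony died during the interval.
    """

    colony_id: str
    interval_index: int
    interval_length_mo: float
    height_start_cm: float
    height_end_cm: float | None

    def __post_init__(self) -> None:
        if self.interval_length_mo <= 0:
            raise ValueError("interval_length_mo must be positive")
        if self.height_start_cm <= 0:
            raise ValueError("height_start_cm must be positive")
        if self.height_end_cm is not None and self.height_end_cm <= 0:
            raise ValueError("height_end_cm must be positive or None (dead)")

    @property
    def died(self) -> bool:
        return self.height_end_cm is None


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-substochastic stage matrix over a size-class scheme.

    ``entries[dest, source]`` is the probability, per step of
    ``step_length_y`` years, that a colony in ``source`` survives and ends
    the step in ``dest``.
    """

    scheme: SizeClassScheme
    entries: np.ndarray
    step_length_y: float = 0.5

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        n = self.scheme.n_classes
        if arr.shape != (n, n):
            raise ValueError(f"entries must be {n}x{n}, got {arr.shape}")
        object.__setattr__(self, "entries", arr)

    @property
    def transient_block(self) -> np.ndarray:
        k = self.scheme.n_transient
        return self.entries[:k, :k]

    def column_sums(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        labels = self.scheme.labels
        return pd.DataFrame(self.entries, index=labels, columns=labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.15g")

    @classmethod
    def from_csv(cls, path, scheme: SizeClassScheme,
                 step_length_y: float = 0.5) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = scheme.labels
        df = df.loc[labels, labels]
        return cls(scheme=scheme, entries=df.to_numpy(float),
                   step_length_y=step_length_y)

    def to_dict(self) -> dict:
        return {
            "scheme": {
                "classes": [list(c) for c in self.scheme.classes],
                "absorbing_label": self.scheme.absorbing_label,
                "resolution_cm": self.scheme.resolution_cm,
            },
            "step_length_y": self.step_length_y,
            "labels": self.scheme.labels,
            "entries": self.entries.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionMatrix":
        scheme = SizeClassScheme(
            classes=tuple(tuple(c) for c in d["scheme"]["classes"]),
            absorbing_label=d["scheme"]["absorbing_label"],
            resolution_cm=d["scheme"]["resolution_cm"],
        )
        return cls(scheme=scheme, entries=np.array(d["entries"], float),
                   step_length_y=d.get("step_length_y", 0.5))

    @classmethod
    def from_json(cls, path) -> "TransitionMatrix":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def validate_matrix(matrix: TransitionMatrix, atol: float = 1e-9) -> list[str]:
    """Check all transition-matrix invariants; return human-readable violations.

    An empty list means the matrix is valid.  This is a reporting operation:
    it never raises.
    """
    violations: list[str] = []
    m = matrix.entries
    labels = matrix.scheme.labels
    a = matrix.scheme.absorbing_index

    rows, cols = np.where((m < -atol) | (m > 1 + atol))
    for i, j in zip(rows, cols):
        violations.append(
            f"entry [{labels[i]}, {labels[j]}] = {m[i, j]:.6g} outside [0, 1]"
        )
    for j, s in enumerate(m.sum(axis=0)[:a]):
        if s > 1 + atol:
            violations.append(
                f"column {labels[j]!r} sums to {s:.6g} > 1 (probability leak)"
            )
    # absorbing column must be the identity column
    col = m[:, a]
    expected = np.zeros(matrix.scheme.n_classes)
    expected[a] = 1.0
    if not np.allclose(col, expected, atol=atol):
        violations.append(
            f"absorbing column {labels[a]!r} is not (0,...,0,1): {col.tolist()}"
        )
    return violations


def class_survival(matrix: TransitionMatrix) -> np.ndarray:
    """Per-step survival of each transient class (transient column sums)."""
    bad = validate_matrix(matrix)
    if bad:
        raise ValueError("invalid matrix: " + "; ".join(bad))
    k = matrix.scheme.n_transient
    return matrix.entries[:, :k].sum(axis=0)
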