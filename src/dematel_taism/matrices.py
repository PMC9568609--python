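"""Matrix containers shared across the DEMATEL and structural stages.

Each container pairs a :class:`~dematel_taism.factors.FactorSystem` with a
square numpy array indexed by the system's factor order and validates the
stage-specific invariants at construction time.  The raw array is always
available as ``.values``; ``.to_frame()`` gives a labelled pandas view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .factors import FactorSystem

__all__ = [
    "ExpertScoreTable",
    "DirectInfluenceMatrix",
    "NormalizedInfluenceMatrix",
    "TotalInfluenceMatrix",
]

SCORE_MAX = 4  # expert scale: 0 none .. 4 very strong


def _as_square(system: FactorSystem, values, dtype) -> np.ndarray:
    arr = np.asarray(values, dtype=dtype)
    if arr.shape != (system.n, system.n):
        raise ValidationError(
            f"expected a {system.n}x{system.n} matrix, got shape {arr.shape}"
        )
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class ExpertScoreTable:
    """One expert's 0-4 pairwise influence scores, zero on the diagonal."""

    expert_id: str
    system: FactorSystem
    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_square(self.system, self.scores, np.int64)
        if arr.min() < 0 or arr.max() > SCORE_MAX:
            raise ValidationError(
                f"expert {self.expert_id!r}: scores must lie in 0..{SCORE_MAX}"
            )
        if np.any(np.diag(arr) != 0):
            raise ValidationError(f"expert {self.expert_id!r}: diagonal must be 0")
        object.__setattr__(self, "scores", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.system.codes, columns=self.system.codes)


@dataclass(frozen=True)
class DirectInfluenceMatrix:
    """Aggregated direct-influence scores O: nonnegative integers, zero diagonal."""

    system: FactorSystem
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_square(self.system, self.values, np.int64)
        if arr.min() < 0:
            raise ValidationError("direct influence entries must be nonnegative")
        if np.any(np.diag(arr) != 0):
            raise ValidationError("direct influence matrix must have a zero diagonal")
        object.__setattr__(self, "values", arr)

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.system.codes, columns=self.system.codes)


@dataclass(frozen=True)
class NormalizedInfluenceMatrix:
    """Normalized direct influence N = O / max_i sqrt(rowsum_i^2 + colsum_i^2).

    ``row_sums``/``col_sums`` are those of the source O, kept so the
    normalizing denominator can be audited after the fact.
    """

    system: FactorSystem
    values: np.ndarray
    denominator: float
    row_sums: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_sums: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = _as_square(self.system, self.values, np.float64)
        if self.denominator <= 0:
            raise ValidationError("normalization denominator must be positive")
        if arr.min() < 0 or arr.max() > 1 + 1e-12:
            raise ValidationError("normalized entries must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.system.codes, columns=self.system.codes)


@dataclass(frozen=True)
class TotalInfluenceMatrix:
    """Total (direct + indirect) influence T = N (I - N)^-1."""

    system: FactorSystem
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_square(self.system, self.values, np.float64)
        object.__setattr__(self, "values", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.system.codes, columns=self.system.codes)
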