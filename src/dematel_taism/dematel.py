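"""DEMATEL stage: aggregation, normalization, total influence, centrality.

The method turns aggregated pairwise direct-influence scores O into a
total influence matrix

    T = N (I - N)^-1 = N + N^2 + N^3 + ...,

where N is O scaled by the largest Euclidean norm of any factor's
(row sum, column sum) pair.  That scaling keeps the spectral radius of N
below 1 in practice so the Neumann series converges, and T then captures
direct plus all orders of mediated influence.  Per-factor row and column
sums of T give the influence degree D_i (how strongly i drives the
system) and influenced degree C_i (how strongly it is driven); their sum
M_i = D_i + C_i is the factor's centrality/prominence, their difference
Rc_i = D_i - C_i its cause degree (net driver when positive, net receiver
when negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError, NormalizationError, ValidationError
from .factors import FactorSystem
from .matrices import (
    DirectInfluenceMatrix,
    ExpertScoreTable,
    NormalizedInfluenceMatrix,
    TotalInfluenceMatrix,
)

__all__ = [
    "aggregate_expert_scores",
    "normalize_direct_matrix",
    "compute_total_influence",
    "compute_centrality",
    "CentralityTable",
]


def aggregate_expert_scores(tables: Sequence[ExpertScoreTable]) -> DirectInfluenceMatrix:
    """Elementwise sum of per-expert 0-4 score tables over one factor system."""
    if not tables:
        raise ValidationError("need at least one expert score table")
    system = tables[0].system
    for t in tables[1:]:
        if t.system != system:
            raise ValidationError(
                f"expert {t.expert_id!r} scores a different factor system"
            )
    total = np.sum([t.scores for t in tables], axis=0)
    return DirectInfluenceMatrix(system, total)


def normalize_direct_matrix(O: DirectInfluenceMatrix) -> NormalizedInfluenceMatrix:
    """Scale O by max_i sqrt(rowsum_i^2 + colsum_i^2).

    The denominator is the largest Euclidean norm, over factors, of the
    (row sum, column sum) pair of O — a row-sum-maximum style scaling that
    bounds every entry by 1.
    """
    values = O.values.astype(float)
    if not values.any():
        raise NormalizationError(
            "cannot normalize an all-zero direct influence matrix: "
            "every factor pair was scored 0"
        )
    row = values.sum(axis=1)
    col = values.sum(axis=0)
    denominator = float(np.sqrt(row**2 + col**2).max())
    return NormalizedInfluenceMatrix(
        O.system, values / denominator, denominator, row_sums=row, col_sums=col
    )


def compute_total_influence(N: NormalizedInfluenceMatrix) -> TotalInfluenceMatrix:
    """Closed-form Neumann sum T = N (I - N)^-1.

    Refuses to return a matrix when the spectral radius of N is >= 1,
    in which case the series N + N^2 + ... has no limit.
    """
    radius = float(np.abs(np.linalg.eigvals(N.values)).max())
    if radius >= 1.0:
        raise DivergenceError(
            f"total influence series diverges: spectral radius {radius:.6f} >= 1"
        )
    eye = np.eye(N.system.n)
    T = N.values @ np.linalg.inv(eye - N.values)
    return TotalInfluenceMatrix(N.system, T)


@dataclass(frozen=True)
class CentralityTable:
    """Per-factor influence statistics derived from T.

    ``D`` influence degree (row sums of T), ``C`` influenced degree
    (column sums), ``M = D + C`` centrality, ``Rc = D - C`` cause degree.
    """

    system: FactorSystem
    D: np.ndarray
    C: np.ndarray

    @property
    def M(self) -> np.ndarray:
        return self.D + self.C

    @property
    def Rc(self) -> np.ndarray:
        return self.D - self.C

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"D": self.D, "C": self.C, "M": self.M, "Rc": self.Rc},
            index=self.system.codes,
        )

    def scatter_points(self) -> list[tuple[str, float, float]]:
        """(code, centrality, cause degree) triples for the cause-effect scatter."""
        return [
            (code, float(m), float(r))
            for code, m, r in zip(self.system.codes, self.M, self.Rc)
        ]


def compute_centrality(T: TotalInfluenceMatrix) -> CentralityTable:
    """Influence/influenced degrees and the derived centrality and cause degrees."""
    return CentralityTable(T.system, D=T.values.sum(axis=1), C=T.values.sum(axis=0))
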