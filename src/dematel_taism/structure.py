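"""TAISM graph stage: intercept, adjacency, reachability, loops, skeleton.

The total influence matrix T is cut at the intercept

    lambda = mean(T) + sd(T)

(mean and *population* standard deviation over all n^2 entries, diagonal
included) to give a Boolean adjacency A.  Boolean powers of B = A + I
stabilize within n steps at the reachability matrix R.  Mutually reachable
factors (R_ij = R_ji = 1) form loops (strongly connected components); the
condensation of R over those components is a partial order R', whose
transitive reduction

    S' = R' - (R' - I)^2 - I        (Boolean arithmetic)

keeps exactly the covering edges.  Re-expanding loops back onto the
original factors yields the general skeleton S, which carries either the
t_ij influence values (matrix TS) or, for edges inside a loop, the marker
value 1 (matrix WS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructureError
from .factors import FactorSystem
from .matrices import TotalInfluenceMatrix, _as_square

__all__ = [
    "InfluenceThreshold",
    "AdjacencyMatrix",
    "ReachabilityStructure",
    "SkeletonMatrix",
    "ValuedSkeleton",
    "compute_threshold",
    "binarize",
    "compute_reachability",
    "compute_skeleton",
    "build_valued_skeleton",
]


@dataclass(frozen=True)
class InfluenceThreshold:
    """Intercept lambda = mean + population sd of all n^2 entries of T."""

    mean: float
    sd: float
    n: int

    @property
    def lam(self) -> float:
        return self.mean + self.sd


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Boolean direct-relation matrix: A_ij = 1 iff t_ij > lambda."""

    system: FactorSystem
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        arr = _as_square(self.system, arr.astype(np.int8), np.int8)
        if not np.isin(arr, (0, 1)).all():
            raise StructureError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "values", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.system.codes, columns=self.system.codes)


def compute_threshold(T: TotalInfluenceMatrix) -> InfluenceThreshold:
    """Mean and population standard deviation (divisor n^2) of T's entries."""
    flat = T.values.ravel()
    mean = float(flat.mean())
    sd = float(np.sqrt(((flat - mean) ** 2).sum() / flat.size))
    return InfluenceThreshold(mean=mean, sd=sd, n=T.system.n)


def binarize(T: TotalInfluenceMatrix, threshold: InfluenceThreshold | float) -> AdjacencyMatrix:
    """Cut T at the intercept: strictly greater entries become edges."""
    lam = threshold.lam if isinstance(threshold, InfluenceThreshold) else float(threshold)
    return AdjacencyMatrix(T.system, (T.values > lam).astype(np.int8))


def _bool_closure(B: np.ndarray, limit: int) -> np.ndarray:
    """Boolean powers of B until stable; asserts stabilization within `limit` steps."""
    R = B.astype(bool)
    for _ in range(limit):
        R2 = R | (R @ R)
        if np.array_equal(R2, R):
            return R
        R = R2
    raise StructureError("Boolean power iteration failed to stabilize within n steps")


@dataclass(frozen=True)
class ReachabilityStructure:
    """Reachability matrix R, its loops (SCCs), and the condensed partial order.

    ``components`` are the strongly connected classes of R (mutual
    reachability), each a tuple of codes in factor order, components
    ordered by their first member.  ``R_condensed`` is reachability on
    components and is checked to be a partial order.  The adjacency the
    structure was built from is retained for skeleton re-expansion.
    """

    system: FactorSystem
    R: np.ndarray
    components: tuple[tuple[str, ...], ...]
    R_condensed: np.ndarray
    adjacency: AdjacencyMatrix

    @property
    def component_index(self) -> dict[str, int]:
        return {code: k for k, comp in enumerate(self.components) for code in comp}

    @property
    def loops(self) -> tuple[tuple[str, ...], ...]:
        """Components of size >= 2 (the loops of the system)."""
        return tuple(c for c in self.components if len(c) >= 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.R.astype(int), index=self.system.codes, columns=self.system.codes
        )


def compute_reachability(A: AdjacencyMatrix) -> ReachabilityStructure:
    """Stable Boolean power of (A + I), loop classes, and their condensation."""
    n = A.system.n
    B = (A.values.astype(bool)) | np.eye(n, dtype=bool)
    R = _bool_closure(B, n + 1)

    mutual = R & R.T
    seen: set[int] = set()
    comps: list[tuple[int, ...]] = []
    for i in range(n):
        if i in seen:
            continue
        members = tuple(j for j in range(n) if mutual[i, j])
        seen.update(members)
        comps.append(members)
    comps.sort(key=lambda c: c[0])
    codes = A.system.codes
    components = tuple(tuple(codes[j] for j in c) for c in comps)

    reps = [c[0] for c in comps]
    Rc = R[np.ix_(reps, reps)]
    asym = Rc & Rc.T & ~np.eye(len(reps), dtype=bool)
    if asym.any():
        raise StructureError("condensed reachability is not antisymmetric")
    return ReachabilityStructure(
        system=A.system, R=R, components=components, R_condensed=Rc, adjacency=A
    )


@dataclass(frozen=True)
class SkeletonMatrix:
    """Transitive reduction S' on components and its loop re-expansion S on factors."""

    system: FactorSystem
    S_condensed: np.ndarray
    S_general: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.S_general.astype(int), index=self.system.codes, columns=self.system.codes
        )


def compute_skeleton(rs: ReachabilityStructure) -> SkeletonMatrix:
    """Edge reduction S' = R' - (R' - I)^2 - I, then loop re-expansion.

    The subtraction is Boolean and-not and the square a Boolean matrix
    product, so S' keeps an edge u -> v exactly when no third component
    lies strictly between u and v: repeated (transitively implied) paths
    are deleted.  Re-expansion onto the original factors (i) threads each
    loop as one directed cycle through its members in factor order and
    (ii) realizes every condensed edge by the adjacency edge between
    member factors with the lexicographically smallest (source index,
    target index) pair.
    """
    Rc = rs.R_condensed
    m = Rc.shape[0]
    eye = np.eye(m, dtype=bool)
    strict = Rc & ~eye
    Sc = Rc & ~(strict @ strict) & ~eye

    n = rs.system.n
    idx = {c: i for i, c in enumerate(rs.system.codes)}
    members = [tuple(idx[c] for c in comp) for comp in rs.components]
    A = rs.adjacency.values
    S = np.zeros((n, n), dtype=bool)

    for comp in members:
        if len(comp) >= 2:  # one cycle through the loop, in factor order
            for a, b in zip(comp, comp[1:] + comp[:1]):
                S[a, b] = True

    for u in range(m):
        for v in range(m):
            if u == v or not Sc[u, v]:
                continue
            pairs = [(i, j) for i in members[u] for j in members[v] if A[i, j]]
            if not pairs:
                raise StructureError(
                    "no adjacency edge realizes condensed skeleton edge "
                    f"{rs.components[u]} -> {rs.components[v]}"
                )
            i, j = min(pairs)
            S[i, j] = True

    return SkeletonMatrix(system=rs.system, S_condensed=Sc, S_general=S)


@dataclass(frozen=True)
class ValuedSkeleton:
    """Skeleton edges carrying influence values.

    ``TS`` places t_ij on every general-skeleton edge; ``WS`` is TS with
    every ordered pair inside a loop set to the marker value 1 (the full
    clique of the loop, not only its cycle edges).
    """

    system: FactorSystem
    TS: np.ndarray
    WS: np.ndarray

    def to_frame(self, which: str = "TS") -> pd.DataFrame:
        arr = self.TS if which == "TS" else self.WS
        return pd.DataFrame(arr, index=self.system.codes, columns=self.system.codes)


def build_valued_skeleton(
    T: TotalInfluenceMatrix, sk: SkeletonMatrix, rs: ReachabilityStructure
) -> ValuedSkeleton:
    if not (T.system == sk.system == rs.system):
        raise StructureError("valued skeleton inputs must share one factor system")
    TS = np.where(sk.S_general, T.values, 0.0)
    WS = TS.copy()
    idx = {c: i for i, c in enumerate(rs.system.codes)}
    for loop in rs.loops:
        ids = [idx[c] for c in loop]
        for a in ids:
            for b in ids:
                if a != b:
                    WS[a, b] = 1.0
    return ValuedSkeleton(system=T.system, TS=TS, WS=WS)
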