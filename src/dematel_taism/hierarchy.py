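"""Antagonistic level extraction and layer classification.

Two extractions are run on the reachability matrix R.  For a factor e in
the residual system, Rset(e) is everything it can still reach, Q(e)
everything that can still reach it, and Tset(e) = Rset(e) & Q(e).

* UP (result priority): every factor with Rset = Tset is removed in one
  round; the first batch is the topmost level 0 and later batches follow
  downward.  Sinks surface first, so outcomes sit on top.
* DOWN (cause priority): every factor with Q = Tset is removed per round;
  batches are stacked bottom-up so the first batch is the lowest level
  and the final batch is level 0.  Sources settle at the bottom.

Factors whose level index differs between the two extractions are the
system's *active elements*.  The union of both bottom levels is the root
layer, the union of both extractions' levels 0-1 the result layer, the
remainder the intermediate layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import StructureError, ValidationError
from .factors import FactorSystem
from .structure import ReachabilityStructure

__all__ = [
    "Mode",
    "FactorSets",
    "LevelPartition",
    "LayerClassification",
    "CausalTerm",
    "CausalSeries",
    "extract_levels",
    "identify_active_elements",
    "classify_layers",
    "full_causal_series",
]


class Mode(str, Enum):
    UP = "UP"      # result priority
    DOWN = "DOWN"  # cause priority


@dataclass(frozen=True)
class FactorSets:
    """Reachable, antecedent and common sets of one factor (within a residual system)."""

    code: str
    reachable: frozenset[str]
    antecedent: frozenset[str]

    @property
    def common(self) -> frozenset[str]:
        return self.reachable & self.antecedent


@dataclass(frozen=True)
class LevelPartition:
    """Ordered levels of one extraction; level 0 first (topmost, result side)."""

    mode: Mode
    system: FactorSystem
    levels: tuple[tuple[str, ...], ...]

    def level_of(self, code: str) -> int:
        for k, level in enumerate(self.levels):
            if code in level:
                return k
        raise KeyError(f"factor {code!r} not in partition")

    def as_sets(self) -> list[set[str]]:
        return [set(level) for level in self.levels]


def _factor_sets(R: np.ndarray, codes: tuple[str, ...], residual: list[int]) -> dict[int, FactorSets]:
    out = {}
    for i in residual:
        reach = frozenset(codes[j] for j in residual if R[i, j])
        ante = frozenset(codes[j] for j in residual if R[j, i])
        out[i] = FactorSets(codes[i], reach, ante)
    return out


def extract_levels(rs: ReachabilityStructure, mode: Mode | str) -> LevelPartition:
    """Iterative level extraction under the result- or cause-priority rule.

    All qualifying factors of a round are removed simultaneously; members
    of a loop qualify together (they are mutually reachable), so loops
    are never split across levels.
    """
    mode = Mode(mode)
    R = rs.R
    if not np.array_equal(R, R | (R @ R)):
        raise StructureError("reachability matrix must be transitive")
    codes = rs.system.codes
    residual = list(range(len(codes)))
    batches: list[tuple[str, ...]] = []
    while residual:
        sets = _factor_sets(R, codes, residual)
        if mode is Mode.UP:
            batch = [i for i in residual if sets[i].reachable == sets[i].common]
        else:
            batch = [i for i in residual if sets[i].antecedent == sets[i].common]
        if not batch:
            raise StructureError("level extraction stalled: reachability is not transitive/reflexive")
        batches.append(tuple(codes[i] for i in sorted(batch)))
        removed = set(batch)
        residual = [i for i in residual if i not in removed]
    if mode is Mode.DOWN:
        batches.reverse()  # first-extracted batch is the lowest level
    return LevelPartition(mode=mode, system=rs.system, levels=tuple(batches))


def _check_same_system(up: LevelPartition, down: LevelPartition) -> None:
    if up.system != down.system:
        raise ValidationError("UP and DOWN partitions cover different factor systems")


def identify_active_elements(up: LevelPartition, down: LevelPartition) -> frozenset[str]:
    """Factors whose level index differs between the UP and DOWN extractions."""
    _check_same_system(up, down)
    return frozenset(
        code for code in up.system.codes if up.level_of(code) != down.level_of(code)
    )


@dataclass(frozen=True)
class LayerClassification:
    root: frozenset[str]
    intermediate: frozenset[str]
    result: frozenset[str]
    active: frozenset[str]


def classify_layers(up: LevelPartition, down: LevelPartition) -> LayerClassification:
    """Root / intermediate / result layers from the two extractions.

    Root is the union of both bottom levels, result the union of levels
    0-1 of both extractions, intermediate the rest.  With fewer than
    three levels the intermediate layer may be empty; the rule still
    applies.
    """
    _check_same_system(up, down)
    all_codes = set(up.system.codes)
    root = set(up.levels[-1]) | set(down.levels[-1])
    result = set()
    for part in (up, down):
        for level in part.levels[:2]:
            result.update(level)
    result -= root  # a 2-level system: sources stay root
    intermediate = all_codes - root - result
    return LayerClassification(
        root=frozenset(root),
        intermediate=frozenset(intermediate),
        result=frozenset(result),
        active=identify_active_elements(up, down),
    )


@dataclass(frozen=True)
class CausalTerm:
    """One level of a causal chain: bracketed loops plus free factors."""

    loops: tuple[tuple[str, ...], ...]
    singletons: tuple[str, ...]

    def member_set(self) -> frozenset[str]:
        return frozenset(c for loop in self.loops for c in loop) | frozenset(self.singletons)

    def __str__(self) -> str:
        parts = ["[" + ", ".join(loop) + "]" for loop in self.loops]
        parts += list(self.singletons)
        return "{" + ", ".join(parts) + "}"


@dataclass(frozen=True)
class CausalSeries:
    """Full causal chain: levels bottom (causes) to top (results), loops bracketed."""

    mode: Mode
    terms: tuple[CausalTerm, ...]

    def __str__(self) -> str:
        return " ≻ ".join(str(t) for t in self.terms)


def full_causal_series(partition: LevelPartition, rs: ReachabilityStructure) -> CausalSeries:
    """Render a level partition as a bottom-to-top chain with loops bracketed.

    Loops (size >= 2 components) always sit wholly inside one level; they
    are listed first within a term, larger loops first, then the free
    factors in factor order.
    """
    loop_of = {}
    for loop in rs.loops:
        for c in loop:
            loop_of[c] = loop
    terms = []
    for level in reversed(partition.levels):
        loops = []
        singles = []
        for code in level:
            if code in loop_of:
                if loop_of[code] not in loops:
                    loops.append(loop_of[code])
            else:
                singles.append(code)
        loops.sort(key=lambda lp: (-len(lp), partition.system.index(lp[0])))
        terms.append(CausalTerm(loops=tuple(loops), singletons=tuple(singles)))
    return CausalSeries(mode=partition.mode, terms=tuple(terms))
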