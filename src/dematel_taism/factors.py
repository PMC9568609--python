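"""Factor systems: the ordered index sets underlying every pipeline matrix.

A :class:`FactorSystem` fixes the order of the factor codes once; every
matrix in the pipeline (direct influence, normalized, total influence,
adjacency, reachability, skeleton) is indexed row- and column-wise by that
order, so results from different stages can be joined without re-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .errors import ValidationError

__all__ = ["FactorInfo", "FactorSystem"]


@dataclass(frozen=True)
class FactorInfo:
    """Human-readable metadata for one factor code."""

    name: str
    dimension: str = ""
    description: str = ""


@dataclass(frozen=True)
class FactorSystem:
    """An ordered set of factor codes with optional labels.

    Parameters
    ----------
    codes
        Ordered, unique, non-empty short identifiers (e.g. ``"B5"``).
    labels
        Optional mapping from code to :class:`FactorInfo`.  Codes without
        an entry simply have no metadata; extra keys are rejected.
    """

    codes: tuple[str, ...]
    labels: Mapping[str, FactorInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = tuple(self.codes)
        object.__setattr__(self, "codes", codes)
        if len(codes) < 2:
            raise ValidationError("a factor system needs at least two factors")
        if any(not c for c in codes):
            raise ValidationError("factor codes must be non-empty strings")
        if len(set(codes)) != len(codes):
            raise ValidationError("factor codes must be unique")
        unknown = set(self.labels) - set(codes)
        if unknown:
            raise ValidationError(f"labels refer to unknown codes: {sorted(unknown)}")
        object.__setattr__(self, "labels", MappingProxyType(dict(self.labels)))

    @property
    def n(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown factor code {code!r}") from None

    def info(self, code: str) -> FactorInfo:
        self.index(code)
        return self.labels.get(code, FactorInfo(name=code))

    def __eq__(self, other: object) -> bool:
        # Two systems are interchangeable iff their code order agrees;
        # labels are presentation metadata.
        if not isinstance(other, FactorSystem):
            return NotImplemented
        return self.codes == other.codes

    def __hash__(self) -> int:
        return hash(self.codes)
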