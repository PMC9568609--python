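"""Bundled example data.

The main dataset is the 13-factor adolescent non-suicidal self-injury
(NSSI) influence system: the direct-influence matrix aggregated from a
27-member expert panel that scored every ordered factor pair on a 0-4
scale.  It is stored here as literal data (not parsed from a file) and the
test suite cross-validates the transcription against the published
normalized matrix, so a copying slip in any of the 169 entries would be
caught mechanically.

``degenerate_cases`` provides tiny hand-built systems (chain, cycle,
isolated factor, complete digraph) used by property tests to probe the
structural stages at their edges.
"""

from __future__ import annotations

import numpy as np

from .factors import FactorInfo, FactorSystem
from .matrices import DirectInfluenceMatrix

__all__ = ["nssi_fixture", "degenerate_cases"]

NSSI_CODES = ("A2", "A3", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B9", "B10", "B11", "Y")

NSSI_LABELS = {
    "A2": FactorInfo("Sleep", "Physiological", "Overall sleep quality and regularity."),
    "A3": FactorInfo("Exercise", "Physiological", "Frequency, duration and intensity of physical exercise."),
    "B2": FactorInfo("Self-cognition", "Cognitive", "Self-evaluation, self-worth and self-respect."),
    "B3": FactorInfo("Self-efficacy", "Cognitive", "Attribution style and judged ability to carry out behaviour."),
    "B4": FactorInfo("Emotional state", "Emotional", "Current affective state: depression, anxiety, stress."),
    "B5": FactorInfo("Emotion regulation ability", "Emotional", "Capacity to change one's own emotional responses."),
    "B6": FactorInfo("Peer support", "Social support", "Care, companionship and support from peers."),
    "B7": FactorInfo("Family support", "Social support", "Communication with and support from parents."),
    "B8": FactorInfo("School support", "Social support", "Safe school environment and teacher support."),
    "B9": FactorInfo("Social support", "Social support", "Access to wider platforms for communication and resources."),
    "B10": FactorInfo("Social environment", "Social environment", "Influence of culture, values and social fairness."),
    "B11": FactorInfo("Leisure entertainment", "Social environment", "Opportunity for healthy leisure and recreation."),
    "Y": FactorInfo("NSSI", "NSSI", "Non-suicidal self-injury ideation or behaviour."),
}

# Aggregated 0-4 scores over 27 experts; rows influence columns.
_NSSI_O = (
    (0, 67, 15, 18, 82, 35, 19, 12, 11, 11, 11, 16, 85),
    (81, 0, 17, 18, 85, 32, 18, 12, 11, 11, 11, 15, 46),
    (15, 13, 0, 102, 23, 79, 59, 18, 17, 18, 18, 14, 82),
    (15, 13, 84, 0, 18, 83, 62, 15, 16, 16, 12, 16, 78),
    (43, 13, 22, 23, 0, 22, 20, 14, 14, 14, 14, 34, 94),
    (43, 12, 20, 19, 85, 0, 24, 16, 12, 12, 12, 36, 97),
    (21, 19, 42, 72, 30, 61, 0, 12, 13, 13, 13, 27, 74),
    (12, 12, 19, 16, 18, 94, 21, 0, 71, 73, 17, 14, 75),
    (11, 14, 18, 19, 21, 81, 22, 77, 0, 70, 18, 16, 62),
    (11, 15, 20, 19, 21, 64, 20, 76, 72, 0, 13, 17, 65),
    (11, 15, 72, 19, 21, 62, 21, 63, 76, 73, 0, 23, 70),
    (20, 19, 18, 50, 22, 78, 21, 15, 19, 15, 15, 0, 85),
    (25, 11, 21, 22, 18, 15, 10, 15, 12, 12, 11, 10, 0),
)


def nssi_fixture() -> tuple[FactorSystem, DirectInfluenceMatrix]:
    """The 13-factor adolescent NSSI system and its aggregated direct-influence matrix."""
    system = FactorSystem(NSSI_CODES, NSSI_LABELS)
    return system, DirectInfluenceMatrix(system, np.array(_NSSI_O, dtype=np.int64))


def _system(codes: tuple[str, ...]) -> FactorSystem:
    return FactorSystem(codes)


def degenerate_cases() -> dict[str, tuple[FactorSystem, DirectInfluenceMatrix]]:
    """Named edge-case systems for property testing.

    Returns a chain, a 3-cycle, a system with a fully isolated factor, and
    a complete digraph.  The positive support of each matrix is the
    intended structure; tests binarize on ``> 0`` when they need the
    adjacency pattern directly rather than the mean+sd intercept.
    """
    cases: dict[str, tuple[FactorSystem, DirectInfluenceMatrix]] = {}

    chain = _system(("F1", "F2", "F3"))
    cases["chain"] = (chain, DirectInfluenceMatrix(
        chain, np.array([[0, 4, 0], [0, 0, 4], [0, 0, 0]])))

    cycle = _system(("F1", "F2", "F3"))
    cases["cycle3"] = (cycle, DirectInfluenceMatrix(
        cycle, np.array([[0, 4, 0], [0, 0, 4], [4, 0, 0]])))

    iso = _system(("F1", "F2", "F3", "F4"))
    # F4 has a zero row and zero column
    cases["isolated"] = (iso, DirectInfluenceMatrix(
        iso, np.array([[0, 4, 2, 0], [0, 0, 4, 0], [0, 0, 0, 0], [0, 0, 0, 0]])))

    comp = _system(("F1", "F2", "F3", "F4"))
    cases["complete"] = (comp, DirectInfluenceMatrix(
        comp, 4 * (np.ones((4, 4), dtype=np.int64) - np.eye(4, dtype=np.int64))))

    return cases
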