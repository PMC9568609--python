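"""Synthetic expert panels for testing the pipeline without survey data.

``generate_panel`` emulates the study design of the bundled NSSI example:
a panel of experts each scores every ordered factor pair on the 0-4 scale,
and the per-expert tables are later summed into one direct-influence
matrix.  Scores are drawn i.i.d. per cell from a categorical distribution
over {0,..,4}.  The default weights put most mass on 0-1 with a thin tail
of strong scores, which mirrors the sparsity of real panels, where most
pairs are judged weakly related and a few strongly; real panels also show
inter-expert correlation and systematic rater biases that this generator
deliberately does not model.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .factors import FactorSystem
from .matrices import SCORE_MAX, ExpertScoreTable

__all__ = ["generate_panel", "DEFAULT_SCORE_WEIGHTS"]

# P(score = 0..4): mostly none/weak, occasional strong judgments.
DEFAULT_SCORE_WEIGHTS = (0.45, 0.25, 0.15, 0.10, 0.05)


def generate_panel(
    n_factors: int = 13,
    n_experts: int = 27,
    score_distribution: tuple[float, ...] = DEFAULT_SCORE_WEIGHTS,
    seed: int | None = None,
) -> tuple[FactorSystem, list[ExpertScoreTable]]:
    """Draw a reproducible panel of expert score tables.

    Parameters
    ----------
    n_factors, n_experts
        Panel dimensions; defaults match the bundled worked example
        (13 factors scored by 27 experts).
    score_distribution
        Nonnegative weights for scores 0..4 (normalized internally).
    seed
        Seed for a single ``numpy.random.default_rng`` stream; identical
        arguments with identical seeds give identical panels.
    """
    if n_factors < 2:
        raise ValidationError("n_factors must be at least 2")
    if n_experts < 1:
        raise ValidationError("n_experts must be at least 1")
    w = np.asarray(score_distribution, dtype=float)
    if w.shape != (SCORE_MAX + 1,) or np.any(w < 0) or w.sum() == 0:
        raise ValidationError(
            f"score_distribution must be {SCORE_MAX + 1} nonnegative weights, not all zero"
        )
    p = w / w.sum()

    rng = np.random.default_rng(seed)
    system = FactorSystem(tuple(f"F{i + 1}" for i in range(n_factors)))
    tables = []
    for e in range(n_experts):
        scores = rng.choice(SCORE_MAX + 1, size=(n_factors, n_factors), p=p)
        np.fill_diagonal(scores, 0)
        tables.append(ExpertScoreTable(f"expert-{e + 1}", system, scores))
    return system, tables
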