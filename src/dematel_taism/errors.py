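"""Exception types raised by the pipeline."""


class PipelineError(ValueError):
    """Base class for all data and contract errors in the pipeline."""


class ValidationError(PipelineError):
    """An input object violates a structural invariant (shape, range, diagonal)."""


class NormalizationError(PipelineError):
    """The direct influence matrix cannot be normalized (e.g. all entries zero)."""


class DivergenceError(PipelineError):
    """The Neumann series for the total influence matrix does not converge
    (spectral radius of the normalized matrix is >= 1)."""


class MatrixFormatError(PipelineError):
    """A CSV matrix file is malformed (ragged rows, duplicate or mismatched
    header codes, non-numeric cells)."""


class StructureError(PipelineError):
    """A graph-stage contract is violated (non-transitive reachability,
    cyclic condensation, missing realizing edge)."""
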