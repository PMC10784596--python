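"""Exception hierarchy shared across the package.

All domain errors derive from :class:`CochregError` so callers (and the CLI,
which maps them to exit code 3) can catch one type.
"""


class CochregError(ValueError):
    """Base class for all cochreg domain errors."""


class ParameterError(CochregError):
    """A model or transform parameter is outside its admissible domain."""


class GeometryError(CochregError):
    """Degenerate geometry: parallel chords, rank-deficient point sets, ..."""


class CorrespondenceError(CochregError):
    """Landmark sets that must correspond index-by-index do not."""


class UnderdeterminedError(GeometryError):
    """Too few landmark pairs to determine an affine transform."""


class PruningPlanError(CochregError):
    """A pruning plan cannot be executed (e.g. protected labels block a batch)."""
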