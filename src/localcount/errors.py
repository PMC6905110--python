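"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: ValidationError -> 2, GeometryError -> 3.
"""


class LocalCountError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(LocalCountError, ValueError):
    """Invalid user input: bad layer spec, out-of-bounds dots, empty metric input."""


class GeometryError(LocalCountError, ValueError):
    """Shape bookkeeping violated: input too small, target/output grid mismatch,
    patch size not matching a model's expected input."""


class CoverageError(LocalCountError, RuntimeError):
    """Internal: a pixel of the canvas is covered by no prediction window.

    Cannot happen under the canonical 64/16/15 geometry on grid-aligned images;
    raised rather than silently dividing by zero."""
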