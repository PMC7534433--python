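"""Exception hierarchy.

Errors are grouped by how a pipeline run should react to them: configuration
problems (bad arguments, missing columns), validation problems (data that
violates an input contract), empty analyses (no records survive filtering),
and statistical degeneracies (a test that cannot be computed).
"""


class GrnOverlapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GrnOverlapError):
    """Bad arguments or run configuration (CLI exit code 2)."""


class ValidationError(GrnOverlapError):
    """Input data violates an invariant (CLI exit code 3)."""


class EmptyAnalysisError(GrnOverlapError):
    """No records remain after filtering; the analysis is undefined (exit 4)."""


class UndefinedRatioError(GrnOverlapError):
    """Shared ratio requested for two empty sets."""


class DegenerateTestError(GrnOverlapError):
    """A statistical test whose sample is entirely ties or otherwise empty."""
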