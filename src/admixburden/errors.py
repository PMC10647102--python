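"""Exception types shared across the package.

Readers reject malformed input rather than coercing it; every error message
names the offending file, record and rule so that pipeline failures are
actionable without re-running under a debugger.
"""


class AdmixBurdenError(Exception):
    """Base class for all package errors."""


class ConfigError(AdmixBurdenError):
    """Invalid simulation or pipeline configuration."""


class FormatError(AdmixBurdenError):
    """Malformed input file (VCF, BED, TSV)."""

    def __init__(self, message, path=None, record=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if record is not None:
            ctx.append(f"record={record}")
        if ctx:
            message = f"{message} [{', '.join(ctx)}]"
        super().__init__(message)
        self.path = path
        self.record = record


class CoverageError(AdmixBurdenError):
    """A genomic position is not covered by any ancestry tract."""


class DegenerateInputError(AdmixBurdenError):
    """Statistical operation called on input with no information (e.g. zero variance)."""
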