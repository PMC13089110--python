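"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`CometBioageError`
so callers (and the CLI) can catch one base class.
"""


class CometBioageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CometBioageError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class GenerationError(CometBioageError, RuntimeError):
    """The synthetic generator cannot realise the requested construction."""


class InputError(CometBioageError, ValueError):
    """Malformed or out-of-contract input data."""


class MissingCpGError(InputError):
    """Clock CpGs absent from the methylation matrix; carries the missing ids."""

    def __init__(self, clock_name: str, missing: list):
        self.clock_name = clock_name
        self.missing = list(missing)
        preview = ", ".join(self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(
            f"clock '{clock_name}' requires {len(self.missing)} CpGs absent from the "
            f"methylation matrix: {preview}{more}"
        )


class AlignmentError(CometBioageError, ValueError):
    """Tables that must share participant ids do not."""


class EstimationError(CometBioageError, RuntimeError):
    """A model fit is degenerate (constant regressor, singular design, zero variance)."""


class FitError(EstimationError):
    """A harmonization or w-score fit cannot be performed."""


class StratificationError(CometBioageError, RuntimeError):
    """Biological-age group stratification is undefined (zero SD, too few subjects)."""


class ValidationError(CometBioageError, ValueError):
    """Fatal schema/consistency violations found by input validation."""
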