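"""Exception hierarchy for the chequity package."""


class ChequityError(Exception):
    """Base class for all package errors."""


class ConfigError(ChequityError, ValueError):
    """A configuration field failed validation; the message names the field."""


class SchemaError(ChequityError, ValueError):
    """A panel file is missing a mandatory column; the message names it."""


class PanelParseError(ChequityError, ValueError):
    """A panel file row could not be parsed; the message cites the row."""


class DegenerateOutcomeError(ChequityError, ValueError):
    """The outcome mean is zero, so a rate-normalised index is undefined."""


class ConvergenceError(ChequityError, RuntimeError):
    """A maximum-likelihood fit failed to converge (e.g. perfect separation)."""


class StageError(ChequityError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
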