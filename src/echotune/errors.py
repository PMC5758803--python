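"""Exception hierarchy shared across the package."""


class EchotuneError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EchotuneError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateBaselineError(EchotuneError, ValueError):
    """Baseline fluorescence f0 is non-positive; refusing to divide."""


class UndefinedTestError(EchotuneError, ValueError):
    """A statistical test is undefined for the given data (e.g. all ties)."""


class ConfigError(EchotuneError, ValueError):
    """A run configuration failed schema validation."""
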