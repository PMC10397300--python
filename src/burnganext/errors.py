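"""Exception taxonomy shared across the package."""


class BurnganextError(Exception):
    """Base class for package errors."""


class ConfigurationError(BurnganextError, ValueError):
    """A model / generator configuration violates an invariant."""


class InputError(BurnganextError, ValueError):
    """A runtime input (tensor, label, file) is malformed."""


class UsageError(BurnganextError, ValueError):
    """An unknown option or convention name was requested."""
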