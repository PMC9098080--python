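"""Named exceptions shared across the pipeline."""


class UsvPipeError(Exception):
    """Base class for all usvpipe errors."""


class InvalidClassLabelError(UsvPipeError):
    """An unknown or unsupported syllable class label was supplied."""


class SampleRateError(UsvPipeError):
    """Sample rate too low for the requested spectral content."""


class EmptyInputError(UsvPipeError):
    """An operation received an empty input it cannot handle."""


class ShapeMismatchError(UsvPipeError):
    """Array arguments have inconsistent shapes or lengths."""


class ConfigError(UsvPipeError):
    """A configuration value lies outside its allowed domain."""


class UntrainedModelError(UsvPipeError):
    """A prediction was requested from an untrained model or stacker."""
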