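"""Exception hierarchy.

``InputError`` maps to CLI exit code 1, ``ConfigError`` to exit code 2.
"""


class AdspeechError(Exception):
    """Base class for all package errors."""


class InputError(AdspeechError, ValueError):
    """Invalid or unusable input data (bad file, too-short signal, ...)."""


class DegenerateInputError(InputError):
    """Input is structurally valid but the operation is undefined on it
    (e.g. a constant series has zero curve length at every scale)."""


class ConfigError(AdspeechError, ValueError):
    """Invalid run configuration (unknown keys, out-of-range values)."""
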