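"""Exception hierarchy shared across the package.

Three failure classes are distinguished so that the CLI can map them onto
exit codes: bad user-supplied data (:class:`InputError`), malformed files
(:class:`FormatError`) and inconsistent gate/region configuration
(:class:`ConfigurationError`).
"""


class VirtualGateError(Exception):
    """Base class for all package-specific errors."""


class InputError(VirtualGateError, ValueError):
    """Invalid input data or parameters (empty stream, negative latency, ...)."""


class FormatError(VirtualGateError, ValueError):
    """A file or frame sequence violates the expected on-disk format."""


class ConfigurationError(VirtualGateError, ValueError):
    """A barrier/gate configuration is inconsistent with the data it is applied to."""


class GroundTruthError(VirtualGateError, ValueError):
    """A synthetic scene cannot produce the requested ground-truth event."""
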