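"""Exception hierarchy shared across the pipeline.

``InputError`` covers malformed user inputs and configuration (CLI exit code 1);
``InternalError`` flags violated internal invariants (exit code 2).
"""


class ProxidiffError(Exception):
    """Base class for all package errors."""


class InputError(ProxidiffError):
    """Malformed input data or configuration supplied by the caller."""


class InternalError(ProxidiffError):
    """An internal consistency invariant was violated; indicates a bug."""
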