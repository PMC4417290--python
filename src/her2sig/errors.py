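"""Exception hierarchy.

Everything user-facing raises a subclass of :class:`Her2SigError` so the CLI
can catch one type, print the message, and exit nonzero.
"""


class Her2SigError(Exception):
    """Base class for all validation and domain errors."""


class InputFormatError(Her2SigError):
    """A delimited input file violates the expected layout."""


class PanelError(Her2SigError):
    """A gene panel is invalid or inconsistent with the data."""


class ProfileError(Her2SigError):
    """An expression profile is incomplete or in the wrong space."""


class ClassificationError(Her2SigError):
    """Correlation or decision-rule preconditions violated."""
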