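"""Error taxonomy shared by every notation codec.

Each parse/validity failure maps to one class of the syntax-error taxonomy
used when profiling invalid model generations.  ``error_class`` strings are
stable identifiers and appear in evaluation histograms.
"""

from __future__ import annotations

ERROR_CLASSES = (
    "chirality_error",
    "ring_closure_error",
    "branch_error",
    "connector_bond_error",
    "valence_error",
    "token_error",
)

NO_ERROR = "none"


class NotationError(ValueError):
    """Base class for string-notation parse/decode failures."""

    error_class = "token_error"


class TokenError(NotationError):
    """Unknown or malformed word / symbol."""

    error_class = "token_error"


class BranchError(NotationError):
    """Unbalanced or misplaced branch (parenthesis) tokens."""

    error_class = "branch_error"


class ConnectorBondError(NotationError):
    """Connector token with an out-of-range attachment index, a missing
    adjacent fragment, or a fragment with no connecting bond."""

    error_class = "connector_bond_error"


class ChiralityError(NotationError):
    """Stereo annotation that cannot be realized: label on an atom that is
    not a perceivable stereocenter, duplicate/conflicting labels, or a
    parity that no tetrahedral tag reproduces."""

    error_class = "chirality_error"


class RingClosureError(NotationError):
    """Unmatched ring-closure digit (atom-level notations only)."""

    error_class = "ring_closure_error"


class ValenceError(NotationError):
    """Decoded structure violates an element's legal valence."""

    error_class = "valence_error"


class UnsupportedStereoError(NotationError):
    """Stereo feature the notation cannot carry (flagged, never dropped
    silently): e.g. a stereocenter with an undefined CIP label."""

    error_class = "chirality_error"


class UnreachableClassError(RuntimeError):
    """Raised by the corruptor when the requested error class cannot be
    planted in the given string (e.g. ring-closure errors in a notation
    without ring-closure syntax)."""


class ConfigError(ValueError):
    """Invalid configuration (unregistered notation, bad probabilities,
    degenerate split fractions, ...)."""
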