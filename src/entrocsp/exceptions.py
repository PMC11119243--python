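"""Exception hierarchy.

All pipeline errors derive from :class:`EntrocspError` so callers can
catch the package's failures with one clause.  Shape/label problems are
``ValidationError`` (a ``ValueError``); container problems at load time
are ``ContainerError``; unrecognised MAT-file layouts are ``LayoutError``.
"""


class EntrocspError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(EntrocspError, ValueError):
    """Input object violates a documented invariant (shape, labels, range)."""


class ContainerError(EntrocspError, OSError):
    """Native container is missing or structurally broken (no manifest, ...)."""


class LayoutError(EntrocspError):
    """A MAT file does not follow the expected competition layout."""


class EpochingError(EntrocspError):
    """An epoch window falls outside the continuous recording."""


class FilterDesignError(EntrocspError):
    """Requested band edges cannot be realised at the given sampling rate."""


class DegenerateTrialError(EntrocspError):
    """A trial has zero total power and cannot be trace-normalised."""


class StratificationError(EntrocspError):
    """A cross-validation training partition is missing a class."""
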