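"""Exception hierarchy.

All package errors derive from :class:`MobishiftError` so callers can catch
one base class; subclasses distinguish bad configuration, malformed files,
invalid analysis input, and requests beyond the implementation's capability
(e.g. exact Mann-Kendall p-values at sizes where enumeration is infeasible).
"""


class MobishiftError(Exception):
    """Base class for all mobishift errors."""


class ConfigurationError(MobishiftError):
    """A configuration value violates its documented constraints."""


class FormatError(MobishiftError):
    """An input file is malformed (bad schema, duplicate keys, bad values)."""


class ValidationError(MobishiftError):
    """A data-model invariant is violated (e.g. overlapping partitions)."""


class InputError(MobishiftError):
    """Analysis input is unusable (empty, degenerate, or mismatched)."""


class CapabilityError(MobishiftError):
    """The request is valid but outside this implementation's supported range."""
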