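"""Exception hierarchy for radcea.

All package-specific errors derive from :class:`RadceaError` so callers can
catch one base class; the CLI maps validation failures to exit code 1 and
runtime model errors to exit code 2.
"""

from __future__ import annotations


class RadceaError(Exception):
    """Base class for all radcea errors."""


class ConfigFormatError(RadceaError):
    """The config file could not be parsed (message names the offending line)."""


class ConfigValidationError(RadceaError):
    """A field violates an invariant (message names field and constraint)."""


class ConfigReferenceError(RadceaError):
    """A name refers to a state/strategy/complication that does not exist."""


class ModelStructureError(RadceaError):
    """The state graph is structurally unusable (e.g. cyclic dwell-exit chain)."""


class RuntimeModelError(RadceaError):
    """Probability mass violated while running the cohort (names cycle and state)."""


class DegenerateWeightsError(RadceaError):
    """All weights are zero in a weighted average."""


class AmbiguousThresholdError(RadceaError):
    """More than one sign change found while bracketing an NMB threshold."""
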