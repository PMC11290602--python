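"""Exception hierarchy shared across the package.

All errors derive from :class:`DivArrestError` so callers can catch the
package's failures with a single ``except`` clause; each subclass also
inherits from the closest builtin (``ValueError``/``KeyError``) so that
generic handling keeps working.
"""


class DivArrestError(Exception):
    """Base class for all package errors."""


class TreeFormatError(DivArrestError, ValueError):
    """A tree file failed to parse; the message names the offending tree."""


class EmptyInputError(DivArrestError, ValueError):
    """An input file or collection contained no usable records."""


class MappingError(DivArrestError, ValueError):
    """A species-to-family map does not cover every tip; offenders listed."""


class UltrametricityError(DivArrestError, ValueError):
    """Root-to-tip depths spread beyond the accepted tolerance."""


class DegenerateTreeError(DivArrestError, ValueError):
    """A tree is too small or degenerate for the requested quantity."""


class DomainError(DivArrestError, ValueError):
    """A numeric argument is outside the mathematical domain of an estimator."""


class ConfigurationError(DivArrestError, ValueError):
    """A setting is structurally impossible (e.g. more bins than families)."""


class UndefinedMPDError(DivArrestError, ValueError):
    """MPD requested for fewer than two tips."""
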