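"""Exception types shared across the package."""


class AsmEventsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AsmEventsError, ValueError):
    """A malformed input line (names the line number where possible)."""


class IntegrityError(AsmEventsError, ValueError):
    """Inconsistent data: dangling references, offset/text mismatches, conflicting tokens."""


class GraphLookupError(AsmEventsError, KeyError):
    """A token index that does not exist in the graph."""


class ConfigurationError(AsmEventsError, ValueError):
    """Invalid matching parameters (negative weights, missing features, bad ranges)."""
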