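"""Exception hierarchy shared across the package."""


class SkateEventsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SkateEventsError, ValueError):
    """A parameter violates its contract (e.g. cutoff at/above Nyquist)."""


class InsufficientDataError(SkateEventsError, ValueError):
    """A signal is too short for the requested operation."""


class InsufficientCyclesError(SkateEventsError):
    """Fewer cycle anchors were found than the minimum required."""

    def __init__(self, count: int, minimum: int = 2):
        self.count = count
        self.minimum = minimum
        super().__init__(
            f"found {count} cycle anchor(s); at least {minimum} required"
        )


class NoCyclesError(SkateEventsError):
    """Not enough left-ski contacts to define a single cycle."""


class GeneratorInfeasibleError(SkateEventsError):
    """A trial spec produces overlapping phases for too many cycles."""


class ParseError(SkateEventsError, ValueError):
    """A file violates its expected schema."""
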