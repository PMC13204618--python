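"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument or configuration value violates a precondition."""


class NoEventsError(ParameterError):
    """Survival data contain no observed events where at least one is required."""


class EmptyBagError(ParameterError):
    """A slide bag ended up with zero patches."""


class EmptyCohortError(ParameterError):
    """A filtering step removed every slide from a cohort."""


class NoComparablePairsError(ParameterError):
    """Censoring pattern leaves no comparable pair for rank statistics."""


class DegenerateGroupsError(ParameterError):
    """Risk scores cannot be split into two non-trivial groups."""


class HorizonError(ParameterError):
    """A time horizon is incompatible with the observed follow-up."""

    def __init__(self, horizon: float, message: str):
        self.horizon = horizon
        super().__init__(f"horizon {horizon}: {message}")
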