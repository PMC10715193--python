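"""Exception hierarchy shared across the pipeline stages."""


class CogScaleError(Exception):
    """Base class for all package errors."""


class FormatError(CogScaleError):
    """An input table row does not have the expected shape."""


class ValidationError(CogScaleError):
    """A value violates a documented precondition or invariant."""


class MappingError(CogScaleError):
    """Organisms present in the data are missing from the taxon map."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        shown = ", ".join(self.offenders[:10])
        more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
        super().__init__(f"organisms missing from taxon map: {shown}{more}")


class InsufficientDataError(CogScaleError):
    """Too few usable points for the requested fit; surfaces as an NA cell."""


class DegenerateDesignError(CogScaleError):
    """The regression design is singular (e.g. constant x)."""
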