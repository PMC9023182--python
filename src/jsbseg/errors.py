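"""Exception hierarchy for jsbseg."""


class JSBSegError(Exception):
    """Base class for all jsbseg errors."""


class DomainError(JSBSegError):
    """A gray value lies outside the open support of a Johnson S_B law."""


class DegenerateLevelError(JSBSegError):
    """A populated gray level has zero density under every mixture component."""


class CollapseError(JSBSegError):
    """An EM component collapsed onto (almost) a single gray level.

    Carries the index of the offending component so the fitter can attempt
    a one-shot reinitialisation before giving up.
    """

    def __init__(self, component: int, message: str | None = None):
        self.component = component
        super().__init__(message or f"mixture component {component} collapsed")


class EstimationError(JSBSegError):
    """The liver-gray-value sampling band was empty after black/white removal."""


class SplitError(JSBSegError):
    """The histogram cannot be divided at the requested gray level."""


class ThresholdError(JSBSegError):
    """A histogram part does not support threshold extraction."""


class RegionOverlapError(JSBSegError):
    """Two phantom regions overlap or leave the body interior."""
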