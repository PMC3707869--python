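"""Exception hierarchy for the beatwalk pipeline."""


class BeatwalkError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(BeatwalkError, ValueError):
    """A synthesis or run specification violates its invariants."""


class EmptySeriesError(BeatwalkError, ValueError):
    """The input signal is too short to produce a single analysis frame."""


class InsufficientDataError(BeatwalkError, ValueError):
    """Not enough samples/beats/songs for the requested computation."""


class UnusableTrialError(BeatwalkError, ValueError):
    """A sensor trial cannot be analyzed (e.g. gaps in the heading stream)."""


class DegenerateDataError(BeatwalkError, ValueError):
    """A statistic is undefined on this input (e.g. zero-variance speeds)."""


class SingularDesignError(BeatwalkError, ValueError):
    """The regression design matrix is rank deficient."""


class NoPeakError(BeatwalkError, ValueError):
    """No spectral peak found in the plausible cadence band."""
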