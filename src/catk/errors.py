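"""Exception hierarchy for the toolkit.

Every stage raises a subclass of :class:`CatkError` so that pipeline drivers
can tag failures with the stage that produced them.
"""


class CatkError(Exception):
    """Base class for all toolkit errors."""


class UnsupportedFormatError(CatkError):
    """The input file is readable but not a format the toolkit supports
    (e.g. RGB TIFF pages, mixed page sizes, unexpected bit depth)."""


class InvalidParameterError(CatkError, ValueError):
    """A parameter or argument violates its contract."""


class InvalidInputError(CatkError, ValueError):
    """Input data violates a precondition (NaN/Inf pixels, ragged traces...)."""


class DegenerateBaselineError(CatkError):
    """The baseline F0 = Flow - Fmin dropped to zero or below for some frame,
    which usually signals an overestimated background floor Fmin."""

    def __init__(self, roi_id, frame, f0_value):
        self.roi_id = roi_id
        self.frame = frame
        self.f0_value = f0_value
        super().__init__(
            f"ROI {roi_id}: baseline F0[{frame}] = {f0_value:.6g} <= 0; "
            "Fmin is likely overestimated for this trace"
        )


class TraceTooShortError(CatkError):
    """A trace is shorter than the sliding window requires."""


class PlacementError(CatkError):
    """The synthetic scene could not place all cells at the requested
    minimum spacing within the retry budget."""
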