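"""Exception hierarchy for the leafgp pipeline."""


class LeafGPError(Exception):
    """Base class for all leafgp errors."""


class InvalidInputError(LeafGPError):
    """Raised when an input image or parameter is malformed or empty."""


class MarkerDetectionError(LeafGPError):
    """Raised when fewer than four reference markers survive filtering.

    Attributes
    ----------
    n_found : int
        Number of candidate markers that survived the morphological filter.
    """

    def __init__(self, n_found: int, message: str | None = None):
        self.n_found = n_found
        super().__init__(
            message
            or f"expected 4 circular reference markers, found {n_found}"
        )


class DegenerateGeometryError(LeafGPError):
    """Raised when marker centres are collinear/duplicated or the scale is zero."""
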