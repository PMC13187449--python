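"""Exception hierarchy shared across the toolkit."""


class BtkError(Exception):
    """Base class for all toolkit errors."""


class FormatError(BtkError):
    """A file did not conform to the expected dialect."""


class AlignmentError(BtkError):
    """Two time bases could not be joined (e.g. disjoint ranges)."""


class ParameterError(BtkError, ValueError):
    """An argument violated a documented precondition."""


class InputError(BtkError, ValueError):
    """Input data violated a documented precondition."""


class DetectionError(BtkError):
    """No object could be detected in a frame."""


class SegmentationError(BtkError):
    """Segmentation produced an empty mask."""


class DegenerateGeometryError(BtkError):
    """Geometry collapsed to a point or all distances are zero."""


class ModelError(BtkError):
    """A statistical model could not be formed from the data given."""
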