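"""Exception hierarchy for the 4D-flow kinetic-energy pipeline."""


class FlowError(Exception):
    """Base class for all pipeline errors."""


class MetadataError(FlowError):
    """Missing or inconsistent acquisition metadata (venc, RR, spacing...)."""


class DimensionMismatchError(FlowError):
    """Component volumes or masks that do not share a grid."""


class LabelVocabularyError(FlowError):
    """Mask volume containing label codes outside the region vocabulary."""


class GeometryError(FlowError):
    """Phantom geometry that does not fit or resolve on the requested grid."""


class DegenerateDataError(FlowError):
    """Data with no usable signal: empty masks, constant curves,
    rank-deficient static-tissue sets, zero-variance samples."""


class AnalysisError(FlowError):
    """A downstream analysis contract violated (empty window, bad denominator)."""
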