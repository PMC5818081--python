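"""Exception types shared across the pipeline."""


class SpheroquantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SpheroquantError, ValueError):
    """A simulation or analysis parameter set is invalid or infeasible."""


class FormatError(SpheroquantError, ValueError):
    """An input table or file does not match the expected layout."""


class SegmentationError(SpheroquantError, RuntimeError):
    """Segmentation could not produce a usable result (e.g. no spheroid)."""


class ThresholdError(SegmentationError):
    """No meaningful intensity threshold exists (flat or saturated image)."""
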