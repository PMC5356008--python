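"""Exception hierarchy for locusrt.

All library errors derive from :class:`LocusRTError` so callers can catch
one base class; each subclass also derives from ``ValueError`` because every
failure mode here is ultimately a bad input or an incompatible artifact.
"""


class LocusRTError(ValueError):
    """Base class for all locusrt errors."""


class AlphabetError(LocusRTError):
    """A sequence contains a character outside the 20 standard residues."""


class FormatError(LocusRTError):
    """A file could not be parsed or lacks required columns/records."""


class EmptyInputError(LocusRTError):
    """An operation received no usable data."""


class SplitError(LocusRTError):
    """A dataset is too small to partition."""


class TrainingError(LocusRTError):
    """Model training preconditions are violated."""


class ModelFormatError(LocusRTError):
    """A model file is corrupt or has an unknown layout."""


class ModelCompatibilityError(LocusRTError):
    """A model's encoding provenance does not match the current encoder."""


class CalibrationError(LocusRTError):
    """Calibration-peptide selection or the linear fit is impossible."""


class EvaluationError(LocusRTError):
    """An evaluation statistic is undefined for the given input."""


class GenerationError(LocusRTError):
    """The synthetic generator cannot satisfy the request."""
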