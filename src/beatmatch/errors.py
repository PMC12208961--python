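"""Exception hierarchy for beatmatch.

Every operational failure mode maps to one of these, so callers (and the
CLI exit-code mapping) can distinguish bad configuration from bad data.
"""


class BeatmatchError(Exception):
    """Base class for all beatmatch errors."""


class FormatError(BeatmatchError):
    """Malformed input file (ragged rows, non-numeric columns, ...)."""


class SamplingError(BeatmatchError):
    """Time column is not uniformly spaced."""


class ConfigError(BeatmatchError):
    """Invalid or unresolvable configuration (cutoffs vs. Nyquist, fs, roles)."""


class LengthError(BeatmatchError):
    """Signal too short for the requested operation."""


class DegenerateSegmentError(BeatmatchError):
    """Flat/all-zero segment: envelope cannot be normalized."""


class DegenerateCandidateError(BeatmatchError):
    """A candidate beat segment has zero variance."""


class InsufficientCandidatesError(BeatmatchError):
    """Fewer than two candidate beats survive edge trimming."""


class NoReliableWindowError(BeatmatchError):
    """No 10-second window in the record passed the reliability gate."""


class DegenerateTemplateError(BeatmatchError):
    """Constant template: normalized cross-correlation undefined."""


class UndefinedMetricError(BeatmatchError):
    """Zero denominator in sensitivity or PPV."""


class SampleSizeError(BeatmatchError):
    """Too few samples for the requested statistical analysis."""


class ParameterError(BeatmatchError):
    """Synthetic-generator parameters outside their valid domain."""
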