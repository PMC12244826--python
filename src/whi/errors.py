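"""Exception hierarchy for the WHI pipeline.

Errors are grouped by where they arise: input plumbing (unreadable files,
malformed annotations), degenerate recordings (no sleep onset, zero
corrected sleep time) and configuration mistakes (lower threshold at or
above the upper threshold).
"""


class WHIError(Exception):
    """Base class for all package errors."""


# --- input / format errors -------------------------------------------------

class FileUnreadable(WHIError):
    """The input file does not exist or cannot be parsed in its format."""


class ChannelNotFound(WHIError):
    """No EDF channel label matched the requested oximetry channel."""

    def __init__(self, hint, available):
        self.hint = hint
        self.available = list(available)
        super().__init__(
            f"no channel matching {hint!r}; available labels: {self.available}"
        )


class MalformedAnnotation(WHIError):
    """Staging annotation file is not XML or carries no sleep-stage list."""


class NonUniformSampling(WHIError):
    """CSV signal rows are not uniformly spaced in time."""


class MalformedManifest(WHIError):
    """Batch manifest CSV lacks the required columns."""


# --- signal / recording errors --------------------------------------------

class EmptySignal(WHIError):
    """Signal contains no samples."""


class LengthMismatch(WHIError):
    """Per-second arrays (signal, masks) are not aligned."""


class NoSleepOnset(WHIError):
    """No run of three consecutive N1/N2/N3 epochs; recording unusable."""


class ZeroSleepTime(WHIError):
    """Corrected total sleep time is zero; the index is undefined."""


class ExcludedEvent(WHIError):
    """An area was requested for an artifact-excluded event."""


# --- configuration errors ---------------------------------------------------

class LowerAboveUpper(WHIError):
    """Artifact (lower) threshold is at or above the event (upper) threshold."""


class OverlappingDips(WHIError):
    """Synthetic spec declares overlapping desaturation dips."""


class UnsupportedShape(WHIError):
    """Synthetic dip shape has no closed-form ground truth."""


# --- cohort errors ----------------------------------------------------------

class TooFewSubjects(WHIError):
    """Quintile assignment needs at least five subjects."""


class NoEvents(WHIError):
    """Survival table has no observed events; Cox model cannot be fit."""


class ConvergenceFailure(WHIError):
    """Cox partial-likelihood optimisation failed to converge."""


class UnfittedModel(WHIError):
    """Survival curves requested from a model that has not been fit."""


class OutOfRange(WHIError):
    """P-values outside [0, 1]."""
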