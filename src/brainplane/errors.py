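"""Exception hierarchy shared across the pipeline."""


class BrainplaneError(Exception):
    """Base class for all errors raised by this package."""


class StackOrderError(BrainplaneError):
    """A plane filename did not yield a usable z index (no match, multiple
    matches, or a duplicate index)."""


class CheckpointMissingError(BrainplaneError):
    """A stage checkpoint was requested before that stage was ever run."""


class CheckpointCorruptError(BrainplaneError):
    """A stage checkpoint exists on disk but could not be parsed."""


class AtlasFormatError(BrainplaneError):
    """An atlas bundle violates its on-disk or in-memory contract."""


class MonotonicityError(BrainplaneError):
    """An anchor edit would break the strictly decreasing z -> AP mapping."""


class ChooserAborted(BrainplaneError):
    """The interactive chooser/corrector gave up on the current plate."""


class RegistrationError(BrainplaneError):
    """Correspondence extraction or warp fitting failed."""


class SegmentationError(BrainplaneError):
    """Invalid segmentation filter or unreadable plane."""


class PhantomError(BrainplaneError):
    """A phantom specification cannot be realised (e.g. regions too small)."""


class StageOrderError(BrainplaneError):
    """A pipeline stage was requested before its prerequisites ran."""
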