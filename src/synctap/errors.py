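"""Exception and warning types shared across the pipeline."""


class SynctapError(Exception):
    """Base class for all synctap errors."""


class InvalidArgumentError(SynctapError, ValueError):
    """A parameter violates an operation's precondition."""


class DegenerateInputError(SynctapError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero force)."""


class UndefinedStatisticError(SynctapError, ValueError):
    """Too few observations (or zero variance) to define the requested statistic."""


class UndefinedDirectionError(UndefinedStatisticError):
    """Circular mean of a perfectly balanced angle set (zero resultant)."""


class UnsupportedTaskError(SynctapError, ValueError):
    """Operation does not apply to this task (e.g. phase angles for REACT)."""


class UnsupportedCombinationError(SynctapError, ValueError):
    """Descriptor x task x window combination is not part of the analysis design."""


class FormatError(SynctapError, ValueError):
    """Unparseable or mis-shaped input file."""


class ShortTrainWarning(UserWarning):
    """A window asked for more taps than the train contains; partial result returned."""


class OverlapWarning(UserWarning):
    """Rendered force pulses overlap closer than their resolvable width."""
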