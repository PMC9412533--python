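"""Exception hierarchy for ivmr."""


class MRError(Exception):
    """Base class for all ivmr errors."""


class FormatError(MRError):
    """A summary-statistic or instrument file violates the expected dialect."""


class EmptyInstrumentError(MRError):
    """No variants survive harmonization or exclusion for an exposure/outcome pair."""


class InsufficientInstrumentsError(MRError):
    """An estimator was asked to run on fewer variants than its minimum."""


class UndefinedRatioError(MRError):
    """Wald ratio requested for a variant with zero exposure effect."""


class CollinearityError(MRError):
    """MR-Egger requires variation in the exposure effects; none was found."""
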