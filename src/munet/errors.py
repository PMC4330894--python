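"""Exception types raised across the pipeline stages."""


class MunetError(Exception):
    """Base class for all package-specific errors."""


class EpochTooShortError(MunetError):
    """Signal segment too short for the requested time-delay embedding."""


class WindowConfigError(MunetError):
    """No admissible comparison times inside the (w1, w2) window."""


class EmptyEpochsError(MunetError):
    """No complete epoch could be extracted for the requested condition."""


class DegenerateDistributionError(MunetError):
    """SL value distribution has zero MAD (all off-diagonal values equal)."""


class EmptyNetworkError(MunetError):
    """Thresholding removed every edge."""


class UndefinedR2Error(MunetError):
    """Coefficient of determination undefined (zero variance)."""


class DisconnectedGraphError(MunetError):
    """No pair of nodes is connected by a finite-length path."""


class InvalidDesignError(MunetError):
    """Statistical design invalid (missing condition, too-small group, ...)."""
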