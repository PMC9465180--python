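"""Exception hierarchy shared across the analysis modules."""


class MozearError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MozearError):
    """Input data violates a documented precondition."""


class InvalidParameterError(MozearError):
    """A model/configuration parameter is outside its valid domain."""


class EmptyBandError(MozearError):
    """Band filtering removed every frequency bin."""


class InsufficientDataError(MozearError):
    """Too few observations to perform the requested fit or summary."""


class NotConvergedError(MozearError):
    """An operation required a converged fit but got a failed one."""


class ExtrapolationError(MozearError):
    """An evaluation grid extends beyond the observed data range."""


class ProtocolError(MozearError):
    """Experiment structure does not match the requested protocol."""


class MissingReferenceError(MozearError):
    """A reference gene or reference tissue is absent from a group."""


class DegenerateRepeatError(MozearError):
    """A phonotaxis repeat contains no responders at any tone."""


class PairingError(MozearError):
    """Paired-test inputs are not properly paired."""


class FitQualityError(MozearError):
    """A fitted curve fails its goodness gate."""
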