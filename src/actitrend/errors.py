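"""Exception hierarchy for the actitrend pipeline."""


class ActitrendError(Exception):
    """Base class for all package errors."""


class FormatError(ActitrendError):
    """Malformed or unparseable input file."""


class UnsupportedEpochError(ActitrendError):
    """Epoch length that does not divide 60 seconds."""


class InvalidTargetError(ActitrendError):
    """Reintegration target incompatible with the source epoch length."""


class InvalidParameterError(ActitrendError):
    """Parameter combination outside the algorithm's domain."""


class MissingAgeError(ActitrendError):
    """No resolvable source for a participant's decimal age."""


class ConfigError(ActitrendError):
    """Missing or inconsistent configuration (cutoffs, simulation)."""


class DegenerateDesignError(ActitrendError):
    """Model design with too few groups or one-level factors."""


class InsufficientDataError(ActitrendError):
    """Fewer valid waves than the operation requires."""


class UndefinedProportionError(ActitrendError):
    """Wear-time standardization attempted with zero wear."""


class InfeasibleTargetError(ActitrendError):
    """Trace rendering targets that do not fit the wear window."""
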