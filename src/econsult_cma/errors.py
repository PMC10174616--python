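"""Exception hierarchy shared across the package."""


class EconsultCmaError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EconsultCmaError, ValueError):
    """A value lies outside the mathematical domain required of it
    (negative cost, probability outside [0, 1], non-positive shape...)."""


class EmptyStratumError(EconsultCmaError, ValueError):
    """A stratum that must contain at least one observation is empty."""

    def __init__(self, stratum: str):
        self.stratum = stratum
        super().__init__(f"empty stratum: {stratum}")


class ConfigurationError(EconsultCmaError, ValueError):
    """A configuration option (variant flag, distribution family, config
    document) is malformed or unknown."""


class UnresolvedParameterError(EconsultCmaError, KeyError):
    """A tree node or cost expression references a parameter id that the
    parameter table does not define."""

    def __init__(self, missing):
        self.missing = sorted(missing) if not isinstance(missing, str) else [missing]
        super().__init__(f"unresolved parameter id(s): {', '.join(self.missing)}")
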