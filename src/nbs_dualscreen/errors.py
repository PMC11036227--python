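"""Exception hierarchy shared across the package."""


class NbsError(Exception):
    """Base class for all package errors."""


class ValidationError(NbsError):
    """Input record violates a documented contract."""


class ContractViolation(NbsError):
    """An operation precondition was not met by the caller."""


class RegistryError(NbsError):
    """A marker is absent from the declared marker registry."""


class UndefinedMetricError(NbsError):
    """A performance metric has a zero denominator."""


class ConfigurationError(NbsError):
    """A simulation or pipeline configuration is inconsistent."""


class FixtureIntegrityError(NbsError):
    """A packaged fixture failed its checksum or schema check."""
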