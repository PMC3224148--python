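"""Exception hierarchy for the probe-design pipeline."""


class MfpsError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MfpsError, ValueError):
    """A synthetic-data specification violates its invariants."""


class FormatError(MfpsError, ValueError):
    """An input file violates the expected format (ragged FASTA, duplicate ids...)."""


class PrimerNotFoundError(MfpsError, ValueError):
    """No alignment interval matches the primer in a majority of sequences."""


class EmptyTargetError(MfpsError, ValueError):
    """Primer truncation left no target columns."""


class UndefinedDistanceError(MfpsError, ValueError):
    """A sequence pair shares no comparable (non double-gap) columns."""


class LabelingError(MfpsError, ValueError):
    """One or more sequences lack taxonomy labels; carries the offending ids."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(f"sequences missing taxonomy labels: {self.missing_ids}")


class ProbeCollisionError(MfpsError, ValueError):
    """A planted probe occurs outside its target group."""


class InfeasibleError(MfpsError, ValueError):
    """The probe-set size k cannot be satisfied under retain/avoid constraints."""


class ConfigError(MfpsError, ValueError):
    """A penalty or annealing configuration value is out of range."""
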