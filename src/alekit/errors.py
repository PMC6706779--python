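"""Exception hierarchy shared across the toolkit."""


class AleError(Exception):
    """Base class for all alekit errors."""


class ConfigurationError(AleError):
    """A simulator or pipeline configuration is invalid."""


class DomainError(AleError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class InsufficientDataError(AleError):
    """Not enough observations to perform the requested computation."""


class UndefinedDoublingTimeError(DomainError):
    """A passage with zero or negative net growth has no doubling time."""


class OneSidedDetectionError(AleError):
    """One qPCR target failed to amplify; a finite ratio does not exist.

    ``detected`` names the primer set that did amplify ("A" or "B").
    """

    def __init__(self, detected: str):
        self.detected = detected
        super().__init__(f"only primer set {detected!r} amplified; ratio is one-sided")


class CalibrationError(AleError):
    """The mixing-series regression is degenerate or under-determined."""


class GroupingError(AleError):
    """Records from incompatible lineage groups were mixed."""


class UnassignedUnitError(AleError):
    """Genomic positions could not be mapped onto any annotation unit."""

    def __init__(self, records):
        self.records = list(records)
        super().__init__(f"{len(self.records)} record(s) fall outside the annotation")


class GridError(AleError):
    """Checkpoint generations are not on a common grid."""


class TabulationError(AleError):
    """A phenotype-microarray tabulation does not cover the plate exactly once."""


class DegenerateTableError(AleError):
    """A contingency table has a zero margin and cannot be tested."""
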