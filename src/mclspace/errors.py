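"""Exception hierarchy shared by all mclspace modules."""


class MclspaceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MclspaceError):
    """Invalid configuration: unknown scheme, missing mandatory column mapping, bad bounds."""


class ValidationError(MclspaceError):
    """Invalid data encountered while reading or assembling tables."""


class SmilesParseError(MclspaceError):
    """A SMILES string could not be parsed; carries the offending record id."""

    def __init__(self, record_id: str, smiles: str):
        self.record_id = record_id
        self.smiles = smiles
        super().__init__(f"could not parse SMILES for record {record_id!r}: {smiles!r}")


class PredictorError(MclspaceError):
    """A predictor could not produce a value (missing inputs, missing column)."""


class AssemblyError(MclspaceError):
    """A feature-vector slot could not be filled."""


class UndefinedDistanceError(MclspaceError):
    """Distance undefined (e.g. both vectors all-zero)."""


class DomainError(MclspaceError):
    """Numeric argument outside the mathematical domain of an operation."""
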