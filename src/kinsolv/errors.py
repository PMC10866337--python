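"""Exception hierarchy shared across the package."""


class KinsolvError(Exception):
    """Base class for all package errors."""


class ParseError(KinsolvError):
    """A SMILES or reaction SMILES string could not be parsed."""


class MappingError(KinsolvError):
    """Atom-map numbers are missing, duplicated, or not a bijection."""


class BalanceError(KinsolvError):
    """Element multisets differ between the reactant and product sides."""


class SchemaError(KinsolvError):
    """A data table is missing required columns or violates the schema."""


class FeatureError(KinsolvError):
    """Additional feature widths are inconsistent or missing."""


class ShapeError(KinsolvError):
    """Array shapes are incompatible with the model parameters."""


class UsageError(KinsolvError):
    """An operation was called with arguments outside its contract."""
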