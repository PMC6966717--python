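"""Exception hierarchy shared across the package."""


class PairscreenError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(PairscreenError):
    """A SMILES string could not be parsed into a molecule."""


class UnknownSchemeError(PairscreenError):
    """A fingerprint scheme name is not registered."""


class FormatError(PairscreenError):
    """An input file violates the expected dialect."""


class CapacityError(PairscreenError):
    """A sampling request exceeds the available population."""


class DegenerateSplitError(PairscreenError):
    """A requested split cannot produce two non-empty, valid sides."""


class ShapeError(PairscreenError):
    """A network layer arithmetic produced a non-positive dimension."""
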