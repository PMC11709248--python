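"""Exception hierarchy for the ligandblob pipeline."""


class LigandBlobError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LigandBlobError):
    """A file could not be parsed as the expected format."""


class ValidationError(LigandBlobError):
    """An input violates a documented precondition."""


class DegenerateMapError(LigandBlobError):
    """A map is statistically degenerate (e.g. constant) for the requested operation."""


class DegenerateBlobError(LigandBlobError):
    """A blob/grid has no usable density (e.g. all voxels zero)."""


class ChemistryParseError(LigandBlobError):
    """A SMILES/InChI string could not be parsed into a molecule."""
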