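"""Exception hierarchy."""


class SasdiagError(Exception):
    """Base class for all package-specific errors."""


class NoPolymerError(SasdiagError):
    """Structure file contains no polymer residues."""


class NoUsableStructuresError(SasdiagError):
    """No candidate structure survives the selection rules."""


class SequenceMismatchError(SasdiagError):
    """Chain sequence identity to the reference falls below the floor."""


class VariantParseError(SasdiagError):
    """Variant string does not match any supported dialect."""


class SynonymousVariantError(VariantParseError):
    """Wild-type and mutant amino acids are identical."""


class FileParseError(SasdiagError):
    """A structured input file is malformed; carries location context."""


class ConfigError(SasdiagError):
    """Missing or inconsistent configuration (e.g. unknown element radius)."""
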