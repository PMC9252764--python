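"""Exception hierarchy."""


class EvoDDGError(Exception):
    """Base class for all package errors."""


class ConfigError(EvoDDGError):
    """Invalid configuration: unknown table, missing required input, bad mode."""


class ParseError(EvoDDGError):
    """A file (MSA, PDB, variant list) could not be parsed."""


class ValidationError(EvoDDGError):
    """Input is well-formed but inconsistent (e.g. wild-type residue mismatch)."""
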