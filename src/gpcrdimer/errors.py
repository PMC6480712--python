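"""Exception types shared across the package."""


class GpcrDimerError(Exception):
    """Base class for all package errors."""


class PDBFormatError(GpcrDimerError, ValueError):
    """Malformed PDB input (bad columns, inconsistent MODEL blocks, ...)."""


class SelectionError(GpcrDimerError, ValueError):
    """Selection string could not be parsed or matched no atoms."""


class TopologyError(GpcrDimerError, ValueError):
    """Structure/trajectory contents violate an operation's preconditions."""


class ParameterError(GpcrDimerError, KeyError):
    """A required physical parameter (LJ/charge) is missing."""


class ConfigError(GpcrDimerError, ValueError):
    """Invalid pipeline or generator configuration."""
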