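"""Exception hierarchy shared across the pipeline."""


class StrainpopError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(StrainpopError):
    """An infeasible or inconsistent simulation/run configuration."""


class FormatError(StrainpopError):
    """Malformed input data (FASTA/Rtab/TSV/VCF contract violations)."""


class ParameterError(StrainpopError):
    """An operation parameter outside its documented domain."""
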