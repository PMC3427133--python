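"""Exception hierarchy shared across the pipeline."""


class PolyptomeError(Exception):
    """Base class for all package errors."""


class FormatError(PolyptomeError, ValueError):
    """Malformed input file (FASTA/FASTQ/TSV/VCF/query string)."""


class AlphabetError(PolyptomeError, ValueError):
    """Sequence contains characters outside the supported alphabet."""


class ConfigError(PolyptomeError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ParameterError(PolyptomeError, ValueError):
    """Operation parameter outside its valid range."""


class InputError(PolyptomeError, ValueError):
    """Inconsistent inputs (e.g. alignment referencing an unknown contig)."""


class EstimationError(PolyptomeError, ValueError):
    """Estimate undefined for the given data (e.g. all-zero coverage)."""


class StatsError(PolyptomeError, ValueError):
    """Summary statistics undefined (e.g. empty contig set)."""
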