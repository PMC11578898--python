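"""Exception hierarchy shared across the package."""


class AutoQCError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(AutoQCError):
    """Auxiliary per-cell vectors do not align 1:1 with the count matrix barcodes."""


class IOFormatError(AutoQCError):
    """Malformed input file (dimension mismatch, duplicates, negative counts...)."""


class ConfigError(AutoQCError):
    """Invalid or inconsistent configuration."""


class DegenerateSampleError(AutoQCError):
    """Sample cannot be clustered (too few cells, or no informative metric)."""


class FitError(AutoQCError):
    """Mixture fitting failed for every candidate component count."""
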