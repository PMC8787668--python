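"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class SamplingError(RuntimeError):
    """A requested sample cannot be drawn (e.g. not enough plants of a phenotype)."""


class DataError(ValueError):
    """Malformed input data (negative depths, p-values outside [0, 1], ...)."""


class SequenceError(ValueError):
    """A nucleotide sequence contains characters outside the expected alphabet."""


class DesignError(ValueError):
    """A marker assay cannot be designed from the given input."""
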