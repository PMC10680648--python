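"""Exception types shared across the package."""


class FamhetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FamhetError):
    """A model or population configuration violates its invariants."""


class DegenerateInputError(FamhetError):
    """An estimator was handed data with no identifying variation
    (monomorphic locus, zero segregation variance, constant phenotype...)."""


class RankDeficiencyError(DegenerateInputError):
    """The regression design matrix is rank deficient; the message names
    the structural cause (e.g. no heterozygous parents)."""


class PedFormatError(FamhetError):
    """A pedigree/genotype file could not be parsed; carries the offending
    line number where applicable."""
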