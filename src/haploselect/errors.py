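"""Exception hierarchy shared across the package."""


class HaploselectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HaploselectError):
    """Malformed input file (multi-allelic site, missing column, bad dialect)."""


class PhaseError(HaploselectError):
    """Heterozygous unphased genotype encountered without the inbred assumption."""


class InbreedingViolationError(HaploselectError):
    """Heterozygous genotype (dosage 1) under the inbred-panel assumption."""


class MissingGenotypeError(HaploselectError):
    """Missing genotype call; imputation is out of scope, so reads reject these."""


class AlignmentError(HaploselectError):
    """Marker identifiers or counts disagree between two companion objects."""


class ConfoundingError(HaploselectError):
    """Genotype and replicate effects are not separable in the trial design."""


class UndefinedLDError(HaploselectError):
    """LD requested for a monomorphic locus where r^2 is undefined."""


class ConstraintError(HaploselectError):
    """A candidate subset violates the exact-cardinality constraint."""


class ParameterError(HaploselectError):
    """An algorithm or model parameter is outside its valid domain."""


class EnumerationCapError(HaploselectError):
    """Brute-force enumeration refused: C(N, k) exceeds the configured cap."""
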