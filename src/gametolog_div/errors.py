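"""Exception hierarchy shared across the package."""


class GametologError(Exception):
    """Base class for all package errors."""


class AlignmentLengthError(GametologError):
    """Records of a supposed alignment do not share one length."""


class LabelError(GametologError):
    """A FASTA header does not parse under the allele-label grammar."""


class DataError(GametologError):
    """Structurally invalid genotype data (e.g. three alleles for one individual)."""


class SchemaError(GametologError):
    """Two recoded vectors do not share a character schema."""


class AnnotationError(GametologError):
    """Repeat/indel annotations are out of range or overlap."""


class MissingAlleleError(GametologError):
    """An individual with a missing allele was passed to a pairwise computation."""
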