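"""Exception hierarchy shared across the package."""


class Promoter5mcError(Exception):
    """Base class for all package errors."""


class ValidationError(Promoter5mcError, ValueError):
    """Input violates a precondition (bad alphabet, wrong central base, bad shape)."""


class FastaFormatError(Promoter5mcError, ValueError):
    """File is not well-formed FASTA (missing header, empty file)."""


class BoundaryError(Promoter5mcError, ValueError):
    """Requested window overhangs the end of its source sequence."""


class StratificationError(Promoter5mcError, ValueError):
    """A class is too small to split or stratify."""


class TrainingError(Promoter5mcError, ValueError):
    """Training input is unusable (single class, NaN features)."""


class UndefinedMetricError(Promoter5mcError, ValueError):
    """A metric is undefined for the given inputs (e.g. ROC with one class)."""


class IncompatibleModelError(Promoter5mcError, ValueError):
    """A model bundle cannot be loaded (truncated, missing parts, version mismatch)."""
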