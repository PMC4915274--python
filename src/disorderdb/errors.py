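"""Exception hierarchy shared across the pipeline."""


class DisorderDBError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(DisorderDBError):
    """Malformed FASTA input (junk before first header, empty sequence, illegal characters)."""


class PredictorParseError(DisorderDBError):
    """Malformed predictor score output."""


class AlignmentError(DisorderDBError):
    """A score track does not cover the protein sequence position-for-position.

    This guards against the silent-truncation hazard of disorder predictors
    that drop unsupported residue codes: a track of the wrong length must
    never be paired with a sequence.
    """


class SequenceError(DisorderDBError):
    """A sequence contains residues that are not eligible for the requested computation."""


class ConfigurationError(DisorderDBError):
    """Infeasible or inconsistent run/generator configuration."""


class DatabaseIntegrityError(DisorderDBError):
    """Inconsistent inputs handed to the database writer."""


class DatabaseFormatError(DisorderDBError):
    """A file that is not a database produced by this package."""


class PipelineError(DisorderDBError):
    """A pipeline stage failed; carries organism, accession and stage context."""

    def __init__(self, message: str, *, organism: str | None = None,
                 accession: str | None = None, stage: str | None = None):
        ctx = ", ".join(f"{k}={v}" for k, v in
                        (("organism", organism), ("accession", accession), ("stage", stage))
                        if v is not None)
        super().__init__(f"{message} [{ctx}]" if ctx else message)
        self.organism = organism
        self.accession = accession
        self.stage = stage
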