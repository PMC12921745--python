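"""Exception hierarchy for ptmfdr."""


class PtmFdrError(Exception):
    """Base class for all ptmfdr errors."""


class ConfigurationError(PtmFdrError):
    """A run/dialect/key-profile configuration is invalid or incomplete."""


class PSMTableError(PtmFdrError):
    """A PSM table cannot be read or a row cannot be parsed."""


class FastaError(PtmFdrError):
    """A FASTA file is malformed (e.g. empty sequence under a header)."""


class GammaEstimationError(PtmFdrError):
    """No threshold passes the error-propagation stability filter.

    Raised when every grid point has sigma above the cutoff (or no modified
    decoys at all); the remedy is a larger decoy population, typically by
    adding random (entrapment) proteins to the search database.
    """


class FitError(PtmFdrError):
    """Too few stable points to fit the requested gamma regression."""
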