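"""Exception hierarchy used across the toolkit."""


class TefamkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TefamkitError):
    """Malformed input file (Stockholm, FASTA, tree config, store layout)."""


class ParameterError(TefamkitError, ValueError):
    """Out-of-range or inconsistent parameter value."""


class LookupFailure(TefamkitError, KeyError):
    """A path, taxon, accession or other key could not be resolved."""
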