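"""Exception hierarchy shared across the toolkit."""


class PicotaxError(Exception):
    """Base class for all toolkit errors."""


class ParseError(PicotaxError):
    """Malformed input text (FASTA, newick, XML, TSV, PDB)."""


class ValidationError(PicotaxError):
    """Well-formed input that violates a domain invariant."""


class ConfigError(PicotaxError):
    """Invalid or incomplete pipeline configuration."""


class PipelineError(PicotaxError):
    """A pipeline stage could not run (missing inputs, bad wiring)."""
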