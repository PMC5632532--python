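"""Exception hierarchy for clonepop."""


class ClonePopError(Exception):
    """Base class for all clonepop errors."""


class FormatError(ClonePopError):
    """Malformed input file (bad column structure, unparseable token)."""


class EmptyTableError(ClonePopError):
    """An operation produced or received a table with no individuals."""


class PipelineAbortError(ClonePopError):
    """A pipeline stage cannot proceed (e.g. <2 loci survive QC)."""


class ConfigError(ClonePopError):
    """Invalid configuration value."""
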