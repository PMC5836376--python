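"""Exception hierarchy.

All package errors derive from :class:`LigandqError` so callers (and the
CLI) can distinguish configuration problems from data problems.
"""


class LigandqError(Exception):
    """Base class for all ligandq errors."""


class FormatError(LigandqError):
    """An input file does not conform to its expected tabular/FASTA format."""


class ConsistencyError(LigandqError):
    """Claimed peptide/protein coordinates disagree with the proteome."""


class ValidationError(LigandqError):
    """Inputs are well-formed but violate a contract (e.g. sample mismatch)."""


class NormalizationError(LigandqError):
    """A sample cannot be width-normalized (too few values or zero width)."""


class ZeroVarianceError(LigandqError):
    """A t statistic is undefined because the sample variance is zero."""


class ConfigError(LigandqError):
    """A pipeline configuration file is invalid."""


class SimulationError(LigandqError):
    """The synthetic-data generator could not satisfy its constraints."""
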