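"""Exception hierarchy for mrtwin.

All package errors derive from :class:`MrTwinError` so callers can catch one
type. Validation problems (bad config, malformed files, misaligned inputs)
map to CLI exit code 2; an empty instrument set maps to exit code 3.
"""


class MrTwinError(Exception):
    """Base class for all mrtwin errors."""


class ConfigError(MrTwinError, ValueError):
    """Invalid simulation or run configuration."""


class InvalidGenotypeError(MrTwinError, ValueError):
    """Genotype entry outside the additive coding {0, 1, 2}."""


class MendelianError(MrTwinError, ValueError):
    """Offspring genotype incompatible with parental genotypes."""


class DesignError(MrTwinError, ValueError):
    """Family data does not match the requested design (trio/duo/sibling)."""


class AlignmentError(MrTwinError, ValueError):
    """SNP or individual identifiers do not line up between inputs."""


class SchemaError(MrTwinError, ValueError):
    """A required column is missing or fails validation."""


class NoInstrumentsError(MrTwinError, RuntimeError):
    """Instrument selection returned the empty set; the test refuses to run."""
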