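"""Exception hierarchy for mirpopgen."""


class MirpopgenError(Exception):
    """Base class for all package errors."""


class AlignmentError(MirpopgenError):
    """Sequences of unequal length or otherwise malformed alignment."""


class AlphabetError(MirpopgenError):
    """Character outside the {A,C,G,T,-} alphabet."""


class SampleSizeError(MirpopgenError):
    """Fewer ingroup haplotypes than an operation requires."""


class CoordinateError(MirpopgenError):
    """Annotation intervals violate containment/disjointness rules."""


class InputError(MirpopgenError):
    """Malformed input table (duplicate ids, missing columns, ...)."""


class StructureError(MirpopgenError):
    """Unbalanced or inconsistent dot-bracket structure."""


class PolarizationError(MirpopgenError):
    """Outgroup required but absent."""


class SaturationError(MirpopgenError):
    """Jukes-Cantor correction undefined (p >= 3/4)."""


class ConfigError(MirpopgenError):
    """Inconsistent synthetic-data or pipeline configuration."""
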