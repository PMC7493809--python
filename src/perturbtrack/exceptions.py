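"""Exception hierarchy for perturbtrack."""


class PerturbTrackError(Exception):
    """Base class for all perturbtrack errors."""


class InputError(PerturbTrackError):
    """Malformed or out-of-contract input data."""


class CoordinateError(InputError):
    """A protein position falls outside [1, protein_length]."""


class MissingAnnotationError(InputError):
    """A requested annotation (e.g. ligand binding frequencies) is absent."""


class DegenerateTrackError(PerturbTrackError):
    """The track has zero score variance under its background, so no Z score exists."""


class UndefinedZError(PerturbTrackError):
    """A Z score was requested where the score standard deviation is zero."""


class CombinationError(PerturbTrackError):
    """The combined-score denominator is non-positive (pathological correlations)."""
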