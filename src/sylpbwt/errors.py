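"""Exception hierarchy shared across the package."""


class SylPBWTError(Exception):
    """Base class for all sylpbwt errors."""


class InputError(SylPBWTError, ValueError):
    """Malformed or inconsistent user input (panels, queries, maps, files)."""


class ThresholdError(SylPBWTError, ValueError):
    """Match-length cutoff L too small for the syllable size B.

    Finding *all* L-long matches at syllable resolution requires that every
    L-site interval contain at least one full syllable, i.e. B <= ceil(L/2).
    ``min_length`` carries the smallest admissible L (= 2B - 1 sites).
    """

    def __init__(self, message: str, min_length: int):
        super().__init__(message)
        self.min_length = min_length


class IndexIOError(SylPBWTError, IOError):
    """Persisted index container is missing, corrupt, or version-incompatible."""
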