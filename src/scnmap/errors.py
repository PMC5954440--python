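"""Exception hierarchy for scnmap.

Every error raised on a contract violation derives from :class:`ScnmapError`
so callers can catch pipeline failures without masking programming errors.
"""


class ScnmapError(Exception):
    """Base class for all scnmap errors."""


class ConfigurationError(ScnmapError, ValueError):
    """A cohort / analysis specification violates one of its invariants."""


class GeometryError(ScnmapError, ValueError):
    """Grid, affine or mask geometry mismatch between inputs."""


class DegenerateDesignError(ScnmapError, ValueError):
    """A regression design matrix is rank deficient or otherwise unusable."""


class ImageIOError(ScnmapError, IOError):
    """A volumetric image could not be read or written as required."""
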