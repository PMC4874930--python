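"""Exception hierarchy."""


class PetsegError(Exception):
    """Base class for all petseg errors."""


class VolumeIOError(PetsegError):
    """Unreadable file, unsupported format, or missing/invalid grid metadata."""


class GridMismatchError(PetsegError):
    """Two volumes that must share a grid (shape, spacing, origin) do not."""


class GraphError(PetsegError):
    """Invalid graph construction parameters."""


class DegenerateProfileError(PetsegError):
    """Shell profile carries no boundary evidence (e.g. seed in flat background)."""


class SeedError(PetsegError):
    """Seed point unusable: outside the volume, in background, or below threshold."""
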