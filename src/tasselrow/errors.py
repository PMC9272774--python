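"""Exception hierarchy for the tasselrow pipeline."""

from __future__ import annotations


class TasselRowError(Exception):
    """Base class for all tasselrow errors."""


class ConfigError(TasselRowError, ValueError):
    """Invalid parameter value or inconsistent configuration."""


class InvalidInputError(TasselRowError, ValueError):
    """Degenerate or malformed input image."""


class NoCropRowError(TasselRowError):
    """No strip on the given image side qualified as an initial region."""

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"no crop row found on side {side!r}")


class InsufficientPointsError(TasselRowError):
    """Too few feature points (or degenerate geometry) for a line fit."""

    def __init__(self, side: str, n_points: int, message: str | None = None):
        self.side = side
        self.n_points = n_points
        super().__init__(
            message
            or f"side {side!r}: {n_points} feature point(s) insufficient for a line fit"
        )


class DetectionError(TasselRowError):
    """A pipeline stage failed for a frame; carries the stage name and side."""

    def __init__(self, stage: str, side: str | None = None, message: str | None = None):
        self.stage = stage
        self.side = side
        where = stage if side is None else f"{stage} ({side})"
        super().__init__(message or f"detection failed at stage {where}")


class SceneGenerationError(TasselRowError):
    """Synthetic scene parameters are infeasible or failed the gamut self-check."""
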