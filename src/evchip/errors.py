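"""Exception hierarchy for the evchip pipeline.

Every stage raises a subclass of :class:`EvChipError` so that the
orchestrator can attach the stage name and re-raise with context.
"""


class EvChipError(Exception):
    """Base class for all evchip errors."""


class ConfigurationError(EvChipError):
    """An input configuration is internally inconsistent (bad panel/grid
    combination, negative amplitudes, zero-length injection, ...)."""


class LigandNotFoundError(EvChipError, KeyError):
    """A ligand name was looked up that does not exist in the layout."""


class FormatError(EvChipError):
    """A file on disk does not match the expected dialect (non-monotonic
    time axis, missing sidecar, NaN heights, missing ROI columns)."""


class WindowError(EvChipError):
    """An analysis window contains no samples or lies outside the trace."""


class QCError(EvChipError):
    """A quality-control check failed (e.g. plasmon minimum truncated at
    the edge of the scanned angle range)."""


class LevelingError(EvChipError):
    """Plane leveling could not classify any background pixels."""


class PlacementError(EvChipError):
    """Requested particle density too high to place without overlap."""


class NormalizationError(EvChipError):
    """Reference response non-positive in some experiment."""


class SelectionError(EvChipError):
    """No ligand is eligible as a normalization reference."""


class PoolingError(EvChipError):
    """Particle tables from different ligands/conditions cannot be pooled."""


class ComparisonError(EvChipError):
    """Profiles or particle sets being compared are incompatible."""


class StatisticsError(EvChipError):
    """A statistical quantity is undefined for the given input
    (empty sample, zero large-EV count in one condition, invalid p)."""


class PipelineError(EvChipError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
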