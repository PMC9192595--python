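"""Analysis configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .errors import ParameterError
from .histogram import default_bin_edges

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline, all in seconds/FRET units.

    ``histogram_window`` is the per-molecule stretch pooled into ensemble
    histograms (short movies); ``classification_window`` is the stretch over
    which a molecule must show a transition to count as transitioning (long
    movies). ``anchor_tolerance`` bounds how far anchored mixture centers may
    move from their protein-free values; 0 fixes them. ``leakage`` and
    ``gamma`` are the standard two-channel FRET corrections, off by default.
    """

    histogram_window: float = 2.0
    classification_window: float = 100.0
    fret_bin_width: float = 0.025
    fret_range: tuple = (-0.2, 1.2)
    anchor_tolerance: float = 0.01
    state_count_min: int = 2
    state_count_max: int = 4
    min_jump: float = 0.1
    leakage: float = 0.0
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.histogram_window > self.classification_window:
            raise ParameterError(
                "histogram_window must not exceed classification_window"
            )
        if self.anchor_tolerance < 0:
            raise ParameterError("anchor_tolerance must be >= 0")
        if self.fret_bin_width <= 0:
            raise ParameterError("fret_bin_width must be positive")
        if not 1 <= self.state_count_min <= self.state_count_max:
            raise ParameterError("invalid state count range")

    @property
    def bin_edges(self) -> np.ndarray:
        return default_bin_edges(
            self.fret_bin_width, self.fret_range[0], self.fret_range[1]
        )

    @property
    def k_range(self) -> tuple:
        return (self.state_count_min, self.state_count_max)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path, **overrides) -> AnalysisConfig:
    """Read a ``key: value`` config file; keyword overrides win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must map keys to values")
    if "fret_range" in data:
        data["fret_range"] = tuple(data["fret_range"])
    data.update(overrides)
    return AnalysisConfig(**data)
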