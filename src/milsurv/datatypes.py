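"""Core record types shared across modules."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyBagError, ParameterError


@dataclass
class SurvivalRecord:
    """Follow-up for one slide: observed time in months and death indicator."""

    time: float
    event: int

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ParameterError(f"time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ParameterError(f"event must be 0 or 1, got {self.event}")


@dataclass
class SlideBag:
    """One slide as a bag of patch embeddings with grid coordinates and labels.

    ``embeddings`` is an (N, d) array; ``coords`` an (N, 2) integer array of
    0-based (row, col) grid positions; ``tissue_class`` an (N,) array of
    string labels.
    """

    slide_id: str
    embeddings: np.ndarray
    coords: np.ndarray
    tissue_class: np.ndarray
    cohort_id: str = "unknown"

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        self.tissue_class = np.asarray(self.tissue_class, dtype=object)
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] == 0:
            raise EmptyBagError(f"slide {self.slide_id}: bag must hold >=1 patch")
        n = self.embeddings.shape[0]
        if self.coords.shape != (n, 2) or self.tissue_class.shape != (n,):
            raise ParameterError(
                f"slide {self.slide_id}: embeddings/coords/tissue_class misaligned")

    @property
    def n_patches(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class RiskPrediction:
    """Per-slide predicted risk; standardized score appears after fold z-scoring."""

    slide_id: str
    fold_id: int | None
    risk_raw: float
    risk_std: float | None = None
    attention: np.ndarray | None = field(default=None, repr=False)
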