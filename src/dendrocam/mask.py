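"""Binary trunk/background segmentation masks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["SegmentationMask"]


@dataclass(frozen=True)
class SegmentationMask:
    """Per-pixel trunk (1) / background (0) labels, optionally with the
    underlying trunk probability map.

    The labelling convention is ``label = 1  iff  probability >= threshold``
    (ties go to trunk); default threshold 0.5.
    """

    labels: np.ndarray
    probability: Optional[np.ndarray] = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"labels must be 2-D (H, W), got shape {labels.shape}")
        vals = np.unique(labels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"labels must be binary 0/1, found values {vals}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        if self.probability is not None:
            prob = np.asarray(self.probability, dtype=np.float64)
            if prob.shape != labels.shape:
                raise ValueError(
                    f"probability shape {prob.shape} != labels shape {labels.shape}"
                )
            if prob.min() < 0 or prob.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")
            if not np.array_equal((prob >= self.threshold).astype(np.uint8), labels):
                raise ValueError(
                    "labels inconsistent with probability >= threshold convention"
                )
            object.__setattr__(self, "probability", prob)

    @classmethod
    def from_probability(
        cls, probability: np.ndarray, threshold: float = 0.5
    ) -> "SegmentationMask":
        prob = np.asarray(probability, dtype=np.float64)
        return cls(
            labels=(prob >= threshold).astype(np.uint8),
            probability=prob,
            threshold=threshold,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def trunk_fraction_of_row(self, row: int) -> float:
        """Fraction of the given row labelled trunk (diagnostic)."""
        return float(self.labels[row].mean())
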