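"""Consistency indicators between original and noise-added survivor maps.

Both indicators compare two binary survivor maps from the same method, one
from the original dataset and one after noise injection:

* false alarm rate = |noisy AND NOT orig| / |noisy| — the fraction of
  noisy-analysis detections absent from the original analysis (an FDR
  analogue, treating the original map as reference);
* hit rate = |noisy AND orig| / |orig| — the fraction of original
  detections retained (a sensitivity analogue).

A rate with an empty denominator is undefined: it is returned as ``None``
(recorded as missing downstream) rather than imputed, since forcing 0 or 1
would bias method comparisons asymmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ConsistencyRecord", "false_alarm_rate", "hit_rate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsistencyRecord:
    """One (method, repetition) pair's false-alarm and hit rates."""

    method: str
    repetition: int
    false_alarm: float | None
    hit: float | None

    def __post_init__(self) -> None:
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        for name in ("false_alarm", "hit"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _as_bool_pair(orig, noisy) -> tuple[np.ndarray, np.ndarray]:
    orig = np.asarray(orig, dtype=bool)
    noisy = np.asarray(noisy, dtype=bool)
    if orig.shape != noisy.shape:
        raise ValueError(
            f"survivor maps have different shapes: {orig.shape} vs {noisy.shape}"
        )
    return orig, noisy


def false_alarm_rate(orig, noisy) -> float | None:
    """|noisy & ~orig| / |noisy|, or None when the noisy map is empty."""
    orig, noisy = _as_bool_pair(orig, noisy)
    denom = int(noisy.sum())
    if denom == 0:
        logger.warning("false alarm rate undefined: noisy survivor map is empty")
        return None
    return float((noisy & ~orig).sum() / denom)


def hit_rate(orig, noisy) -> float | None:
    """|noisy & orig| / |orig|, or None when the original map is empty."""
    orig, noisy = _as_bool_pair(orig, noisy)
    denom = int(orig.sum())
    if denom == 0:
        logger.warning("hit rate undefined: original survivor map is empty")
        return None
    return float((noisy & orig).sum() / denom)
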