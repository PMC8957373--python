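"""Inverse-frequency error weights over 10% SO2 bins.

Occlusion protocols produce an uneven distribution of reference SO2
targets (mid-range values dominate; the extremes near 0% and 100% are
visited only briefly).  To keep the regression from fitting the bulk at
the expense of the tails, each 10% bin receives a weight proportional to
1/count, normalized so the largest weight is 1.  Bins are half-open
[10k, 10(k+1)) with the last bin closed at 100; out-of-range targets
(the reference can report slightly below 0 or above 100) clamp into the
edge bins rather than being discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WeightVector", "compute_weight_vector", "lookup_weights", "bin_index"]

logger = logging.getLogger(__name__)

N_BINS = 10
BIN_WIDTH = 10.0


def bin_index(targets: np.ndarray) -> np.ndarray:
    """Map SO2 targets (%) to bin indices 0..9, clamping out-of-range."""
    t = np.asarray(targets, dtype=np.float64)
    idx = np.floor(t / BIN_WIDTH).astype(int)
    return np.clip(idx, 0, N_BINS - 1)


@dataclass(frozen=True)
class WeightVector:
    """Per-bin inverse-frequency weights: edges 0,10,...,100; weight
    (1/count) / max over occupied bins; empty bins carry weight 0."""

    counts: np.ndarray
    weights: np.ndarray

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, 100.0 + BIN_WIDTH, BIN_WIDTH)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame({
            "bin_lo": edges[:-1], "bin_hi": edges[1:],
            "count": self.counts, "weight": self.weights,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeightVector":
        df = pd.read_csv(path)
        return cls(counts=df["count"].to_numpy(int),
                   weights=df["weight"].to_numpy(float))


def compute_weight_vector(targets: np.ndarray) -> WeightVector:
    """Bin targets in 10% intervals and build the inverse-count weights."""
    t = np.asarray(targets, dtype=np.float64)
    if t.size == 0:
        raise ValueError("targets must be nonempty")
    counts = np.bincount(bin_index(t), minlength=N_BINS)
    occupied = counts > 0
    inv = np.zeros(N_BINS)
    inv[occupied] = 1.0 / counts[occupied]
    weights = inv / inv.max()
    if not occupied.all():
        logger.warning("empty SO2 bins (weight 0): %s",
                       np.flatnonzero(~occupied).tolist())
    return WeightVector(counts=counts, weights=weights)


def lookup_weights(w: WeightVector, targets: np.ndarray) -> np.ndarray:
    """Per-sample weight: each target mapped to its bin's weight."""
    idx = bin_index(targets)
    out = w.weights[idx]
    if np.any(out == 0):
        logger.warning("%d target(s) fall in empty bins and get weight 0",
                       int(np.sum(out == 0)))
    return out
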