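"""From reflectance cubes to normalized 16-channel spectra.

Each cube pixel yields a 16-channel spectrum.  Spectra are normalized to
their mean intensity (removing overall brightness, keeping shape), and
collected into a :class:`SpectrumSet` — a thin wrapper over a pandas
DataFrame with one row per spectrum plus its regression target (reference
SO2 in %), subject id, provocation label, timestamp, per-sample error
weight and train/val/test/evaluation split tag.

Training spectra are drawn as a handful of random pixels per cube from a
region of interest near the reference probe; ROI-mean spectra serve the
probe-comparison analyses; a simple brightness threshold masks the arm
from the background for whole-image prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mosaic import CubeStage, DataCube, N_BANDS

__all__ = [
    "ROI",
    "SpectrumSet",
    "BAND_COLUMNS",
    "normalize_spectrum",
    "normalize_rows",
    "sample_roi_pixels",
    "roi_mean_spectrum",
    "mask_foreground",
    "pair_with_reference",
]

BAND_COLUMNS = [f"band_{b:02d}" for b in range(N_BANDS)]
META_COLUMNS = ["target_so2", "subject_id", "provocation", "timestamp_s",
                "weight", "split"]


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle [row0, row1) x [col0, col1) in binned
    cube coordinates, labelled by its quadrant id."""

    row0: int
    row1: int
    col0: int
    col1: int
    label: str = "q0"

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI rectangle must have positive extent")

    @property
    def area(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def validate_within(self, shape: tuple[int, ...]) -> None:
        rows, cols = shape[0], shape[1]
        if self.row0 < 0 or self.col0 < 0 or self.row1 > rows or self.col1 > cols:
            raise ValueError(f"ROI {self} outside cube bounds {(rows, cols)}")


class SpectrumSet:
    """Collection of mean-normalized spectra with targets and metadata.

    Backed by a DataFrame whose band columns (``band_00`` .. ``band_15``)
    each hold a spectrum row-normalized to mean 1.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in BAND_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing band columns: {missing}")
        for col in META_COLUMNS:
            if col not in frame.columns:
                frame = frame.assign(**{col: np.nan})
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """N x 16 matrix of mean-normalized spectra."""
        return self.frame[BAND_COLUMNS].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        """Reference SO2 targets in %."""
        return self.frame["target_so2"].to_numpy(dtype=np.float64)

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=np.float64)

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(self.frame.loc[np.asarray(mask)].copy())

    @staticmethod
    def concat(parts: list["SpectrumSet"]) -> "SpectrumSet":
        return SpectrumSet(pd.concat([p.frame for p in parts], ignore_index=True))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumSet":
        return cls(pd.read_csv(path))


def normalize_spectrum(raw16: np.ndarray) -> np.ndarray:
    """Scale a 16-vector to mean intensity 1 (shape preserved)."""
    v = np.asarray(raw16, dtype=np.float64)
    if v.shape != (N_BANDS,):
        raise ValueError(f"expected a {N_BANDS}-vector, got shape {v.shape}")
    m = v.mean()
    if m <= 0:
        raise ValueError("spectrum mean must be positive")
    return v / m


def normalize_rows(spectra: np.ndarray) -> np.ndarray:
    """Row-wise mean normalization of an N x 16 matrix."""
    spectra = np.asarray(spectra, dtype=np.float64)
    means = spectra.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise ValueError("every spectrum must have positive mean")
    return spectra / means


def sample_roi_pixels(cube: DataCube, roi: ROI, n: int = 10,
                      rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw ``n`` distinct ROI pixels and return their normalized spectra.

    Sampling is uniform without replacement within the cube (independent
    draws across cubes when a shared generator is passed).  Returns a
    DataFrame with band columns plus pixel coordinates and the cube
    timestamp; targets/weights are attached later.
    """
    if cube.stage is not CubeStage.REFLECTANCE:
        raise ValueError("sampling requires a reflectance-stage cube")
    roi.validate_within(cube.shape)
    if roi.area < n:
        raise ValueError(f"ROI area {roi.area} < requested n={n}")
    rng = np.random.default_rng(rng)
    flat = rng.choice(roi.area, size=n, replace=False)
    rr = roi.row0 + flat // (roi.col1 - roi.col0)
    cc = roi.col0 + flat % (roi.col1 - roi.col0)
    spectra = normalize_rows(cube.values[rr, cc, :])
    df = pd.DataFrame(spectra, columns=BAND_COLUMNS)
    df["pixel_row"] = rr
    df["pixel_col"] = cc
    df["timestamp_s"] = cube.timestamp
    return df


def roi_mean_spectrum(cube: DataCube, roi: ROI) -> np.ndarray:
    """Per-band mean over the ROI, then mean-intensity normalized."""
    if cube.stage is not CubeStage.REFLECTANCE:
        raise ValueError("ROI mean requires a reflectance-stage cube")
    roi.validate_within(cube.shape)
    block = cube.values[roi.row0:roi.row1, roi.col0:roi.col1, :]
    return normalize_spectrum(block.reshape(-1, N_BANDS).mean(axis=0))


def mask_foreground(cube: DataCube, threshold: float) -> np.ndarray:
    """Boolean map: pixel kept iff its mean reflectance exceeds threshold.

    Drives whole-image prediction; an all-false mask is allowed.
    """
    if cube.stage is not CubeStage.REFLECTANCE:
        raise ValueError("masking requires a reflectance-stage cube")
    return cube.values.mean(axis=2) > threshold


def pair_with_reference(timestamps_s: np.ndarray, ref_times_s: np.ndarray,
                        ref_so2: np.ndarray) -> np.ndarray:
    """Target for each spectrum: the reference sample nearest in time.

    The imager (~1.4 fps) and the probe (1 Hz) run on independent clocks;
    both signals vary slowly relative to half the probe interval, so a
    nearest-timestamp match (ties to the earlier sample) is used.
    """
    t = np.asarray(timestamps_s, dtype=np.float64)
    rt = np.asarray(ref_times_s, dtype=np.float64)
    idx = np.searchsorted(rt, t)
    idx = np.clip(idx, 1, len(rt) - 1)
    left, right = rt[idx - 1], rt[idx]
    use_left = (t - left) <= (right - t)  # ties go to the earlier sample
    nearest = np.where(use_left, idx - 1, idx)
    return np.asarray(ref_so2, dtype=np.float64)[nearest]
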