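"""Snapshot filter-mosaic sensor model and raw-frame preprocessing.

A snapshot multispectral camera covers its monochrome sensor with a
repeating 4x4 mosaic of 16 spectral filters, so a single exposure holds
all 16 bands as interleaved sparse samples.  This module turns such raw
frames into calibrated reflectance data cubes:

    dark_correct -> demosaic_wbi -> bin_spatial -> white_normalize

Cubes are band-last float arrays (``rows x cols x 16``) carried in a
:class:`DataCube` with an explicit processing ``stage``.  Cube I/O uses
multi-page 32-bit float TIFF stacks (one page per band) with a YAML
sidecar for metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.ndimage import convolve1d

__all__ = [
    "FilterLayout",
    "RawMosaicFrame",
    "CubeStage",
    "DataCube",
    "dark_correct",
    "sum_snapshots",
    "demosaic_wbi",
    "bin_spatial",
    "white_normalize",
    "preprocess",
    "save_cube",
    "load_cube",
]

N_BANDS = 16
PATTERN_SIZE = 4


@dataclass(frozen=True)
class FilterLayout:
    """Repeating 4x4 arrangement of the 16 band indices on the sensor.

    ``pattern[r, c]`` is the band index recorded by sensor pixels whose
    coordinates are congruent to ``(r, c)`` modulo 4 after subtracting
    ``origin``.  Each band index must occur exactly once, so tiling the
    pattern covers the sensor with every pixel mapped to one band.
    """

    pattern: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        pat = np.asarray(self.pattern, dtype=int)
        if pat.shape != (PATTERN_SIZE, PATTERN_SIZE):
            raise ValueError(f"pattern must be 4x4, got {pat.shape}")
        if sorted(pat.ravel().tolist()) != list(range(N_BANDS)):
            raise ValueError("pattern must contain each band index 0-15 exactly once")
        object.__setattr__(self, "pattern", pat)

    @classmethod
    def default(cls) -> "FilterLayout":
        """Row-major band order; the real sensor's order is configurable."""
        return cls(pattern=np.arange(N_BANDS).reshape(PATTERN_SIZE, PATTERN_SIZE))

    def band_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel band index for a sensor of the given (rows, cols)."""
        rows, cols = shape
        r0, c0 = self.origin
        rr = (np.arange(rows)[:, None] - r0) % PATTERN_SIZE
        cc = (np.arange(cols)[None, :] - c0) % PATTERN_SIZE
        return self.pattern[rr, cc]

    def band_offsets(self, band: int) -> tuple[int, int]:
        """(row, col) of the native lattice of ``band`` within a tile."""
        pos = np.argwhere(self.pattern == band)
        r, c = pos[0]
        return (int((r + self.origin[0]) % PATTERN_SIZE),
                int((c + self.origin[1]) % PATTERN_SIZE))


@dataclass
class RawMosaicFrame:
    """One mosaic exposure: a rows x cols nonnegative intensity grid.

    ``exposure_count`` records how many consecutive snapshots were summed
    into this frame (16 on the real system, to reduce noise).
    """

    values: np.ndarray
    layout: FilterLayout = field(default_factory=FilterLayout.default)
    exposure_count: int = 16
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("frame values must be 2-D")
        if v.shape[0] % PATTERN_SIZE or v.shape[1] % PATTERN_SIZE:
            raise ValueError(
                f"frame dimensions {v.shape} must be divisible by {PATTERN_SIZE}")
        if not np.all(np.isfinite(v)):
            raise ValueError("frame values must be finite")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class CubeStage(str, enum.Enum):
    DEMOSAICED = "demosaiced"
    BINNED = "binned"
    REFLECTANCE = "reflectance"


@dataclass
class DataCube:
    """rows x cols x 16 spectral cube with an explicit processing stage."""

    values: np.ndarray
    stage: CubeStage
    wavelength_band_ids: list[int] = field(default_factory=lambda: list(range(N_BANDS)))
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[2] != N_BANDS:
            raise ValueError(f"cube must be rows x cols x {N_BANDS}, got {v.shape}")
        self.values = v
        self.stage = CubeStage(self.stage)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def dark_correct(frame: RawMosaicFrame, dark: RawMosaicFrame) -> RawMosaicFrame:
    """Subtract a dark frame, clamping negatives to zero.

    Intensities are physical, so residual noise driving a pixel below the
    dark level is clipped rather than propagated as negative reflectance.
    """
    if frame.shape != dark.shape:
        raise ValueError(f"frame shape {frame.shape} != dark shape {dark.shape}")
    corrected = np.maximum(frame.values - dark.values, 0.0)
    return replace(frame, values=corrected)


def sum_snapshots(frames: list[RawMosaicFrame]) -> RawMosaicFrame:
    """Sum consecutive snapshots into one frame (noise reduction)."""
    if not frames:
        raise ValueError("cannot sum an empty list of frames")
    first = frames[0]
    total = np.zeros_like(first.values)
    for f in frames:
        if f.shape != first.shape:
            raise ValueError("all frames must share the same shape")
        total = total + f.values
    return replace(first, values=total, exposure_count=len(frames))


def _triangle_kernel(step: int) -> np.ndarray:
    """1-D bilinear (triangle) kernel for a lattice of the given stride.

    Shifted copies at stride ``step`` form a partition of unity, which
    makes the separable 2-D interpolation exact on affine images.
    """
    taps = np.arange(-(step - 1), step)
    return 1.0 - np.abs(taps) / step


def demosaic_wbi(frame: RawMosaicFrame) -> DataCube:
    """Weighted-bilinear demosaicing of a mosaic frame into a full cube.

    Per band, the native samples sit on a stride-4 lattice; missing pixels
    are filled by separable bilinear interpolation with weights normalized
    over the native samples actually present (normalized convolution).
    Native samples are reproduced exactly; near the sensor border, where
    part of the bilinear support falls outside, the remaining weights are
    renormalized to sum to one.
    """
    rows, cols = frame.shape
    if rows < PATTERN_SIZE or cols < PATTERN_SIZE:
        raise ValueError("frame smaller than one full mosaic tile")
    band_map = frame.layout.band_map((rows, cols))
    kern = _triangle_kernel(PATTERN_SIZE)
    out = np.empty((rows, cols, N_BANDS), dtype=np.float64)
    for b in range(N_BANDS):
        native = band_map == b
        sparse = np.where(native, frame.values, 0.0)
        mask = native.astype(np.float64)
        num = convolve1d(sparse, kern, axis=0, mode="constant")
        num = convolve1d(num, kern, axis=1, mode="constant")
        den = convolve1d(mask, kern, axis=0, mode="constant")
        den = convolve1d(den, kern, axis=1, mode="constant")
        out[:, :, b] = num / den
    return DataCube(values=out, stage=CubeStage.DEMOSAICED, timestamp=frame.timestamp)


def bin_spatial(cube: DataCube, factor: int = 4) -> DataCube:
    """Average non-overlapping ``factor x factor`` blocks per band.

    The mean (rather than the sum) keeps the intensity scale independent
    of the binning factor; the subsequent white-normalization ratio is
    unaffected either way.
    """
    if cube.stage is not CubeStage.DEMOSAICED:
        raise ValueError(f"expected a demosaiced cube, got stage={cube.stage.value}")
    rows, cols, nb = cube.shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"cube dimensions ({rows}, {cols}) not divisible by factor {factor}")
    v = cube.values.reshape(rows // factor, factor, cols // factor, factor, nb)
    binned = v.mean(axis=(1, 3))
    return DataCube(values=binned, stage=CubeStage.BINNED,
                    wavelength_band_ids=cube.wavelength_band_ids,
                    timestamp=cube.timestamp)


def white_normalize(cube: DataCube, white: DataCube) -> DataCube:
    """Divide by a white-reference cube, yielding dimensionless reflectance."""
    if cube.stage is not CubeStage.BINNED or white.stage is not CubeStage.BINNED:
        raise ValueError("both cubes must be at the binned stage")
    if cube.shape != white.shape:
        raise ValueError(f"cube shape {cube.shape} != white shape {white.shape}")
    nonpos = white.values <= 0
    if np.any(nonpos):
        bad_bands = sorted(set(np.argwhere(nonpos)[:, 2].tolist()))
        raise ValueError(
            f"white reference has non-positive values in band(s) {bad_bands}")
    return DataCube(values=cube.values / white.values, stage=CubeStage.REFLECTANCE,
                    wavelength_band_ids=cube.wavelength_band_ids,
                    timestamp=cube.timestamp)


def preprocess(frame: RawMosaicFrame, dark: RawMosaicFrame,
               white: DataCube, bin_factor: int = 4) -> DataCube:
    """Full chain: dark correction, demosaicing, binning, white normalization.

    ``white`` must already be a binned cube (preprocess the white-reference
    frame once with :func:`preprocess_reference`).
    """
    corrected = dark_correct(frame, dark)
    cube = bin_spatial(demosaic_wbi(corrected), factor=bin_factor)
    return white_normalize(cube, white)


def preprocess_reference(white_frame: RawMosaicFrame, dark: RawMosaicFrame,
                         bin_factor: int = 4) -> DataCube:
    """Dark-correct, demosaic and bin a white-reference frame."""
    return bin_spatial(demosaic_wbi(dark_correct(white_frame, dark)),
                       factor=bin_factor)


def save_cube(cube: DataCube, path: str | Path) -> None:
    """Write a cube as a multi-page float32 TIFF plus a YAML sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.values.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "stage": cube.stage.value,
        "wavelength_band_ids": list(map(int, cube.wavelength_band_ids)),
        "timestamp": float(cube.timestamp),
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def load_cube(path: str | Path) -> DataCube:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    values = np.moveaxis(np.asarray(pages, dtype=np.float64), 0, 2)
    return DataCube(values=values, stage=CubeStage(meta["stage"]),
                    wavelength_band_ids=meta["wavelength_band_ids"],
                    timestamp=meta["timestamp"])
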