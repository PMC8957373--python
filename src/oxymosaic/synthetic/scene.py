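"""Spatial scene rendering: from subject physiology to raw mosaic frames.

A measurement series emulates one provocation on one subject: an
elliptical "arm" on a dark background, mild spatial heterogeneity in
RBC fraction, melanin and SO2, a probe site distinct from the imaging
ROI (the probe sits distally on real arms, so its SO2 differs from the
ROI's by a configurable offset), multiplicative sensor noise on each
summed frame, interleaved dark frames, a white-reference frame, and the
1-Hz reference trace.

Scenes are rendered constant over each 4x4 mosaic tile (i.e., at the
binned resolution), which keeps rendering fast and makes the noiseless
preprocessing chain exactly invertible away from tile edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..mosaic import FilterLayout, RawMosaicFrame
from ..sampling import ROI
from .optics import FilterBank, forward_reflectance, sensor_response, white_response
from .protocol import (ReferenceTrace, OcclusionProtocol, SubjectParams,
                       occlusion_timecourse)

__all__ = ["Profile", "NoiseConfig", "DESK_PROFILE", "FULL_SCALE_PROFILE",
           "Measurement", "render_measurement"]

BACKGROUND_REFLECTANCE = 0.02


@dataclass(frozen=True)
class Profile:
    """Rendering scale.  The desk profile keeps the full pipeline fast
    enough for routine testing; the full-scale profile reproduces the
    real sensor geometry and cube counts."""

    frame_shape: tuple[int, int] = (64, 64)     # (rows, cols), divisible by 4
    n_cubes: int = 100                          # cubes per provocation
    protocol: OcclusionProtocol = field(default_factory=OcclusionProtocol)
    store_maps: bool = True

    @property
    def binned_shape(self) -> tuple[int, int]:
        return (self.frame_shape[0] // 4, self.frame_shape[1] // 4)


DESK_PROFILE = Profile()
FULL_SCALE_PROFILE = Profile(frame_shape=(1088, 2048), n_cubes=760, store_maps=False)


@dataclass(frozen=True)
class NoiseConfig:
    """All stochastic imperfections of the testbed, in one place.

    ``sensor_noise_sd`` is the relative SD of multiplicative noise per
    summed frame; ``reference_rms`` the RMS deviation (%) of the
    reference trace from the probe-site truth; ``site_mismatch_sd`` the
    SD (%) of the per-subject probe-vs-ROI SO2 offset.  The three
    ``*_sd`` spatial terms control scene heterogeneity; zeroing the
    whole config gives a deterministic, homogeneous measurement.
    """

    sensor_noise_sd: float = 0.01
    dark_level: float = 50.0
    dark_noise_sd: float = 0.5
    white_noise_sd: float = 0.002
    reference_rms: float = 5.0
    site_mismatch_sd: float = 3.0
    so2_spatial_sd: float = 2.0
    frbc_rel_sd: float = 0.15
    mel_rel_sd: float = 0.10
    jitter_sd: float = 1.0

    @classmethod
    def zeroed(cls) -> "NoiseConfig":
        return cls(sensor_noise_sd=0.0, dark_noise_sd=0.0, white_noise_sd=0.0,
                   reference_rms=0.0, site_mismatch_sd=0.0, so2_spatial_sd=0.0,
                   frbc_rel_sd=0.0, mel_rel_sd=0.0, jitter_sd=0.0)


@dataclass
class Measurement:
    """One provocation's rendered data plus its ground truth."""

    frames: list[RawMosaicFrame]
    dark: RawMosaicFrame
    white_frame: RawMosaicFrame
    reference: ReferenceTrace
    timestamps_s: np.ndarray
    rois: dict[str, ROI]
    probe_roi: str
    arm_mask: np.ndarray                  # binned-resolution boolean map
    roi_truth: np.ndarray                 # per-cube mean true SO2 (%) in probe ROI
    so2_maps: np.ndarray | None           # n_cubes x R x C true SO2 (%), if stored
    true_channels: np.ndarray | None      # n_cubes x R x C x 16 noiseless DU
    white_channels: np.ndarray            # per-band white level (DU)
    params: SubjectParams
    provocation: str


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-SD smooth random field for spatial heterogeneity."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 8.0,
                        mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _quadrant_rois(shape: tuple[int, int]) -> dict[str, ROI]:
    r4, c4 = shape[0] // 4, shape[1] // 4
    return {
        "q0": ROI(r4, 2 * r4, c4, 2 * c4, "q0"),
        "q1": ROI(r4, 2 * r4, 2 * c4, 3 * c4, "q1"),
        "q2": ROI(2 * r4, 3 * r4, c4, 2 * c4, "q2"),
        "q3": ROI(2 * r4, 3 * r4, 2 * c4, 3 * c4, "q3"),
    }


def render_measurement(params: SubjectParams, provocation: str,
                       bank: FilterBank,
                       layout: FilterLayout | None = None,
                       noise: NoiseConfig = NoiseConfig(),
                       rng: np.random.Generator | int | None = None,
                       profile: Profile = DESK_PROFILE,
                       keep_true_channels: bool = False) -> Measurement:
    """Render one subject/provocation into raw frames plus ground truth."""
    rng = np.random.default_rng(rng)
    layout = layout or FilterLayout.default()
    rows, cols = profile.frame_shape
    R, C = profile.binned_shape
    protocol = profile.protocol

    # --- static scene fields (binned resolution, constant per 4x4 tile)
    yy, xx = np.mgrid[0:R, 0:C]
    arm_mask = (((yy - R / 2 + 0.5) / (0.47 * R)) ** 2
                + ((xx - C / 2 + 0.5) / (0.47 * C)) ** 2) <= 1.0
    so2_spatial = noise.so2_spatial_sd * _smooth_field(rng, (R, C))
    mel_map = params.melanin * np.clip(
        1.0 + noise.mel_rel_sd * _smooth_field(rng, (R, C)), 0.1, None)
    frbc_base = params.f_rbc * np.clip(
        1.0 + noise.frbc_rel_sd * _smooth_field(rng, (R, C)), 0.1, None)

    # --- time courses on a common fine grid
    master_t = np.arange(0.0, protocol.window_end_s + 0.5, 0.5)
    so2_master, frbc_master = occlusion_timecourse(
        provocation, params, master_t, protocol, rng=rng,
        jitter_sd=noise.jitter_sd)
    timestamps = (np.arange(profile.n_cubes) + 0.5) \
        * protocol.window_end_s / profile.n_cubes
    so2_t = np.interp(timestamps, master_t, so2_master)
    frbc_t = np.interp(timestamps, master_t, frbc_master)

    # --- reference trace from the probe-site truth
    ref_times = np.arange(0.0, protocol.window_end_s + 1.0, 1.0)
    probe_truth = np.interp(ref_times, master_t, so2_master) - params.site_offset
    reference = ReferenceTrace(times_s=ref_times,
                     so2=probe_truth + rng.normal(0.0, noise.reference_rms,
                                                  ref_times.size),
                     truth=probe_truth)

    # --- sensor gain and reference frames
    white = white_response(bank)
    gain = 3000.0 / white.max()
    white_channels = gain * white
    band_map = layout.band_map((rows, cols))
    ii = np.arange(rows)[:, None] // 4
    jj = np.arange(cols)[None, :] // 4

    def expand(channels: np.ndarray) -> np.ndarray:
        """Binned-resolution 16-channel image -> full-resolution mosaic."""
        return channels[ii, jj, band_map]

    dark = RawMosaicFrame(
        values=np.maximum(noise.dark_level
                          + rng.normal(0.0, noise.dark_noise_sd, (rows, cols)), 0.0),
        layout=layout, exposure_count=16, timestamp=-1.0)
    white_full = expand(np.broadcast_to(white_channels, (R, C, 16)).copy())
    white_frame = RawMosaicFrame(
        values=white_full * (1.0 + rng.normal(0.0, noise.white_noise_sd,
                                              (rows, cols))) + noise.dark_level,
        layout=layout, exposure_count=16, timestamp=-2.0)

    bg_channels = gain * sensor_response(
        np.full_like(bank.wavelengths_nm, BACKGROUND_REFLECTANCE), bank)

    probe_roi = "q0"
    rois = _quadrant_rois((R, C))
    roi = rois[probe_roi]

    frames: list[RawMosaicFrame] = []
    roi_truth = np.empty(profile.n_cubes)
    so2_maps = np.empty((profile.n_cubes, R, C)) if profile.store_maps else None
    true_channels = (np.empty((profile.n_cubes, R, C, 16))
                     if keep_true_channels else None)
    for k, t in enumerate(timestamps):
        so2_map = np.clip(so2_t[k] + so2_spatial, 0.0, 100.0)
        refl = forward_reflectance(so2_map / 100.0, frbc_base * frbc_t[k],
                                   mel_map, params.path_length_mm,
                                   params.scatter_scale, bank.wavelengths_nm)
        channels = gain * sensor_response(refl, bank)
        channels[~arm_mask] = bg_channels
        signal = expand(channels)
        if noise.sensor_noise_sd > 0:
            signal = signal * (1.0 + rng.normal(0.0, noise.sensor_noise_sd,
                                                signal.shape))
        frames.append(RawMosaicFrame(values=signal + noise.dark_level,
                                     layout=layout, exposure_count=16,
                                     timestamp=float(t)))
        roi_truth[k] = so2_map[roi.row0:roi.row1, roi.col0:roi.col1].mean()
        if so2_maps is not None:
            so2_maps[k] = np.where(arm_mask, so2_map, np.nan)
        if true_channels is not None:
            true_channels[k] = channels

    return Measurement(frames=frames, dark=dark, white_frame=white_frame,
                       reference=reference, timestamps_s=timestamps, rois=rois,
                       probe_roi=probe_roi, arm_mask=arm_mask,
                       roi_truth=roi_truth, so2_maps=so2_maps,
                       true_channels=true_channels,
                       white_channels=white_channels, params=params,
                       provocation=provocation)
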