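"""Occlusion provocation time courses and the probe-like reference trace.

The emulated protocol follows the standard forearm cuff experiment: a
baseline plateau, 5 min of cuff occlusion, and release.  The analysis
timeline starts 1 min before occlusion (t = 0), so occlusion runs from
60 s to 360 s and the rendered window ends 3 min after release (540 s).

Arterial occlusion (suprasystolic cuff) drives tissue SO2 exponentially
toward a floor of a few percent and the rapid release produces a
reactive-hyperemia overshoot toward 75-96% before relaxing back.
Venous occlusion (cuff ~45 mmHg) blocks only venous return: SO2 declines
moderately (floor 18-49%), RBC tissue fraction rises from pooling, and
the release rebound is modest.  Cohort parameter ranges are calibrated
so the reference statistics of the three protocol phases resemble those
reported for real occlusion cohorts (baseline ~56 +/- 10%, arterial end
of occlusion ~0-5%, reperfusion peak up to ~96%).

The reference trace emulates a validated probe at 1 Hz whose output
deviates from the probe-site truth by ~5% RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["OcclusionProtocol", "SubjectParams", "ReferenceTrace",
           "draw_subject_params", "occlusion_timecourse", "reference_trace"]


@dataclass(frozen=True)
class OcclusionProtocol:
    """Timing of the analysis window (seconds)."""

    occlusion_start_s: float = 60.0
    occlusion_end_s: float = 360.0
    window_end_s: float = 540.0

    # Bland-Altman phase windows
    @property
    def baseline_window(self) -> tuple[float, float]:
        return (self.occlusion_start_s - 60.0, self.occlusion_start_s - 5.0)

    @property
    def end_occlusion_window(self) -> tuple[float, float]:
        return (self.occlusion_end_s - 60.0, self.occlusion_end_s - 10.0)

    @property
    def release_window(self) -> tuple[float, float]:
        # 5 s before release to 50 s after: a 55-s window (355-410 s for
        # the default timeline) capturing the early reperfusion peak
        return (self.occlusion_end_s - 5.0, self.occlusion_end_s + 50.0)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiology and optics for the forward model."""

    baseline_so2: float            # %
    arterial_floor: float          # % at end of arterial occlusion
    venous_floor: float            # % at end of venous occlusion
    reperfusion_peak: float        # % hyperemia peak after arterial release
    venous_rebound: float          # % overshoot above baseline after venous release
    tau_arterial_s: float          # occlusion decay time constant
    tau_venous_s: float
    f_rbc: float                   # baseline RBC tissue fraction
    melanin: float                 # melanin absorption scale (mm^-1 at 550 nm)
    scatter_scale: float
    path_length_mm: float
    site_offset: float             # probe-site minus ROI SO2 offset (%)
    seed: int

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def draw_subject_params(rng: np.random.Generator,
                        site_mismatch_sd: float = 3.0,
                        seed: int | None = None) -> SubjectParams:
    """One subject from the cohort distribution."""
    return SubjectParams(
        baseline_so2=float(np.clip(rng.normal(56.0, 7.0), 39.0, 75.0)),
        arterial_floor=float(rng.uniform(0.2, 4.0)),
        venous_floor=float(rng.uniform(18.0, 49.0)),
        reperfusion_peak=float(rng.uniform(75.0, 96.0)),
        venous_rebound=float(rng.uniform(2.0, 8.0)),
        tau_arterial_s=float(rng.uniform(45.0, 70.0)),
        tau_venous_s=float(rng.uniform(90.0, 130.0)),
        f_rbc=float(rng.uniform(0.006, 0.015)),
        melanin=float(rng.uniform(0.05, 0.30)),
        scatter_scale=float(rng.uniform(0.85, 1.15)),
        path_length_mm=float(rng.uniform(0.8, 1.2)),
        site_offset=float(rng.normal(0.0, site_mismatch_sd)),
        seed=int(rng.integers(2 ** 31)) if seed is None else seed,
    )


def _hyperemia_pulse(s: np.ndarray, rise_s: float = 4.0,
                     hold_s: float = 10.0, decay_s: float = 120.0) -> np.ndarray:
    """Post-release pulse: fast saturating rise, slow decay (peak ~0.95)."""
    s = np.maximum(np.asarray(s, dtype=np.float64), 0.0)
    return (1.0 - np.exp(-s / rise_s)) * np.exp(-np.maximum(s - hold_s, 0.0) / decay_s)


def occlusion_timecourse(provocation: str, params: SubjectParams,
                         times_s: np.ndarray,
                         protocol: OcclusionProtocol = OcclusionProtocol(),
                         rng: np.random.Generator | None = None,
                         jitter_sd: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """True tissue SO2 (%) and RBC-fraction factor along ``times_s``.

    Returns ``(so2_pct, f_rbc_factor)``; multiply ``params.f_rbc`` by the
    factor to get the instantaneous RBC tissue fraction.  ``jitter_sd``
    adds smooth physiological wander (set 0 for a deterministic curve).
    """
    if provocation not in ("arterial", "venous"):
        raise ValueError(f"unknown provocation {provocation!r}")
    t = np.asarray(times_s, dtype=np.float64)
    os_, oe = protocol.occlusion_start_s, protocol.occlusion_end_s
    b = params.baseline_so2
    if provocation == "arterial":
        floor, tau = params.arterial_floor, params.tau_arterial_s
        peak = params.reperfusion_peak
    else:
        floor, tau = params.venous_floor, params.tau_venous_s
        peak = b + params.venous_rebound

    so2 = np.full_like(t, b)
    during = (t >= os_) & (t < oe)
    so2[during] = floor + (b - floor) * np.exp(-(t[during] - os_) / tau)
    after = t >= oe
    s = t[after] - oe
    v_end = floor + (b - floor) * np.exp(-(oe - os_) / tau)
    pulse = _hyperemia_pulse(s)
    so2[after] = b + (peak - b) * pulse + (v_end - b) * np.exp(-s / 5.0)

    # RBC fraction dynamics: venous pooling, post-release hyperemia
    factor = np.ones_like(t)
    if provocation == "venous":
        factor[during] = 1.0 + 0.4 * (1.0 - np.exp(-(t[during] - os_) / 100.0))
        f_end = 1.0 + 0.4 * (1.0 - np.exp(-(oe - os_) / 100.0))
        factor[after] = 1.0 + (f_end - 1.0) * np.exp(-s / 60.0)
    else:
        factor[during] = 1.0 - 0.1 * (1.0 - np.exp(-(t[during] - os_) / 100.0))
        factor[after] = 1.0 + 0.5 * _hyperemia_pulse(s) \
            - 0.1 * np.exp(-s / 10.0)

    if rng is not None and jitter_sd > 0:
        wander = gaussian_filter1d(rng.standard_normal(t.size), sigma=5.0,
                                   mode="nearest")
        sd = wander.std()
        if sd > 0:
            so2 = so2 + jitter_sd * wander / sd
    return so2, factor


@dataclass(frozen=True)
class ReferenceTrace:
    """1-Hz reference SO2 trace: truth at the probe site plus ~5% RMS
    measurement deviation (not clipped: real references report slightly
    out-of-range values)."""

    times_s: np.ndarray
    so2: np.ndarray
    truth: np.ndarray = field(repr=False, default=None)


def reference_trace(probe_truth_fn, protocol: OcclusionProtocol,
                    rng: np.random.Generator,
                    reference_rms: float = 5.0) -> ReferenceTrace:
    """Sample the probe-site truth at 1 Hz and add reference noise."""
    times = np.arange(0.0, protocol.window_end_s + 1.0, 1.0)
    truth = probe_truth_fn(times)
    noisy = truth + rng.normal(0.0, reference_rms, size=times.size)
    return ReferenceTrace(times_s=times, so2=noisy, truth=truth)
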