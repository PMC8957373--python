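"""Cohort generation: many subjects, both provocations, ready-to-train spectra.

``simulate_cohort`` renders every subject's arterial and venous
measurement series with one shared filter bank (training is camera
specific, so one sensor serves the whole cohort), pushes each raw frame
through the full preprocessing chain, samples 10 random ROI pixels per
cube, and pairs every spectrum with the nearest-in-time reference
sample.  All randomness flows from a single seed through per-subject
``SeedSequence`` spawns, so a fixed seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ..mosaic import FilterLayout, preprocess, preprocess_reference
from ..sampling import SpectrumSet, pair_with_reference, sample_roi_pixels
from .optics import FilterBank
from .protocol import ReferenceTrace, SubjectParams, draw_subject_params
from .scene import DESK_PROFILE, Measurement, NoiseConfig, Profile, render_measurement

__all__ = ["CohortDataset", "simulate_cohort", "measurement_to_spectra"]


def measurement_to_spectra(meas: Measurement, subject_id: str,
                           n_pixels: int = 10,
                           rng: np.random.Generator | int | None = None) -> SpectrumSet:
    """Preprocess every frame of a measurement and sample ROI spectra.

    Targets are the (noisy) reference samples nearest in time to each
    cube; truth columns are carried along for generator audits.
    """
    rng = np.random.default_rng(rng)
    white_cube = preprocess_reference(meas.white_frame, meas.dark)
    roi = meas.rois[meas.probe_roi]
    parts = []
    for k, frame in enumerate(meas.frames):
        cube = preprocess(frame, meas.dark, white_cube)
        df = sample_roi_pixels(cube, roi, n=n_pixels, rng=rng)
        df["roi_truth_so2"] = meas.roi_truth[k]
        parts.append(df)
    table = pd.concat(parts, ignore_index=True)
    table["target_so2"] = pair_with_reference(
        table["timestamp_s"].to_numpy(), meas.reference.times_s, meas.reference.so2)
    table["subject_id"] = subject_id
    table["provocation"] = meas.provocation
    table["weight"] = np.nan
    table["split"] = ""
    return SpectrumSet(table)


@dataclass
class CohortDataset:
    """Everything downstream modules need, frames already discarded."""

    spectra: SpectrumSet
    traces: dict[tuple[str, str], ReferenceTrace]
    roi_truth: dict[tuple[str, str], np.ndarray]
    timestamps: dict[tuple[str, str], np.ndarray]
    subjects: dict[str, SubjectParams]
    profile: Profile
    noise: NoiseConfig
    seed: int
    bank: FilterBank = field(repr=False, default=None)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subjects)

    def manifest(self) -> dict:
        """JSON-able ground-truth record of the simulated cohort."""
        return {
            "seed": self.seed,
            "n_subjects": len(self.subjects),
            "n_cubes_per_provocation": self.profile.n_cubes,
            "frame_shape": list(self.profile.frame_shape),
            "noise": asdict(self.noise),
            "subjects": {sid: asdict(p) for sid, p in self.subjects.items()},
            "n_spectra": len(self.spectra),
        }


def simulate_cohort(n_subjects: int = 20, seed: int = 0,
                    profile: Profile = DESK_PROFILE,
                    noise: NoiseConfig = NoiseConfig(),
                    n_pixels: int = 10,
                    layout: FilterLayout | None = None) -> CohortDataset:
    """Simulate the full occlusion cohort (both provocations per subject)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    root = np.random.SeedSequence(seed)
    bank_ss, subjects_ss = root.spawn(2)
    bank = FilterBank.default(np.random.default_rng(bank_ss))
    layout = layout or FilterLayout.default()

    spectra_parts: list[SpectrumSet] = []
    traces: dict[tuple[str, str], ReferenceTrace] = {}
    roi_truth: dict[tuple[str, str], np.ndarray] = {}
    timestamps: dict[tuple[str, str], np.ndarray] = {}
    subjects: dict[str, SubjectParams] = {}
    for i, subj_ss in enumerate(subjects_ss.spawn(n_subjects)):
        sid = f"S{i:02d}"
        param_ss, art_ss, ven_ss = subj_ss.spawn(3)
        params = draw_subject_params(np.random.default_rng(param_ss),
                                     site_mismatch_sd=noise.site_mismatch_sd,
                                     seed=int(param_ss.generate_state(1)[0] % 2**31))
        subjects[sid] = params
        for prov, prov_ss in (("arterial", art_ss), ("venous", ven_ss)):
            render_ss, sample_ss = prov_ss.spawn(2)
            meas = render_measurement(params, prov, bank, layout=layout,
                                      noise=noise,
                                      rng=np.random.default_rng(render_ss),
                                      profile=profile)
            spectra_parts.append(measurement_to_spectra(
                meas, sid, n_pixels=n_pixels,
                rng=np.random.default_rng(sample_ss)))
            traces[(sid, prov)] = meas.reference
            roi_truth[(sid, prov)] = meas.roi_truth
            timestamps[(sid, prov)] = meas.timestamps_s
            meas.frames = []  # free frame memory as we go
    return CohortDataset(spectra=SpectrumSet.concat(spectra_parts),
                         traces=traces, roi_truth=roi_truth,
                         timestamps=timestamps, subjects=subjects,
                         profile=profile, noise=noise, seed=seed, bank=bank)
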