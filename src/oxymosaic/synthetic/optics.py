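"""Forward optics: tissue reflectance and the 16-channel mosaic sensor.

The tissue model is a deliberately simple modified Beer-Lambert form

    R(lambda) = R_s(lambda) * exp(-<L> * [ f_rbc * mua_blood(lambda, so2)
                                           + m * mua_mel(lambda) ])

with a single effective photon path length <L> (mm), an RBC tissue
fraction f_rbc, a melanin scale m, and a smooth scattering baseline
R_s.  Real skin optics are layered and require Monte Carlo transport;
the learning method under test only needs a sensor->SO2 mapping that is
physically plausible and identifiable, which this form provides.

The sensor model integrates reflectance against 16 overlapping Gaussian
passbands (with a weak secondary lobe and per-sensor random
perturbations, emulating the complex Fabry-Perot sensitivities of real
mosaic sensors) times a broadband illumination spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromophores import WAVELENGTHS_NM, mua_blood, mua_melanin

__all__ = ["FilterBank", "forward_reflectance", "sensor_response", "white_response"]

N_CHANNELS = 16


@dataclass(frozen=True)
class FilterBank:
    """16 passband transmission curves plus an illumination spectrum,
    both on the 450-650 nm, 1-nm grid.  Transmissions lie in [0, 1] and
    adjacent passbands overlap substantially."""

    wavelengths_nm: np.ndarray
    transmissions: np.ndarray   # 16 x n_lambda
    illumination: np.ndarray    # n_lambda

    def __post_init__(self) -> None:
        if self.transmissions.shape != (N_CHANNELS, self.wavelengths_nm.size):
            raise ValueError("transmissions must be 16 x n_wavelengths")
        if np.any(self.transmissions < 0) or np.any(self.transmissions > 1):
            raise ValueError("transmissions must lie in [0, 1]")

    @classmethod
    def default(cls, rng: np.random.Generator | int | None = None,
                center_jitter_nm: float = 2.0) -> "FilterBank":
        """A generic sensor: centers spread over 460-640 nm, ~14 nm
        Gaussian passbands with a weak displaced secondary lobe, random
        per-sensor amplitude/center perturbations."""
        rng = np.random.default_rng(rng)
        lam = WAVELENGTHS_NM
        centers = np.linspace(460.0, 640.0, N_CHANNELS)
        centers = centers + rng.normal(0.0, center_jitter_nm, N_CHANNELS)
        widths = 14.0 * (1.0 + rng.uniform(-0.15, 0.15, N_CHANNELS))
        amps = rng.uniform(0.5, 0.9, N_CHANNELS)
        lobe_shift = rng.uniform(30.0, 50.0, N_CHANNELS) * rng.choice([-1, 1], N_CHANNELS)
        trans = np.empty((N_CHANNELS, lam.size))
        for c in range(N_CHANNELS):
            main = np.exp(-0.5 * ((lam - centers[c]) / widths[c]) ** 2)
            lobe = 0.12 * np.exp(-0.5 * ((lam - centers[c] - lobe_shift[c])
                                         / (1.6 * widths[c])) ** 2)
            trans[c] = np.clip(amps[c] * (main + lobe), 0.0, 1.0)
        # broadband LED-ring-like illumination
        illum = (0.9 * np.exp(-0.5 * ((lam - 470.0) / 45.0) ** 2)
                 + 1.0 * np.exp(-0.5 * ((lam - 580.0) / 70.0) ** 2) + 0.15)
        return cls(wavelengths_nm=lam, transmissions=trans, illumination=illum)


def forward_reflectance(so2: np.ndarray | float,
                        f_rbc: np.ndarray | float,
                        melanin: np.ndarray | float,
                        path_length_mm: float = 1.0,
                        scatter_scale: np.ndarray | float = 1.0,
                        wavelengths_nm: np.ndarray = WAVELENGTHS_NM) -> np.ndarray:
    """Diffuse reflectance curve(s); leading dims broadcast, last dim is
    wavelength.  ``so2`` is a fraction in [0, 1]."""
    so2 = np.asarray(so2, dtype=np.float64)
    f_rbc = np.asarray(f_rbc, dtype=np.float64)
    melanin = np.asarray(melanin, dtype=np.float64)
    if np.any(f_rbc < 0) or np.any(melanin < 0):
        raise ValueError("f_rbc and melanin must be nonnegative")
    lam = np.asarray(wavelengths_nm, dtype=np.float64)
    r_s = 0.6 * (lam / 550.0) ** -0.2 * np.asarray(scatter_scale)[..., None]
    mua = (f_rbc[..., None] * mua_blood(so2, lam)
           + melanin[..., None] * mua_melanin(lam))
    return r_s * np.exp(-path_length_mm * mua)


def sensor_response(reflectance: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Channel responses c = integral R(l) T_c(l) I(l) dl (trapezoid).

    ``reflectance`` has wavelength on the last axis; the result replaces
    it with the 16 channels.
    """
    reflectance = np.asarray(reflectance, dtype=np.float64)
    if reflectance.shape[-1] != bank.wavelengths_nm.size:
        raise ValueError("reflectance grid does not match the filter bank")
    weighted = bank.transmissions * bank.illumination  # 16 x n_lambda
    # trapezoid weights on the wavelength grid
    lam = bank.wavelengths_nm
    w = np.empty_like(lam)
    w[1:-1] = (lam[2:] - lam[:-2]) / 2.0
    w[0] = (lam[1] - lam[0]) / 2.0
    w[-1] = (lam[-1] - lam[-2]) / 2.0
    return reflectance @ (weighted * w).T


def white_response(bank: FilterBank) -> np.ndarray:
    """Sensor response to an ideal white reference (R = 1)."""
    return sensor_response(np.ones_like(bank.wavelengths_nm), bank)
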