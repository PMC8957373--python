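"""Embedded absorption spectra of the modelled skin chromophores.

Molar extinction coefficients of oxy- and deoxyhemoglobin are a coarse
5-nm resampling of the standard published compilations, linearly
interpolated to the working 1-nm grid (450-650 nm).  The values are
approximate; what matters for the synthetic testbed is the realistic
band structure — the HbO2 double peak near 542/577 nm, the single Hb
peak near 556 nm, the isosbestic crossings, and the strong oxy/deoxy
contrast above 600 nm.  Melanin follows the usual smooth power law.
"""

from __future__ import annotations

import numpy as np

__all__ = ["WAVELENGTHS_NM", "mua_blood", "mua_melanin", "isosbestic_wavelengths"]

WAVELENGTHS_NM = np.arange(450.0, 651.0, 1.0)

# wavelength (nm), HbO2, Hb molar extinction (cm^-1 / (mol/L))
_EXTINCTION_5NM = np.array([
    [450, 62816, 104000],
    [455, 55000, 94000],
    [460, 44480, 81000],
    [465, 38000, 69000],
    [470, 33209, 58000],
    [475, 29539, 49000],
    [480, 26629, 41000],
    [485, 24500, 34500],
    [490, 23105, 29000],
    [495, 21900, 24500],
    [500, 20932, 21100],
    [505, 20500, 18700],
    [510, 20035, 17500],
    [515, 21200, 17800],
    [520, 24202, 19500],
    [525, 28500, 22500],
    [530, 35000, 27000],
    [535, 43000, 32500],
    [540, 51000, 38500],
    [545, 52500, 44000],
    [550, 47500, 49000],
    [555, 40000, 52500],
    [560, 33209, 53412],
    [565, 36000, 51500],
    [570, 44500, 47500],
    [575, 55500, 42500],
    [580, 50000, 36000],
    [585, 31000, 30000],
    [590, 12000, 24000],
    [595, 5500, 19000],
    [600, 3200, 14677],
    [605, 1850, 11500],
    [610, 1250, 9500],
    [615, 900, 8000],
    [620, 740, 6800],
    [625, 610, 5900],
    [630, 550, 5149],
    [635, 500, 4700],
    [640, 460, 4350],
    [645, 420, 4050],
    [650, 368, 3750],
], dtype=np.float64)

_HB_GRAMS_PER_LITER = 150.0    # whole-blood hemoglobin concentration
_HB_MOLAR_MASS = 64500.0       # g/mol (tetramer)


def _interp(column: int, wavelengths_nm: np.ndarray) -> np.ndarray:
    return np.interp(wavelengths_nm, _EXTINCTION_5NM[:, 0], _EXTINCTION_5NM[:, column])


def mua_blood(so2: np.ndarray | float,
              wavelengths_nm: np.ndarray = WAVELENGTHS_NM) -> np.ndarray:
    """Whole-blood absorption coefficient (mm^-1) at oxygenation ``so2``.

    ``so2`` is a fraction in [0, 1]; broadcasting follows
    ``mua[..., k] = so2[...] * mua_HbO2[k] + (1 - so2[...]) * mua_Hb[k]``.
    """
    so2 = np.asarray(so2, dtype=np.float64)
    if np.any(so2 < 0) or np.any(so2 > 1):
        raise ValueError("so2 must lie in [0, 1]")
    # 2.303 * epsilon * C / M, in cm^-1, then /10 for mm^-1
    factor = np.log(10.0) * _HB_GRAMS_PER_LITER / _HB_MOLAR_MASS / 10.0
    mua_oxy = factor * _interp(1, wavelengths_nm)
    mua_deoxy = factor * _interp(2, wavelengths_nm)
    return so2[..., None] * mua_oxy + (1.0 - so2[..., None]) * mua_deoxy


def mua_melanin(wavelengths_nm: np.ndarray = WAVELENGTHS_NM) -> np.ndarray:
    """Relative melanin absorption (power law, 1 at 550 nm); a subject's
    melanin parameter scales this curve and carries the mm^-1 units."""
    return (np.asarray(wavelengths_nm, dtype=np.float64) / 550.0) ** -3.46


def isosbestic_wavelengths(wavelengths_nm: np.ndarray = WAVELENGTHS_NM) -> np.ndarray:
    """Crossing points of the embedded HbO2/Hb absorption curves (nm)."""
    diff = _interp(1, wavelengths_nm) - _interp(2, wavelengths_nm)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    crossings = []
    for i in sign_change:
        w0, w1 = wavelengths_nm[i], wavelengths_nm[i + 1]
        d0, d1 = diff[i], diff[i + 1]
        crossings.append(w0 + (w1 - w0) * d0 / (d0 - d1))
    return np.asarray(crossings)
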