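"""Synthetic stand-in tabulations of chromophore specific-absorption spectra.

The unmixing basis needs specific absorption spectra for oxy-, deoxy- and
met-hemoglobin, for water, and for the two gelatin types.  The spectra bundled
here are *synthetic*: smooth parametric models (sums of Gaussian bands on a
small constant floor) anchored at the canonical band positions and magnitudes
of the real compounds —

* water: overtone bands near 740 and 836 nm and the strong 970 nm band;
* HbO2: Soret tail below 480 nm, Q-bands at 542 and 576 nm, weak NIR rise;
* Hb: Soret tail, the single broad 556 nm band and the 758 nm band;
* MetHb: the 500 nm band and the diagnostic 630 nm band;
* gelatin: a featureless short-wavelength rise, stronger and yellower for the
  research-grade (bovine-bone, acid-cured) material than for the store-bought
  food gelatin.

They reproduce the qualitative spectroscopy the pipeline depends on (band
locations, relative magnitudes, non-negativity, mutual distinguishability) but
are not literature data and must not be used to analyze real measurements.

Hemoglobin spectra are expressed per micromolar of *tetramer* (MW 64,500
g/mol), i.e. four hemes per formula unit; water per unit volume fraction;
gelatin per unit mass fraction.  All specific absorptions are in mm^-1 per
concentration unit.  Native tabulation span: 450-1000 nm at 1 nm.
"""

from __future__ import annotations

import numpy as np

NATIVE_GRID_NM = np.arange(450.0, 1000.0 + 0.5, 1.0)

#: molar extinction (M^-1 cm^-1, per heme) -> mm^-1 per uM tetramer
_EXT_TO_SPECABS = 4.0 * np.log(10.0) * 1e-7


def _bands(lam: np.ndarray, floor: float, bands: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of Gaussian bands (amplitude, center nm, width nm) on a floor."""
    lam = np.asarray(lam, dtype=float)
    out = np.full_like(lam, floor)
    for amp, center, width in bands:
        out += amp * np.exp(-(((lam - center) / width) ** 2))
    return out


def water_absorption(lam: np.ndarray) -> np.ndarray:
    """Pure-water absorption, mm^-1 per unit volume fraction."""
    return _bands(
        lam,
        2.0e-4,
        [
            (2.2e-3, 740.0, 22.0),
            (3.2e-3, 836.0, 28.0),
            (4.6e-2, 970.0, 38.0),
        ],
    )


def hbo2_specific_absorption(lam: np.ndarray) -> np.ndarray:
    """Oxyhemoglobin, mm^-1 per uM tetramer."""
    ext = _bands(
        lam,
        250.0,
        [
            (60000.0, 440.0, 25.0),
            (13500.0, 542.0, 13.0),
            (15000.0, 576.0, 12.0),
            (900.0, 930.0, 110.0),
        ],
    )
    return _EXT_TO_SPECABS * ext


def hb_specific_absorption(lam: np.ndarray) -> np.ndarray:
    """Deoxyhemoglobin, mm^-1 per uM tetramer."""
    ext = _bands(
        lam,
        350.0,
        [
            (35000.0, 432.0, 28.0),
            (13000.0, 556.0, 18.0),
            (1300.0, 758.0, 28.0),
            (700.0, 910.0, 120.0),
        ],
    )
    return _EXT_TO_SPECABS * ext


def methb_specific_absorption(lam: np.ndarray) -> np.ndarray:
    """Methemoglobin, mm^-1 per uM tetramer; diagnostic 630 nm band."""
    ext = _bands(
        lam,
        150.0,
        [
            (30000.0, 406.0, 30.0),
            (9000.0, 500.0, 25.0),
            (3800.0, 630.0, 18.0),
            (500.0, 900.0, 150.0),
        ],
    )
    return _EXT_TO_SPECABS * ext


def gelatin_store_bought_absorption(lam: np.ndarray) -> np.ndarray:
    """Store-bought (porcine food) gelatin, mm^-1 per unit mass fraction."""
    lam = np.asarray(lam, dtype=float)
    return 3.0e-3 + 0.25 * np.exp(-(lam - 450.0) / 60.0)


def gelatin_research_grade_absorption(lam: np.ndarray) -> np.ndarray:
    """Research-grade (110-Bloom bovine) gelatin, mm^-1 per unit mass fraction.

    Stronger below ~580 nm than the store-bought material (visibly yellow).
    """
    lam = np.asarray(lam, dtype=float)
    return (
        3.0e-3
        + 0.55 * np.exp(-(lam - 450.0) / 55.0)
        + 0.08 * np.exp(-(((lam - 460.0) / 30.0) ** 2))
    )


#: component name -> (evaluator, concentration unit tag)
SYNTHETIC_COMPONENTS = {
    "HbO2": (hbo2_specific_absorption, "uM"),
    "Hb": (hb_specific_absorption, "uM"),
    "MetHb": (methb_specific_absorption, "uM"),
    "water": (water_absorption, "volume_fraction"),
    "gelatin_store_bought": (gelatin_store_bought_absorption, "mass_fraction"),
    "gelatin_research_grade": (gelatin_research_grade_absorption, "mass_fraction"),
}
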