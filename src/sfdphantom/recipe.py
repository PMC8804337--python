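"""Phantom recipes: composition arithmetic and predicted optical properties.

A phantom is specified by weight percentages of water, gelatin and
Intralipid-20% (which must sum to 100), a gelatin type, and an optional
hemoglobin additive (ferrous-stabilized powder in mg, or whole blood in ml).
The scatterer is always the Intralipid; holding it at a fixed weight
percentage decouples scattering from the water/gelatin ratio, so the water
fraction can be varied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ABSORPTION, CONCENTRATION_UNIT, ChromophoreBasis, REDUCED_SCATTERING, Spectrum

#: fraction of Intralipid-20% mass that is water
INTRALIPID20_WATER_FRACTION = 0.8

GELATIN_TYPES = ("store_bought", "research_grade")


class CompositionError(ValueError):
    """Recipe weight percentages are inconsistent."""


class UnitError(ValueError):
    """Concentration unit does not match the basis component's unit."""


@dataclass(frozen=True)
class HemoglobinAdditive:
    """Hemoglobin added to the cooled gelatin/Intralipid mixture.

    ``ferrous_powder`` amounts are in mg of ferrous-stabilized hemoglobin;
    ``whole_blood`` amounts are in ml of heparinized whole blood.
    """

    kind: str
    amount: float
    unit: str

    def __post_init__(self) -> None:
        if self.kind not in ("ferrous_powder", "whole_blood"):
            raise ValueError(f"unknown hemoglobin additive kind {self.kind!r}")
        expected = "mg" if self.kind == "ferrous_powder" else "ml"
        if self.unit != expected:
            raise UnitError(f"{self.kind} amounts must be in {expected}, got {self.unit!r}")
        if self.amount < 0:
            raise ValueError("additive amount must be non-negative")


@dataclass(frozen=True)
class PhantomRecipe:
    """Weight-percent composition of one phantom."""

    water_wt_pct: float
    gelatin_wt_pct: float
    intralipid20_wt_pct: float
    gelatin_type: str = "store_bought"
    hemoglobin_additive: HemoglobinAdditive | None = None
    batch_label: str = ""
    #: absolute batch mass, needed only to convert an absolute additive amount
    #: to a concentration (the hemoglobin protocol: 25 g water + 2.5 g gelatin
    #: + 3 g Intralipid-20% = 30.5 g)
    total_mass_g: float = 30.5

    def __post_init__(self) -> None:
        if self.gelatin_type not in GELATIN_TYPES:
            raise ValueError(f"unknown gelatin type {self.gelatin_type!r}")
        pcts = (self.water_wt_pct, self.gelatin_wt_pct, self.intralipid20_wt_pct)
        if any(p < 0 for p in pcts):
            raise CompositionError("weight percentages must be non-negative")
        if abs(sum(pcts) - 100.0) > 1e-6:
            raise CompositionError(
                f"weight percentages must sum to 100, got {sum(pcts):.8g}"
            )
        if self.total_mass_g <= 0:
            raise CompositionError("total mass must be positive")


#: the four-phantom water-fraction ladder at fixed 10% Intralipid-20%
WATER_LADDER_RECIPES = tuple(
    PhantomRecipe(w, g, 10.0, batch_label=f"phantom{i + 1}")
    for i, (w, g) in enumerate([(89.0, 1.0), (80.0, 10.0), (60.0, 30.0), (40.0, 50.0)])
)

#: density (g/ml) and molar-mass assumptions used for unit conversions
DEFAULT_ASSUMPTIONS = {
    "density_water_g_ml": 1.0,
    "density_gelatin_g_ml": 1.0,
    "density_intralipid20_g_ml": 1.0,
    "hb_molar_mass_g_mol": 64500.0,  # tetramer
    "whole_blood_hb_g_per_l": 150.0,
}


def total_water_fraction(recipe: PhantomRecipe) -> float:
    """Total water mass fraction, counting the 80% water content of Intralipid-20%."""
    return (recipe.water_wt_pct + INTRALIPID20_WATER_FRACTION * recipe.intralipid20_wt_pct) / 100.0


def nominal_concentrations(
    recipe: PhantomRecipe, assumptions: dict[str, float] | None = None
) -> dict[str, float]:
    """Nominal chromophore concentrations implied by the recipe.

    Returns total-water volume fraction (``water``), gelatin mass fraction
    (``gelatin``), and — if an additive is present — the hemoglobin tetramer
    concentration in uM (``hemoglobin_uM``), computed as added hemoglobin mass
    / molar mass / total phantom volume under the density assumptions.
    """
    a = dict(DEFAULT_ASSUMPTIONS)
    if assumptions:
        unknown = set(assumptions) - set(a)
        if unknown:
            raise KeyError(f"unknown assumption entries: {sorted(unknown)}")
        a.update(assumptions)
    water_mass_frac = total_water_fraction(recipe)
    # volume fractions under the density table
    masses = {
        "water": recipe.water_wt_pct,
        "gelatin": recipe.gelatin_wt_pct,
        "intralipid20": recipe.intralipid20_wt_pct,
    }
    volumes = {
        "water": masses["water"] / a["density_water_g_ml"],
        "gelatin": masses["gelatin"] / a["density_gelatin_g_ml"],
        "intralipid20": masses["intralipid20"] / a["density_intralipid20_g_ml"],
    }
    total_volume_per_100g = sum(volumes.values())
    water_volume = (
        volumes["water"]
        + INTRALIPID20_WATER_FRACTION * volumes["intralipid20"]
    )
    out = {
        "water": water_volume / total_volume_per_100g,
        "water_mass_fraction": water_mass_frac,
        "gelatin": recipe.gelatin_wt_pct / 100.0,
        "hemoglobin_uM": 0.0,
    }
    additive = recipe.hemoglobin_additive
    if additive is not None:
        if additive.kind == "ferrous_powder":
            hb_mass_g = additive.amount / 1000.0
        else:
            hb_mass_g = additive.amount / 1000.0 * a["whole_blood_hb_g_per_l"]
        phantom_volume_l = (
            recipe.total_mass_g * (total_volume_per_100g / 100.0) / 1000.0
        )
        mol = hb_mass_g / a["hb_molar_mass_g_mol"]
        out["hemoglobin_uM"] = mol / phantom_volume_l * 1e6
    return out


def expected_absorption(
    basis: ChromophoreBasis,
    concentrations: dict[str, float],
    units: dict[str, str] | None = None,
) -> Spectrum:
    """Forward linear mixing: mu_a(lambda) = sum_i c_i * eps_i(lambda).

    ``units`` optionally declares the concentration unit of each entry; a
    mismatch with the basis component's unit tag raises :class:`UnitError`.
    """
    grid = basis.grid
    mu_a = np.zeros_like(grid)
    for name, c in concentrations.items():
        if name not in basis.components:
            raise UnitError(f"concentration {name!r} has no basis component")
        if units is not None and name in units:
            expected = CONCENTRATION_UNIT[basis.components[name].unit]
            if units[name] != expected:
                raise UnitError(
                    f"{name!r} given in {units[name]!r} but basis expects {expected!r}"
                )
        mu_a = mu_a + c * basis.components[name].values
    return Spectrum(grid.copy(), mu_a, unit=ABSORPTION)


@dataclass(frozen=True)
class ScatteringModel:
    """Rayleigh+Mie power-law model for the Intralipid reduced scattering.

    mu_s'(lambda) = (IL20 wt% / 10) * amplitude *
        [r (lambda/lambda0)^-4 + (1-r) (lambda/lambda0)^-b]

    Defaults give a 10% Intralipid-20% phantom (2% Intralipid) a mid-spectrum
    mu_s' of roughly 1-2 mm^-1, the regime of skin-mimicking phantoms.
    """

    amplitude_mm1: float = 1.6
    reference_wavelength_nm: float = 700.0
    rayleigh_fraction: float = 0.05
    mie_power: float = 2.4

    def __post_init__(self) -> None:
        if self.amplitude_mm1 <= 0:
            raise ValueError("amplitude must be positive")
        if not 0.0 <= self.rayleigh_fraction <= 1.0:
            raise ValueError("rayleigh_fraction must lie in [0, 1]")
        if self.mie_power <= 0:
            raise ValueError("mie_power must be positive")


def expected_scattering(
    recipe: PhantomRecipe, model: ScatteringModel, grid_nm: np.ndarray
) -> Spectrum:
    """Predicted mu_s'(lambda), proportional to the Intralipid weight percent."""
    lam = np.asarray(grid_nm, dtype=float)
    if not (lam.min() <= model.reference_wavelength_nm <= lam.max()):
        raise ValueError("reference wavelength must lie within the grid span")
    x = lam / model.reference_wavelength_nm
    shape = (
        model.rayleigh_fraction * x**-4.0
        + (1.0 - model.rayleigh_fraction) * x ** (-model.mie_power)
    )
    musp = (recipe.intralipid20_wt_pct / 10.0) * model.amplitude_mm1 * shape
    return Spectrum(lam, musp, unit=REDUCED_SCATTERING)
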