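"""Spectral containers and the chromophore unmixing basis.

A :class:`Spectrum` is a wavelength grid plus one value per wavelength with a
unit tag; a :class:`ChromophoreBasis` is an ordered set of specific-absorption
spectra sharing one grid.  This module also implements the non-negative
residual estimator that extracts a gelatin specific-absorption spectrum from a
gelatin/water dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import basis_synthetic

# unit tags for Spectrum.unit
ABSORPTION = "absorption_mm^-1"
SPECABS_UM = "specabs_mm^-1_uM^-1"
SPECABS_VOLFRAC = "specabs_mm^-1_volfrac^-1"
SPECABS_MASSFRAC = "specabs_mm^-1_massfrac^-1"
REDUCED_SCATTERING = "reduced_scattering_mm^-1"
DIMENSIONLESS = "dimensionless"

_VALID_UNITS = {
    ABSORPTION,
    SPECABS_UM,
    SPECABS_VOLFRAC,
    SPECABS_MASSFRAC,
    REDUCED_SCATTERING,
    DIMENSIONLESS,
}

_ABSORPTION_LIKE = {ABSORPTION, SPECABS_UM, SPECABS_VOLFRAC, SPECABS_MASSFRAC}

#: concentration unit implied by each specific-absorption unit tag
CONCENTRATION_UNIT = {
    SPECABS_UM: "uM",
    SPECABS_VOLFRAC: "volume_fraction",
    SPECABS_MASSFRAC: "mass_fraction",
}
_SPECABS_FOR_CONC = {v: k for k, v in CONCENTRATION_UNIT.items()}


class GridError(ValueError):
    """Wavelength grids do not match or lie outside a tabulated span."""


@dataclass(frozen=True)
class Spectrum:
    """One spectral quantity on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in [250, 1100] nm.
    values
        One finite value per wavelength; non-negative for absorption-typed
        units.
    unit
        One of the module unit tags (``ABSORPTION``, ``SPECABS_UM``, ...).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: str = ABSORPTION

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        val = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "values", val)
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if lam.ndim != 1 or val.shape != lam.shape:
            raise ValueError("wavelengths and values must be congruent 1-D arrays")
        if lam.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if lam[0] < 250.0 or lam[-1] > 1100.0:
            raise ValueError("wavelengths must lie within [250, 1100] nm")
        if not np.all(np.isfinite(val)):
            raise ValueError("spectrum values must be finite")
        if self.unit in _ABSORPTION_LIKE and np.any(val < 0):
            raise ValueError("absorption-typed values must be non-negative")

    def resample(self, target_grid_nm: np.ndarray, name: str = "spectrum") -> "Spectrum":
        """Linear interpolation onto ``target_grid_nm``; no extrapolation."""
        target = np.asarray(target_grid_nm, dtype=float)
        lam = self.wavelengths_nm
        if target.min() < lam[0] or target.max() > lam[-1]:
            raise GridError(
                f"resampling {name}: target grid [{target.min():g}, {target.max():g}] nm "
                f"exceeds native span [{lam[0]:g}, {lam[-1]:g}] nm"
            )
        if target.shape == lam.shape and np.array_equal(target, lam):
            return replace(self, wavelengths_nm=target.copy(), values=self.values.copy())
        return replace(
            self,
            wavelengths_nm=target,
            values=np.interp(target, lam, self.values),
        )


@dataclass(frozen=True)
class ChromophoreBasis:
    """Ordered set of specific-absorption spectra on one shared grid."""

    components: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("basis needs at least one component")
        grids = [s.wavelengths_nm for s in self.components.values()]
        for name, spec in self.components.items():
            if not np.array_equal(spec.wavelengths_nm, grids[0]):
                raise GridError(f"component {name!r} is not on the shared grid")
            if spec.unit not in CONCENTRATION_UNIT:
                raise ValueError(
                    f"component {name!r} must carry a specific-absorption unit, got {spec.unit!r}"
                )

    @property
    def grid(self) -> np.ndarray:
        return next(iter(self.components.values())).wavelengths_nm

    @property
    def names(self) -> list[str]:
        return list(self.components)

    def concentration_unit(self, name: str) -> str:
        return CONCENTRATION_UNIT[self.components[name].unit]

    def design_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_wavelengths, n_components) matrix of specific absorptions."""
        names = self.names if names is None else names
        return np.column_stack([self.components[n].values for n in names])


@dataclass(frozen=True)
class DilutionSeriesPoint:
    """One gelatin/water dilution: measured mu_a plus the recipe fractions."""

    mu_a: Spectrum
    water_fraction: float
    gelatin_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_fraction <= 1.0 and 0.0 <= self.gelatin_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.water_fraction + self.gelatin_fraction > 1.0 + 1e-9:
            raise ValueError("water + gelatin fractions exceed 1")


def resample_basis(basis: ChromophoreBasis, target_grid_nm: np.ndarray) -> ChromophoreBasis:
    """Linearly interpolate every basis component onto ``target_grid_nm``.

    Raises :class:`GridError`, naming the offending component, if the target
    grid extends beyond any component's native span.
    """
    return ChromophoreBasis(
        {name: spec.resample(target_grid_nm, name=name) for name, spec in basis.components.items()}
    )


def make_reference_basis(
    grid_nm: np.ndarray,
    gelatin_spectra: dict[str, Spectrum] | None = None,
    include_gelatin_defaults: bool = False,
) -> ChromophoreBasis:
    """Bundled reference basis (HbO2, Hb, MetHb, water) resampled to ``grid_nm``.

    The bundled spectra are the synthetic tabulations of
    :mod:`sfdphantom.basis_synthetic` (450-1000 nm native span).  Hemoglobin
    species are per uM tetramer, water per volume fraction.  Supplied
    ``gelatin_spectra`` (per mass fraction) are appended after resampling;
    ``include_gelatin_defaults`` appends the two bundled synthetic gelatin
    spectra instead.
    """
    grid = np.asarray(grid_nm, dtype=float)
    native = basis_synthetic.NATIVE_GRID_NM
    if grid.min() < native[0] or grid.max() > native[-1]:
        raise GridError(
            f"requested grid [{grid.min():g}, {grid.max():g}] nm outside the bundled "
            f"tabulation span [{native[0]:g}, {native[-1]:g}] nm"
        )
    components: dict[str, Spectrum] = {}
    for name in ("HbO2", "Hb", "MetHb", "water"):
        fn, conc_unit = basis_synthetic.SYNTHETIC_COMPONENTS[name]
        tab = Spectrum(native, fn(native), unit=_SPECABS_FOR_CONC[conc_unit])
        components[name] = tab.resample(grid, name=name)
    if include_gelatin_defaults:
        for name in ("gelatin_store_bought", "gelatin_research_grade"):
            fn, conc_unit = basis_synthetic.SYNTHETIC_COMPONENTS[name]
            tab = Spectrum(native, fn(native), unit=_SPECABS_FOR_CONC[conc_unit])
            components[name] = tab.resample(grid, name=name)
    for name, spec in (gelatin_spectra or {}).items():
        resampled = spec.resample(grid, name=name)
        if resampled.unit not in CONCENTRATION_UNIT:
            resampled = replace(resampled, unit=SPECABS_MASSFRAC)
        components[name] = resampled
    return ChromophoreBasis(components)


def estimate_gelatin_spectrum(
    series: list[DilutionSeriesPoint],
    water_basis: Spectrum,
    water_mode: str = "known",
    joint: bool = False,
) -> Spectrum:
    """Gelatin specific absorption from the non-negative water-fit residual.

    For each dilution point the water contribution is removed from the
    measured mu_a, the residual is clipped at zero (absorption cannot be
    negative), and divided by the gelatin mass fraction; the estimator returns
    the unweighted mean across points, per unit gelatin mass fraction.

    Parameters
    ----------
    water_mode
        ``"known"`` (default) scales the water basis by each point's recipe
        water fraction before subtracting — the fractions are part of the
        dilution design and using them keeps the estimator unbiased.
        ``"fitted"`` instead estimates the water coefficient of each point by
        one-component least squares, which leaks any gelatin absorption that
        projects onto the water spectrum into the water coefficient.
    joint
        Solve all points jointly per wavelength (least squares over the known
        gelatin fractions of the clipped residuals) instead of averaging the
        per-point ratios.
    """
    if water_mode not in ("known", "fitted"):
        raise ValueError(f"unknown water_mode {water_mode!r}")
    points = [p for p in series if p.gelatin_fraction > 0]
    if len(points) < 2 or len({p.gelatin_fraction for p in points}) < 2:
        raise ValueError(
            "need >= 2 dilution points with distinct nonzero gelatin fractions"
        )
    grid = water_basis.wavelengths_nm
    w = water_basis.values
    residuals, fractions = [], []
    for p in points:
        if not np.array_equal(p.mu_a.wavelengths_nm, grid):
            raise GridError("dilution point grid does not match the water basis grid")
        if water_mode == "known":
            coef = p.water_fraction
        else:
            coef = float(p.mu_a.values @ w) / float(w @ w)
        residuals.append(np.clip(p.mu_a.values - coef * w, 0.0, None))
        fractions.append(p.gelatin_fraction)
    r = np.asarray(residuals)
    f = np.asarray(fractions)
    if joint:
        gelatin = (f @ r) / (f @ f)
    else:
        gelatin = np.mean(r / f[:, None], axis=0)
    return Spectrum(grid.copy(), np.clip(gelatin, 0.0, None), unit=SPECABS_MASSFRAC)
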