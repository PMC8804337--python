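"""Forward model of calibrated spatial-frequency-domain diffuse reflectance.

Sinusoidal illumination at spatial frequency fx probes a homogeneous
semi-infinite turbid medium; the modulation transfer of the diffuse
reflectance, Rd(fx), decays with fx at a rate set jointly by absorption and
reduced scattering, which is what lets a multi-frequency measurement separate
mu_a from mu_s' at a single wavelength.  The closed form used here is the
standard diffusion-approximation solution with a partial-current boundary
condition:

    mu_tr     = mu_a + mu_s'
    a'        = mu_s' / mu_tr
    mu_eff'   = sqrt(3 mu_a mu_tr + (2 pi fx)^2)
    Rd(fx)    = 3 A a' / ((mu_eff'/mu_tr + 1) (mu_eff'/mu_tr + 3A))

with A = (1 - R_eff) / (2 (1 + R_eff)) and R_eff the effective internal
reflection coefficient from the usual cubic-in-1/n polynomial.  Spatial
frequencies are in cycles/mm; the 2*pi lives inside mu_eff'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .inverse import OpticalProperties

#: five evenly spaced spatial frequencies spanning 0 to 0.2 mm^-1
DEFAULT_FREQUENCIES_MM1 = np.array([0.0, 0.05, 0.10, 0.15, 0.20])

DEFAULT_REFRACTIVE_INDEX = 1.40


class CalibrationError(ValueError):
    """Reference measurement unusable at specific (wavelength, frequency) cells."""


def effective_reflection_coefficient(n: float) -> float:
    """R_eff(n) polynomial for the refractive-index-mismatched boundary."""
    if n < 1.0:
        raise ValueError("refractive index must be >= 1")
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def boundary_coefficient_A(n: float) -> float:
    """Partial-current boundary coefficient A = (1 - R_eff)/(2 (1 + R_eff))."""
    r_eff = effective_reflection_coefficient(n)
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


def diffusion_reflectance(mu_a, mu_s_prime, fx, n: float = DEFAULT_REFRACTIVE_INDEX):
    """Diffuse reflectance Rd at spatial frequency fx (broadcasting).

    Parameters are in mm^-1; ``fx`` in cycles/mm.  Raises for non-positive
    optical properties or negative frequencies.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if np.any(mu_a <= 0) or np.any(mu_s_prime <= 0):
        raise ValueError("optical properties must be strictly positive")
    if np.any(fx < 0):
        raise ValueError("spatial frequencies must be non-negative")
    a_coef = boundary_coefficient_A(n)
    mu_tr = mu_a + mu_s_prime
    a_prime = mu_s_prime / mu_tr
    mu_eff_prime = np.sqrt(3.0 * mu_a * mu_tr + (2.0 * np.pi * fx) ** 2)
    x = mu_eff_prime / mu_tr
    return 3.0 * a_coef * a_prime / ((x + 1.0) * (x + 3.0 * a_coef))


@dataclass(frozen=True)
class SFDMeasurement:
    """Calibrated diffuse reflectance, wavelength x spatial frequency."""

    wavelengths_nm: np.ndarray
    spatial_frequencies_mm1: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        fx = np.asarray(self.spatial_frequencies_mm1, dtype=float)
        rd = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "spatial_frequencies_mm1", fx)
        object.__setattr__(self, "reflectance", rd)
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.diff(fx) > 0):
            raise ValueError("spatial frequencies must be strictly increasing")
        if rd.shape != (lam.size, fx.size):
            raise ValueError("reflectance must be (n_wavelengths, n_frequencies)")
        if np.any(rd < 0) or np.any(rd > 1) or not np.all(np.isfinite(rd)):
            raise ValueError("reflectance values must be finite and within [0, 1]")

    def is_frequency_monotone(self) -> np.ndarray:
        """Per-wavelength flag: Rd non-increasing along the frequency axis.

        A violation is physically inconsistent for a homogeneous sample but is
        reported, not rejected — the inverse solver flags it as a poor fit.
        """
        return np.all(np.diff(self.reflectance, axis=1) <= 1e-12, axis=1)


def calibrate_reflectance(
    raw_sample: np.ndarray,
    raw_reference: np.ndarray,
    reference_props: "OpticalProperties",
    wavelengths_nm: np.ndarray,
    fx: np.ndarray,
    n: float = DEFAULT_REFRACTIVE_INDEX,
    meta: dict | None = None,
) -> SFDMeasurement:
    """Calibrate raw demodulated intensities against a reference phantom.

    Rd_sample = (raw_sample / raw_reference) * Rd_model(reference_props, fx)
    elementwise; instrument gain and spectral throughput cancel in the ratio.
    """
    raw_sample = np.asarray(raw_sample, dtype=float)
    raw_reference = np.asarray(raw_reference, dtype=float)
    fx = np.asarray(fx, dtype=float)
    lam = np.asarray(wavelengths_nm, dtype=float)
    if raw_sample.shape != raw_reference.shape:
        raise CalibrationError("sample and reference matrices must share a shape")
    if raw_sample.shape != (lam.size, fx.size):
        raise CalibrationError("raw matrices must be (n_wavelengths, n_frequencies)")
    bad = np.argwhere(raw_reference <= 0)
    if bad.size:
        cells = ", ".join(
            f"(lambda={lam[i]:g} nm, fx={fx[j]:g} mm^-1)" for i, j in bad[:5]
        )
        raise CalibrationError(f"non-positive reference intensity at {cells}")
    if not np.array_equal(reference_props.wavelengths_nm, lam):
        raise CalibrationError("reference optical properties not on the measurement grid")
    model = diffusion_reflectance(
        reference_props.mu_a[:, None], reference_props.mu_s_prime[:, None], fx[None, :], n=n
    )
    rd = raw_sample / raw_reference * model
    full_meta = {"calibration_reference": "model", "n": n}
    full_meta.update(meta or {})
    return SFDMeasurement(lam, fx, np.clip(rd, 0.0, 1.0), meta=full_meta)
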