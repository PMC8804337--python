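"""Per-wavelength recovery of (mu_a, mu_s') from multi-frequency reflectance.

Each wavelength is inverted independently — no spectral priors, constraints or
smoothing — so absorption features enter the recovered spectra only through
the data.  The solver is two-stage: a coarse lookup table (LUT) of the
diffusion forward model supplies the nearest node, and a damped Gauss–Newton
refinement in log10(mu_a, mu_s') space polishes it against the continuous
forward model.  All wavelengths are refined simultaneously as a vectorized
batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import (
    DEFAULT_FREQUENCIES_MM1,
    DEFAULT_REFRACTIVE_INDEX,
    SFDMeasurement,
    diffusion_reflectance,
)

FLAG_OK = "ok"
FLAG_AT_BOUND = "at_bound"
FLAG_POOR_FIT = "poor_fit"


class FrequencyMismatchError(ValueError):
    """Measurement frequencies differ from the lookup table's."""


class ConfigurationError(ValueError):
    """Degenerate lookup-table configuration."""


@dataclass(frozen=True)
class OpticalProperties:
    """Paired mu_a(lambda) and mu_s'(lambda) with per-wavelength fit quality."""

    wavelengths_nm: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    fit_residual: np.ndarray | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        mu_a = np.asarray(self.mu_a, dtype=float)
        musp = np.asarray(self.mu_s_prime, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_s_prime", musp)
        if mu_a.shape != lam.shape or musp.shape != lam.shape:
            raise ValueError("property arrays must be congruent with the grid")
        resid = self.fit_residual
        flags = self.flags
        if resid is None:
            resid = np.zeros_like(lam)
        if flags is None:
            flags = np.full(lam.shape, FLAG_OK, dtype=object)
        object.__setattr__(self, "fit_residual", np.asarray(resid, dtype=float))
        object.__setattr__(self, "flags", np.asarray(flags, dtype=object))
        ok = self.flags == FLAG_OK
        if np.any(mu_a[ok] < 0) or np.any(musp[ok] <= 0):
            raise ValueError("ok-flagged wavelengths must have mu_a >= 0 and mu_s' > 0")


@dataclass(frozen=True)
class InversionLUT:
    """Precomputed diffusion reflectance over a log-spaced property grid."""

    mu_a_grid: np.ndarray
    mu_s_prime_grid: np.ndarray
    fx: np.ndarray
    table: np.ndarray  # (n_mu_a, n_mu_s_prime, n_fx)
    n: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        if not (np.all(np.diff(self.mu_a_grid) > 0) and np.all(np.diff(self.mu_s_prime_grid) > 0)):
            raise ConfigurationError("LUT grids must be strictly increasing")
        if self.table.shape != (self.mu_a_grid.size, self.mu_s_prime_grid.size, self.fx.size):
            raise ConfigurationError("LUT table shape inconsistent with its grids")
        if not np.all(np.isfinite(self.table)) or np.any(self.table <= 0) or np.any(self.table >= 1):
            raise ConfigurationError("LUT entries must be finite and inside (0, 1)")


def build_lookup(
    mu_a_range: tuple[float, float] = (1e-4, 1.0),
    mu_s_prime_range: tuple[float, float] = (0.1, 10.0),
    grid_sizes: tuple[int, int] = (64, 64),
    fx: np.ndarray = DEFAULT_FREQUENCIES_MM1,
    n: float = DEFAULT_REFRACTIVE_INDEX,
) -> InversionLUT:
    """Tabulate the diffusion forward model over log-spaced property grids."""
    for lo, hi in (mu_a_range, mu_s_prime_range):
        if not (0 < lo < hi):
            raise ConfigurationError(f"degenerate range ({lo}, {hi})")
    if min(grid_sizes) < 16:
        raise ConfigurationError("grid sizes must be >= 16")
    mu_a_grid = np.logspace(np.log10(mu_a_range[0]), np.log10(mu_a_range[1]), grid_sizes[0])
    musp_grid = np.logspace(
        np.log10(mu_s_prime_range[0]), np.log10(mu_s_prime_range[1]), grid_sizes[1]
    )
    fx = np.asarray(fx, dtype=float)
    table = diffusion_reflectance(
        mu_a_grid[:, None, None], musp_grid[None, :, None], fx[None, None, :], n=n
    )
    return InversionLUT(mu_a_grid, musp_grid, fx, table, n=n)


def _nearest_node(lut: InversionLUT, reflectance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-occurrence argmin of SSE over the LUT; ties favor smaller mu_a."""
    n_lam = reflectance.shape[0]
    sse = np.zeros((n_lam, lut.mu_a_grid.size, lut.mu_s_prime_grid.size))
    for k in range(lut.fx.size):
        sse += (lut.table[None, :, :, k] - reflectance[:, None, None, k]) ** 2
    flat = sse.reshape(n_lam, -1).argmin(axis=1)
    i, j = np.unravel_index(flat, sse.shape[1:])
    return i, j


def _refine(
    lut: InversionLUT,
    reflectance: np.ndarray,
    p0: np.ndarray,
    max_iter: int = 40,
    damping: float = 1e-10,
) -> np.ndarray:
    """Batch damped Gauss–Newton in p = log10(mu_a, mu_s'), clipped to LUT bounds."""
    lo = np.log10([lut.mu_a_grid[0], lut.mu_s_prime_grid[0]])
    hi = np.log10([lut.mu_a_grid[-1], lut.mu_s_prime_grid[-1]])
    p = np.clip(p0, lo, hi)
    fx = lut.fx
    h = 1e-6
    for _ in range(max_iter):
        props = 10.0**p
        r0 = diffusion_reflectance(props[:, 0:1], props[:, 1:2], fx[None, :], n=lut.n)
        resid = r0 - reflectance
        # central-difference Jacobian in log space, (n_lam, n_fx, 2)
        jac = np.empty(resid.shape + (2,))
        for d in range(2):
            pp = p.copy()
            pp[:, d] += h
            pm = p.copy()
            pm[:, d] -= h
            rp = diffusion_reflectance(10.0 ** pp[:, 0:1], 10.0 ** pp[:, 1:2], fx[None, :], n=lut.n)
            rm = diffusion_reflectance(10.0 ** pm[:, 0:1], 10.0 ** pm[:, 1:2], fx[None, :], n=lut.n)
            jac[:, :, d] = (rp - rm) / (2.0 * h)
        jtj = np.einsum("lfa,lfb->lab", jac, jac)
        jtr = np.einsum("lfa,lf->la", jac, resid)
        jtj[:, 0, 0] += damping
        jtj[:, 1, 1] += damping
        try:
            step = np.linalg.solve(jtj, jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.einsum("lab,lb->la", np.linalg.pinv(jtj), jtr)
        step = np.clip(step, -0.25, 0.25)
        p = np.clip(p - step, lo, hi)
        if np.max(np.abs(step)) < 1e-12:
            break
    return p


def invert_reflectance(
    measurement: SFDMeasurement,
    lut: InversionLUT,
    refine: bool = True,
    poor_fit_rel_rms: float = 0.05,
) -> OpticalProperties:
    """Recover (mu_a, mu_s') independently at every wavelength.

    Wavelengths whose refined optimum sits on a LUT boundary are flagged
    ``at_bound``; wavelengths whose RMS reflectance misfit exceeds
    ``poor_fit_rel_rms`` of the mean measured reflectance are flagged
    ``poor_fit`` (e.g. physically inconsistent frequency dependence).  No
    exception is raised for poor fits.
    """
    if measurement.spatial_frequencies_mm1.shape != lut.fx.shape or not np.allclose(
        measurement.spatial_frequencies_mm1, lut.fx
    ):
        raise FrequencyMismatchError(
            "measurement spatial frequencies do not match the lookup table"
        )
    rd = measurement.reflectance
    i, j = _nearest_node(lut, rd)
    p = np.column_stack([np.log10(lut.mu_a_grid[i]), np.log10(lut.mu_s_prime_grid[j])])
    if refine:
        p = _refine(lut, rd, p)
    mu_a = 10.0 ** p[:, 0]
    musp = 10.0 ** p[:, 1]
    model = diffusion_reflectance(mu_a[:, None], musp[:, None], lut.fx[None, :], n=lut.n)
    rms = np.sqrt(np.mean((model - rd) ** 2, axis=1))
    scale = np.maximum(np.mean(np.abs(rd), axis=1), 1e-12)
    lo = np.log10([lut.mu_a_grid[0], lut.mu_s_prime_grid[0]])
    hi = np.log10([lut.mu_a_grid[-1], lut.mu_s_prime_grid[-1]])
    at_bound = np.any((p <= lo + 1e-9) | (p >= hi - 1e-9), axis=1)
    flags = np.full(mu_a.shape, FLAG_OK, dtype=object)
    flags[at_bound] = FLAG_AT_BOUND
    flags[rms / scale > poor_fit_rel_rms] = FLAG_POOR_FIT
    return OpticalProperties(
        measurement.wavelengths_nm.copy(), mu_a, musp, fit_residual=rms, flags=flags
    )


class SFDInverter:
    """Scikit-learn-style transformer from reflectance rows to (mu_a, mu_s').

    ``fit`` builds the lookup table (``lut_``); ``transform`` maps an array of
    shape (n_wavelengths, n_frequencies) to (n_wavelengths, 2) columns
    [mu_a, mu_s'] in mm^-1.  Parameters follow the usual get_params/set_params
    contract so the inverter composes with sklearn pipelines.
    """

    def __init__(
        self,
        fx=tuple(DEFAULT_FREQUENCIES_MM1),
        n: float = DEFAULT_REFRACTIVE_INDEX,
        mu_a_range: tuple[float, float] = (1e-4, 1.0),
        mu_s_prime_range: tuple[float, float] = (0.1, 10.0),
        grid_sizes: tuple[int, int] = (64, 64),
        refine: bool = True,
    ):
        self.fx = fx
        self.n = n
        self.mu_a_range = mu_a_range
        self.mu_s_prime_range = mu_s_prime_range
        self.grid_sizes = grid_sizes
        self.refine = refine

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "fx": self.fx,
            "n": self.n,
            "mu_a_range": self.mu_a_range,
            "mu_s_prime_range": self.mu_s_prime_range,
            "grid_sizes": self.grid_sizes,
            "refine": self.refine,
        }

    def set_params(self, **params) -> "SFDInverter":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for SFDInverter")
            setattr(self, key, value)
        return self

    # -- estimator surface -------------------------------------------------
    def fit(self, X=None, y=None) -> "SFDInverter":
        """Precompute the lookup table; X and y are ignored."""
        self.lut_ = build_lookup(
            self.mu_a_range,
            self.mu_s_prime_range,
            self.grid_sizes,
            np.asarray(self.fx, dtype=float),
            self.n,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "lut_"):
            raise RuntimeError("SFDInverter is not fitted; call fit() first")

    def invert(self, measurement: SFDMeasurement) -> OpticalProperties:
        """Full inversion, with fit residuals and quality flags."""
        self._check_fitted()
        return invert_reflectance(measurement, self.lut_, refine=self.refine)

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.lut_.fx):
            raise ValueError(
                f"X must be (n_wavelengths, {len(self.lut_.fx)}) reflectance values"
            )
        lam = 450.0 + np.arange(X.shape[0])  # placeholder grid; values only
        meas = SFDMeasurement(lam, self.lut_.fx, np.clip(X, 0.0, 1.0))
        props = invert_reflectance(meas, self.lut_, refine=self.refine)
        return np.column_stack([props.mu_a, props.mu_s_prime])

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit().transform(X)
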