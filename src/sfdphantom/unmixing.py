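"""Linear spectral unmixing of absorption into chromophore concentrations.

The measured absorption spectrum is modeled as mu_a(lambda) = E c where the
columns of E are specific-absorption spectra (HbO2, Hb, MetHb in uM of
tetramer; water as a volume fraction; gelatin as a mass fraction).  The fit is
either non-negative least squares (hemoglobin panels, where a species may be
pinned at zero) or unconstrained ordinary least squares (water/gelatin fits,
where estimates above 100% are allowed and diagnostic).  One-sigma
uncertainties come from the residual-scaled unconstrained covariance,
sigma_i = sqrt([(E^T E)^-1]_ii * chi2 / dof); species pinned at zero by the
non-negativity bound still receive this unconstrained uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .basis import ChromophoreBasis, GridError, Spectrum
from .inverse import OpticalProperties

MODE_NONNEGATIVE = "nonnegative"
MODE_UNCONSTRAINED = "unconstrained"

#: condition-number guard for E^T E; above this the basis is treated as collinear
CONDITION_LIMIT = 1e10


class CollinearityError(ValueError):
    """Basis components are numerically indistinguishable over the fit grid."""


@dataclass(frozen=True)
class ConcentrationFit:
    """Fitted chromophore amounts with chi-squared-based 1-sigma uncertainties."""

    concentrations: dict[str, float]
    uncertainties: dict[str, float]
    chi2: float
    dof: int
    mode: str
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in (MODE_NONNEGATIVE, MODE_UNCONSTRAINED):
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if any(s < 0 for s in self.uncertainties.values()):
            raise ValueError("uncertainties must be non-negative")
        if self.mode == MODE_NONNEGATIVE and any(
            c < 0 for c in self.concentrations.values()
        ):
            raise ValueError("nonnegative mode cannot return negative concentrations")


def _check_collinearity(design: np.ndarray, names: list[str]) -> None:
    gram = design.T @ design
    if np.linalg.cond(gram) <= CONDITION_LIMIT:
        return
    # report the most correlated pair
    norms = np.sqrt(np.diag(gram))
    corr = gram / np.outer(norms, norms)
    np.fill_diagonal(corr, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
    raise CollinearityError(
        f"basis is rank-deficient over this grid; most collinear pair: "
        f"{names[i]!r} and {names[j]!r} (|corr|={abs(corr[i, j]):.6f})"
    )


def fit_concentrations(
    mu_a: Spectrum,
    basis: ChromophoreBasis,
    components: list[str] | None = None,
    mode: str = MODE_NONNEGATIVE,
    fixed: dict[str, float] | None = None,
) -> ConcentrationFit:
    """Least-squares decomposition of an absorption spectrum.

    Parameters
    ----------
    components
        Basis components to fit (defaults to every component in the basis).
    mode
        ``"nonnegative"`` (NNLS) or ``"unconstrained"`` (OLS).
    fixed
        Optional components held at a known value (e.g. the recipe gelatin
        mass fraction); their contribution is subtracted before fitting and
        they are reported with zero uncertainty.
    """
    components = list(basis.names if components is None else components)
    missing = [c for c in components if c not in basis.components]
    if missing:
        raise KeyError(f"components not in basis: {missing}")
    if not np.array_equal(mu_a.wavelengths_nm, basis.grid):
        raise GridError("absorption spectrum is not on the basis grid")
    fixed = dict(fixed or {})
    free = [c for c in components if c not in fixed]
    y = mu_a.values.astype(float).copy()
    for name, value in fixed.items():
        y -= value * basis.components[name].values
    design = basis.design_matrix(free)
    n_lam, k = design.shape
    dof = n_lam - k
    if dof < 1:
        raise ValueError("need more wavelengths than fitted components")
    _check_collinearity(design, free)
    if mode == MODE_NONNEGATIVE:
        coef, _ = nnls(design, y)
    elif mode == MODE_UNCONSTRAINED:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    resid = y - design @ coef
    chi2 = float(resid @ resid)
    cov_unscaled = np.linalg.inv(design.T @ design)
    sigma = np.sqrt(np.clip(np.diag(cov_unscaled), 0.0, None) * chi2 / dof)
    concentrations = {name: float(c) for name, c in zip(free, coef)}
    uncertainties = {name: float(s) for name, s in zip(free, sigma)}
    for name, value in fixed.items():
        concentrations[name] = float(value)
        uncertainties[name] = 0.0
    units = {name: basis.concentration_unit(name) for name in components}
    return ConcentrationFit(
        concentrations={c: concentrations[c] for c in components},
        uncertainties={c: uncertainties[c] for c in components},
        chi2=chi2,
        dof=dof,
        mode=mode,
        units=units,
    )


def unmix_timecourse(
    series: list[tuple[float, OpticalProperties]],
    basis: ChromophoreBasis,
    components: list[str] | None = None,
    mode: str = MODE_NONNEGATIVE,
    fixed: dict[str, float] | None = None,
) -> list[tuple[float, ConcentrationFit]]:
    """Fit each timepoint independently; output sorted by time.

    Errors from individual fits are re-raised with the timepoint attached.
    """
    if not series:
        raise ValueError("timecourse needs at least one timepoint")
    out = []
    for t, props in sorted(series, key=lambda item: item[0]):
        spectrum = Spectrum(props.wavelengths_nm, np.clip(props.mu_a, 0.0, None))
        try:
            fit = fit_concentrations(spectrum, basis, components, mode=mode, fixed=fixed)
        except (ValueError, KeyError) as exc:
            raise type(exc)(f"timepoint {t}: {exc}") from exc
        out.append((t, fit))
    return out


class ChromophoreUnmixer:
    """Scikit-learn-style transformer from absorption spectra to concentrations.

    Parameters are the basis, the component list and the fit mode; ``fit``
    validates the design matrix (``design_matrix_``, ``components_``) and
    ``transform`` maps (n_samples, n_wavelengths) absorption rows to
    (n_samples, n_components) concentration rows.
    """

    def __init__(
        self,
        basis: ChromophoreBasis = None,
        components: list[str] | None = None,
        mode: str = MODE_NONNEGATIVE,
    ):
        self.basis = basis
        self.components = components
        self.mode = mode

    def get_params(self, deep: bool = True) -> dict:
        return {"basis": self.basis, "components": self.components, "mode": self.mode}

    def set_params(self, **params) -> "ChromophoreUnmixer":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for ChromophoreUnmixer")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "ChromophoreUnmixer":
        if self.basis is None:
            raise ValueError("ChromophoreUnmixer requires a basis")
        self.components_ = list(self.components or self.basis.names)
        design = self.basis.design_matrix(self.components_)
        _check_collinearity(design, self.components_)
        self.design_matrix_ = design
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "design_matrix_"):
            raise RuntimeError("ChromophoreUnmixer is not fitted; call fit() first")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.design_matrix_.shape[0]:
            raise ValueError(
                f"X must have {self.design_matrix_.shape[0]} wavelength columns"
            )
        out = np.empty((X.shape[0], len(self.components_)))
        for row in range(X.shape[0]):
            if self.mode == MODE_NONNEGATIVE:
                coef, _ = nnls(self.design_matrix_, X[row])
            else:
                coef, *_ = np.linalg.lstsq(self.design_matrix_, X[row], rcond=None)
            out[row] = coef
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit().transform(X)
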