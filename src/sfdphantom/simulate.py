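"""Synthetic phantom studies with the statistical structure of a real one.

The generator composes the whole forward chain — recipe -> nominal truth
concentrations -> batch and spatial variability -> temporal drift -> expected
optical properties -> spatial-frequency reflectance -> multiplicative
measurement noise — so every downstream stage (inversion, unmixing,
regression, stability) can be exercised and scored against known truth.

Emulated phenomenology:

* a four-level total-water-fraction ladder (0.97/0.88/0.68/0.48) at fixed
  10% Intralipid-20%, fabricated in multiple batches with repeated
  measurements per phantom;
* hemoglobin phantoms from ferrous-stabilized powder (MetHb contamination
  present at time zero, fast HbO2 -> MetHb auto-oxidation) or whole blood
  (essentially MetHb-free at time zero, slow conversion);
* first-order HbO2 -> MetHb conversion with conserved total heme;
* a small early water loss that plateaus after about two days;
* batch-to-batch and within-phantom (spatial) variability as independent
  lognormal factors on the true concentrations, and gain-like multiplicative
  Gaussian noise on the calibrated reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .basis import ChromophoreBasis, make_reference_basis
from .forward import DEFAULT_FREQUENCIES_MM1, DEFAULT_REFRACTIVE_INDEX, SFDMeasurement, diffusion_reflectance
from .inverse import OpticalProperties
from .recipe import (
    PhantomRecipe,
    ScatteringModel,
    WATER_LADDER_RECIPES,
    expected_absorption,
    expected_scattering,
    nominal_concentrations,
)

#: default measurement schedule: 2 h, 4 h, 1 d, 2 d, 3 d, 4 d
DEFAULT_TIMEPOINTS_DAYS = (2 / 24, 4 / 24, 1.0, 2.0, 3.0, 4.0)

#: (total heme uM, initial MetHb fraction, conversion rate /day) per scenario;
#: magnitudes are tuning constants chosen to echo fitted hemoglobin phantoms
SCENARIO_DEFAULTS = {
    "none": (0.0, 0.0, 0.0),
    "ferrous_powder": (3.2, 0.35, 1.0),
    "whole_blood": (4.2, 0.05, 0.08),
}


def methb_drift(
    c_hbo2_0: float, c_methb_0: float, k_per_day: float, times_days: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-order HbO2 -> MetHb conversion; total heme is conserved.

    HbO2(t) = c0 exp(-k t); MetHb(t) = m0 + c0 (1 - exp(-k t)).
    """
    t = np.asarray(times_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if k_per_day < 0 or c_hbo2_0 < 0 or c_methb_0 < 0:
        raise ValueError("rate and initial concentrations must be non-negative")
    decay = np.exp(-k_per_day * t)
    return c_hbo2_0 * decay, c_methb_0 + c_hbo2_0 * (1.0 - decay)


def water_drift(
    f0: float, early_loss: float, plateau_day: float, times_days: np.ndarray
) -> np.ndarray:
    """Early linear water loss reaching a stable plateau.

    Declines linearly from f0 at t=0 to f0*(1 - early_loss) at ``plateau_day``
    and stays constant afterwards.  Defaults elsewhere (8% by day 2) emulate
    the small initial evaporation of refrigerated gelatin phantoms.
    """
    t = np.asarray(times_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not 0.0 <= early_loss < 1.0:
        raise ValueError("early_loss must lie in [0, 1)")
    if plateau_day <= 0:
        return np.full_like(t, f0 * (1.0 - early_loss))
    frac = np.minimum(t / plateau_day, 1.0)
    return f0 * (1.0 - early_loss * frac)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Everything needed to regenerate a study bit-exactly, except the seed."""

    recipes: tuple[PhantomRecipe, ...] = WATER_LADDER_RECIPES
    gelatin_type: str = "store_bought"
    scenario: str = "none"
    heme_total_uM: float | None = None
    initial_methb_fraction: float | None = None
    conversion_rate_per_day: float | None = None
    water_early_loss: float = 0.08
    water_plateau_day: float = 2.0
    reflectance_noise_sd: float = 0.01
    batch_sd: float = 0.05
    spatial_sd: float = 0.03
    timepoints_days: tuple[float, ...] = DEFAULT_TIMEPOINTS_DAYS
    n_batches: int = 3
    n_spatial_repeats: int = 3
    wavelength_step_nm: float = 0.5
    wavelength_range_nm: tuple[float, float] = (450.0, 1000.0)
    fx: tuple[float, ...] = tuple(DEFAULT_FREQUENCIES_MM1)
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    scattering: ScatteringModel = field(default_factory=ScatteringModel)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_DEFAULTS:
            raise ValueError(f"unknown hemoglobin scenario {self.scenario!r}")
        for name in ("reflectance_noise_sd", "batch_sd", "spatial_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_batches < 1 or self.n_spatial_repeats < 1:
            raise ValueError("need at least one batch and one repeat")
        if len(self.timepoints_days) < 1:
            raise ValueError("need at least one timepoint")

    def resolved_scenario(self) -> tuple[float, float, float]:
        total, mfrac, k = SCENARIO_DEFAULTS[self.scenario]
        if self.heme_total_uM is not None:
            total = self.heme_total_uM
        if self.initial_methb_fraction is not None:
            mfrac = self.initial_methb_fraction
        if self.conversion_rate_per_day is not None:
            k = self.conversion_rate_per_day
        return total, mfrac, k

    def wavelength_grid(self) -> np.ndarray:
        lo, hi = self.wavelength_range_nm
        return np.arange(lo, hi + self.wavelength_step_nm / 2, self.wavelength_step_nm)


@dataclass(frozen=True)
class StudyCell:
    """One simulated measurement: truth plus noisy observation."""

    recipe_index: int
    batch: int
    repeat: int
    timepoint_days: float
    truth_concentrations: dict[str, float]
    truth_properties: OpticalProperties
    measurement: SFDMeasurement


@dataclass(frozen=True)
class SyntheticStudy:
    config: SyntheticStudyConfig
    seed: int
    basis: ChromophoreBasis
    cells: tuple[StudyCell, ...]

    def select(self, **criteria) -> list[StudyCell]:
        """Cells matching every given attribute (recipe_index, batch, ...)."""
        out = []
        for cell in self.cells:
            if all(getattr(cell, key) == value for key, value in criteria.items()):
                out.append(cell)
        return out


def _gelatin_component(gelatin_type: str) -> str:
    return f"gelatin_{gelatin_type}"


def config_to_dict(config: SyntheticStudyConfig) -> dict:
    """JSON-serializable echo of the config (recipes inlined)."""
    from .io import recipe_to_dict  # local import to avoid a cycle

    out = {
        "recipes": [recipe_to_dict(r) for r in config.recipes],
        "gelatin_type": config.gelatin_type,
        "scenario": config.scenario,
        "heme_total_uM": config.heme_total_uM,
        "initial_methb_fraction": config.initial_methb_fraction,
        "conversion_rate_per_day": config.conversion_rate_per_day,
        "water_early_loss": config.water_early_loss,
        "water_plateau_day": config.water_plateau_day,
        "reflectance_noise_sd": config.reflectance_noise_sd,
        "batch_sd": config.batch_sd,
        "spatial_sd": config.spatial_sd,
        "timepoints_days": list(config.timepoints_days),
        "n_batches": config.n_batches,
        "n_spatial_repeats": config.n_spatial_repeats,
        "wavelength_step_nm": config.wavelength_step_nm,
        "wavelength_range_nm": list(config.wavelength_range_nm),
        "fx": list(config.fx),
        "refractive_index": config.refractive_index,
        "scattering": {
            "amplitude_mm1": config.scattering.amplitude_mm1,
            "reference_wavelength_nm": config.scattering.reference_wavelength_nm,
            "rayleigh_fraction": config.scattering.rayleigh_fraction,
            "mie_power": config.scattering.mie_power,
        },
    }
    return out


def config_from_dict(data: dict) -> SyntheticStudyConfig:
    from .io import recipe_from_dict  # local import to avoid a cycle

    data = dict(data)
    kwargs = {}
    if "recipes" in data:
        kwargs["recipes"] = tuple(recipe_from_dict(d) for d in data.pop("recipes"))
    if "scattering" in data:
        kwargs["scattering"] = ScatteringModel(**data.pop("scattering"))
    for key in (
        "timepoints_days",
        "wavelength_range_nm",
        "fx",
    ):
        if key in data:
            data[key] = tuple(data[key])
    kwargs.update(data)
    return SyntheticStudyConfig(**kwargs)


def generate_study(config: SyntheticStudyConfig, seed: int = 0) -> SyntheticStudy:
    """Simulate the full study; identical (config, seed) gives identical output.

    Batches draw from independent child streams of the root seed, so adding a
    batch never perturbs the previous ones.
    """
    grid = config.wavelength_grid()
    fx = np.asarray(config.fx, dtype=float)
    basis = make_reference_basis(grid, include_gelatin_defaults=True)
    gel_name = _gelatin_component(config.gelatin_type)
    heme_total, methb_frac, k_rate = config.resolved_scenario()
    times = np.asarray(config.timepoints_days, dtype=float)

    chromophores = ["water", gel_name]
    if config.scenario != "none":
        chromophores += ["HbO2", "MetHb"]

    root = np.random.SeedSequence(seed)
    batch_streams = [np.random.default_rng(s) for s in root.spawn(config.n_batches)]

    cells: list[StudyCell] = []
    for batch, rng in enumerate(batch_streams):
        batch_factors = {
            name: float(np.exp(rng.normal(0.0, config.batch_sd))) for name in chromophores
        }
        for recipe_index, recipe in enumerate(config.recipes):
            recipe = replace(recipe, gelatin_type=config.gelatin_type)
            nominal = nominal_concentrations(recipe)
            base = {
                "water": nominal["water"],
                gel_name: nominal["gelatin"],
            }
            if config.scenario != "none":
                base["HbO2"] = heme_total * (1.0 - methb_frac)
                base["MetHb"] = heme_total * methb_frac
            musp = expected_scattering(recipe, config.scattering, grid)
            for repeat in range(config.n_spatial_repeats):
                spatial_factors = {
                    name: float(np.exp(rng.normal(0.0, config.spatial_sd)))
                    for name in chromophores
                }
                start = {
                    name: base[name] * batch_factors[name] * spatial_factors[name]
                    for name in base
                }
                water_t = water_drift(
                    start["water"], config.water_early_loss, config.water_plateau_day, times
                )
                if config.scenario != "none":
                    hbo2_t, methb_t = methb_drift(
                        start["HbO2"], start["MetHb"], k_rate, times
                    )
                for t_index, t in enumerate(times):
                    conc = {
                        "water": float(water_t[t_index]),
                        gel_name: start[gel_name],
                    }
                    if config.scenario != "none":
                        conc["HbO2"] = float(hbo2_t[t_index])
                        conc["MetHb"] = float(methb_t[t_index])
                        conc["Hb"] = 0.0
                    mu_a = expected_absorption(basis, conc)
                    rd = diffusion_reflectance(
                        np.maximum(mu_a.values[:, None], 1e-12),
                        musp.values[:, None],
                        fx[None, :],
                        n=config.refractive_index,
                    )
                    if config.reflectance_noise_sd > 0:
                        gain = 1.0 + rng.normal(0.0, config.reflectance_noise_sd, rd.shape)
                        rd = rd * gain
                    rd = np.clip(rd, 0.0, 1.0)
                    props = OpticalProperties(grid.copy(), mu_a.values, musp.values)
                    meas = SFDMeasurement(
                        grid.copy(),
                        fx,
                        rd,
                        meta={
                            "recipe_index": recipe_index,
                            "batch": batch,
                            "repeat": repeat,
                            "timepoint_days": float(t),
                        },
                    )
                    cells.append(
                        StudyCell(
                            recipe_index=recipe_index,
                            batch=batch,
                            repeat=repeat,
                            timepoint_days=float(t),
                            truth_concentrations=conc,
                            truth_properties=props,
                            measurement=meas,
                        )
                    )
    return SyntheticStudy(config=config, seed=seed, basis=basis, cells=tuple(cells))
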