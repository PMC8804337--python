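"""End-to-end helpers chaining simulate -> invert -> unmix -> analyze.

These are the drivers behind the ``report`` command and the recovery studies:
given a (synthetic or loaded) study, invert every measurement to optical
properties, unmix the absorption spectra, and condense the results into the
water-fraction regression and per-chromophore stability summaries.
"""

from __future__ import annotations

import numpy as np

from .analysis import RegressionResult, StabilityResult, regress_water_fraction, stability_period
from .inverse import SFDInverter
from .recipe import total_water_fraction
from .simulate import SyntheticStudy, _gelatin_component
from .unmixing import MODE_NONNEGATIVE, MODE_UNCONSTRAINED, fit_concentrations
from .basis import Spectrum


def default_inverter(study: SyntheticStudy) -> SFDInverter:
    return SFDInverter(fx=tuple(study.config.fx), n=study.config.refractive_index).fit()


def estimate_cell_concentrations(
    study: SyntheticStudy,
    inverter: SFDInverter | None = None,
    components: list[str] | None = None,
    mode: str | None = None,
) -> list[dict]:
    """Invert and unmix every cell; returns one record per cell.

    Water/gelatin-only studies are fit unconstrained (water above 1 is allowed
    and diagnostic); hemoglobin studies are fit non-negatively over
    {HbO2, Hb, MetHb, water, gelatin}.
    """
    inverter = inverter or default_inverter(study)
    gel = _gelatin_component(study.config.gelatin_type)
    if components is None:
        if study.config.scenario == "none":
            components = ["water", gel]
            mode = mode or MODE_UNCONSTRAINED
        else:
            components = ["HbO2", "Hb", "MetHb", "water", gel]
            mode = mode or MODE_NONNEGATIVE
    mode = mode or MODE_UNCONSTRAINED
    records = []
    for cell in study.cells:
        props = inverter.invert(cell.measurement)
        spectrum = Spectrum(props.wavelengths_nm, np.clip(props.mu_a, 0.0, None))
        fit = fit_concentrations(spectrum, study.basis, components, mode=mode)
        records.append(
            {
                "recipe_index": cell.recipe_index,
                "batch": cell.batch,
                "repeat": cell.repeat,
                "timepoint_days": cell.timepoint_days,
                "fit": fit,
                "properties": props,
            }
        )
    return records


def water_ladder_pairs(
    study: SyntheticStudy,
    records: list[dict] | None = None,
    timepoint_days: float | None = None,
) -> list[tuple[float, float]]:
    """(total water fraction, mean estimated water fraction) per recipe.

    Estimates are averaged over batches and spatial repeats at one timepoint
    (default: the first, before any drift has acted).
    """
    records = records if records is not None else estimate_cell_concentrations(study)
    if timepoint_days is None:
        timepoint_days = min(r["timepoint_days"] for r in records)
    pairs = []
    for recipe_index, recipe in enumerate(study.config.recipes):
        est = [
            r["fit"].concentrations["water"]
            for r in records
            if r["recipe_index"] == recipe_index
            and np.isclose(r["timepoint_days"], timepoint_days)
        ]
        pairs.append((total_water_fraction(recipe), float(np.mean(est))))
    return pairs


def ladder_regressions(
    study: SyntheticStudy, records: list[dict] | None = None
) -> dict[str, RegressionResult]:
    pairs = water_ladder_pairs(study, records)
    return {
        "water_unconstrained": regress_water_fraction(pairs, constrained=False),
        "water_constrained": regress_water_fraction(pairs, constrained=True),
    }


def component_stability(
    study: SyntheticStudy,
    records: list[dict],
    component: str,
    recipe_index: int = 0,
    threshold: float = 0.10,
) -> StabilityResult:
    """Stability of one fitted chromophore, meaned over batches/repeats per timepoint."""
    times = sorted({r["timepoint_days"] for r in records if r["recipe_index"] == recipe_index})
    means = []
    for t in times:
        vals = [
            r["fit"].concentrations[component]
            for r in records
            if r["recipe_index"] == recipe_index and np.isclose(r["timepoint_days"], t)
        ]
        means.append(float(np.mean(vals)))
    return stability_period(
        np.asarray(times), np.asarray(means), threshold=threshold, component=component
    )
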