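"""Text formats: spectra, reflectance, optical properties, timecourses, recipes.

All formats are plain CSV/JSON so every intermediate of the pipeline can be
inspected and diffed.  Numeric columns are written with 10 significant digits,
which the readers recover exactly at the precision the writers guarantee.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import ABSORPTION, ChromophoreBasis, Spectrum
from .forward import SFDMeasurement
from .inverse import OpticalProperties
from .recipe import HemoglobinAdditive, PhantomRecipe
from .unmixing import ConcentrationFit

_FLOAT_FMT = "%.10g"


def write_spectrum_csv(path, spectrum: Spectrum, comments: dict | None = None) -> None:
    """Two columns ``wavelength_nm,value``; ``#``-comments carry the unit tag."""
    path = Path(path)
    lines = [f"# unit: {spectrum.unit}"]
    for key, value in (comments or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append("wavelength_nm,value")
    for lam, val in zip(spectrum.wavelengths_nm, spectrum.values):
        lines.append(f"{lam:.10g},{val:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path) -> Spectrum:
    path = Path(path)
    unit = ABSORPTION
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("unit:"):
                    unit = body.split(":", 1)[1].strip()
                continue
            if line.startswith("wavelength_nm"):
                continue
            lam, val = line.split(",")
            rows.append((float(lam), float(val)))
    lam, val = zip(*rows)
    return Spectrum(np.asarray(lam), np.asarray(val), unit=unit)


def write_basis_dir(path, basis: ChromophoreBasis) -> None:
    """One CSV per component; file stem = component name."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, spectrum in basis.components.items():
        write_spectrum_csv(path / f"{name}.csv", spectrum)


def read_basis_dir(path) -> ChromophoreBasis:
    path = Path(path)
    components = {p.stem: read_spectrum_csv(p) for p in sorted(path.glob("*.csv"))}
    return ChromophoreBasis(components)


def write_reflectance_csv(path, measurement: SFDMeasurement) -> None:
    """Long format ``wavelength_nm,fx_mm^-1,Rd``; lossless round trip."""
    lam = np.repeat(measurement.wavelengths_nm, measurement.spatial_frequencies_mm1.size)
    fx = np.tile(measurement.spatial_frequencies_mm1, measurement.wavelengths_nm.size)
    df = pd.DataFrame(
        {"wavelength_nm": lam, "fx_mm^-1": fx, "Rd": measurement.reflectance.ravel()}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_reflectance_csv(path, meta: dict | None = None) -> SFDMeasurement:
    df = pd.read_csv(path)
    lam = np.unique(df["wavelength_nm"].to_numpy())
    fx = np.unique(df["fx_mm^-1"].to_numpy())
    pivot = df.pivot(index="wavelength_nm", columns="fx_mm^-1", values="Rd")
    pivot = pivot.sort_index().reindex(sorted(pivot.columns), axis=1)
    return SFDMeasurement(lam, fx, pivot.to_numpy(), meta=meta or {})


def write_optical_properties_csv(path, props: OpticalProperties) -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": props.wavelengths_nm,
            "mu_a_mm^-1": props.mu_a,
            "mu_s_prime_mm^-1": props.mu_s_prime,
            "residual": props.fit_residual,
            "flag": props.flags,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_optical_properties_csv(path) -> OpticalProperties:
    df = pd.read_csv(path)
    return OpticalProperties(
        df["wavelength_nm"].to_numpy(float),
        df["mu_a_mm^-1"].to_numpy(float),
        df["mu_s_prime_mm^-1"].to_numpy(float),
        fit_residual=df["residual"].to_numpy(float),
        flags=df["flag"].to_numpy(object),
    )


_TIMECOURSE_SPECIES = ("HbO2", "Hb", "MetHb")


def write_timecourse_csv(path, series: list[tuple[float, ConcentrationFit]]) -> None:
    """Concentration timecourse with 1-sigma errors.

    Hemoglobin species are uM of tetramer (MW 64,500 g/mol); water is a
    volume fraction.  Missing species are left blank.
    """
    rows = []
    for t, fit in series:
        row: dict[str, float] = {"timepoint_days": t}
        for name in _TIMECOURSE_SPECIES:
            if name in fit.concentrations:
                row[f"{name}_uM"] = fit.concentrations[name]
                row[f"{name}_sd"] = fit.uncertainties[name]
        if "water" in fit.concentrations:
            row["water_frac"] = fit.concentrations["water"]
            row["water_sd"] = fit.uncertainties["water"]
        for name in fit.concentrations:
            if name.startswith("gelatin"):
                row["gelatin_frac"] = fit.concentrations[name]
                row["gelatin_sd"] = fit.uncertainties[name]
        row["chi2"] = fit.chi2
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def recipe_to_dict(recipe: PhantomRecipe) -> dict:
    out = {
        "water_wt_pct": recipe.water_wt_pct,
        "gelatin_wt_pct": recipe.gelatin_wt_pct,
        "intralipid20_wt_pct": recipe.intralipid20_wt_pct,
        "gelatin_type": recipe.gelatin_type,
        "batch_label": recipe.batch_label,
        "total_mass_g": recipe.total_mass_g,
    }
    if recipe.hemoglobin_additive is not None:
        out["hemoglobin_additive"] = {
            "kind": recipe.hemoglobin_additive.kind,
            "amount": recipe.hemoglobin_additive.amount,
            "unit": recipe.hemoglobin_additive.unit,
        }
    return out


def recipe_from_dict(data: dict) -> PhantomRecipe:
    additive = None
    if data.get("hemoglobin_additive"):
        additive = HemoglobinAdditive(**data["hemoglobin_additive"])
    return PhantomRecipe(
        water_wt_pct=float(data["water_wt_pct"]),
        gelatin_wt_pct=float(data["gelatin_wt_pct"]),
        intralipid20_wt_pct=float(data["intralipid20_wt_pct"]),
        gelatin_type=data.get("gelatin_type", "store_bought"),
        hemoglobin_additive=additive,
        batch_label=data.get("batch_label", ""),
        total_mass_g=float(data.get("total_mass_g", 30.5)),
    )


def write_study_bundle(path, study) -> dict:
    """Write a study as recipe JSON + per-cell reflectance CSVs + a manifest.

    The manifest records the schema version, seed, full config echo, one entry
    per cell (file name, indices, truth concentrations) and the SHA-256 of
    every written CSV, so a bundle is self-describing and verifiable.
    """
    import hashlib

    from .simulate import config_to_dict

    path = Path(path)
    (path / "cells").mkdir(parents=True, exist_ok=True)
    write_recipes_json(path / "recipes.json", study.config.recipes)
    cell_entries = []
    for index, cell in enumerate(study.cells):
        name = f"cells/cell_{index:04d}.csv"
        write_reflectance_csv(path / name, cell.measurement)
        digest = hashlib.sha256((path / name).read_bytes()).hexdigest()
        cell_entries.append(
            {
                "file": name,
                "sha256": digest,
                "recipe_index": cell.recipe_index,
                "batch": cell.batch,
                "repeat": cell.repeat,
                "timepoint_days": cell.timepoint_days,
                "truth_concentrations": cell.truth_concentrations,
            }
        )
    manifest = {
        "schema_version": 1,
        "seed": study.seed,
        "config": config_to_dict(study.config),
        "cells": cell_entries,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_study_bundle(path):
    """Rehydrate a study bundle; truth properties are not stored on disk."""
    from .basis import make_reference_basis
    from .simulate import StudyCell, SyntheticStudy, config_from_dict

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    config = config_from_dict(manifest["config"])
    basis = make_reference_basis(config.wavelength_grid(), include_gelatin_defaults=True)
    cells = []
    for entry in manifest["cells"]:
        meas = read_reflectance_csv(
            path / entry["file"],
            meta={k: entry[k] for k in ("recipe_index", "batch", "repeat", "timepoint_days")},
        )
        cells.append(
            StudyCell(
                recipe_index=entry["recipe_index"],
                batch=entry["batch"],
                repeat=entry["repeat"],
                timepoint_days=entry["timepoint_days"],
                truth_concentrations=entry.get("truth_concentrations"),
                truth_properties=None,
                measurement=meas,
            )
        )
    return SyntheticStudy(
        config=config, seed=manifest["seed"], basis=basis, cells=tuple(cells)
    )


def write_recipes_json(path, recipes) -> None:
    Path(path).write_text(json.dumps([recipe_to_dict(r) for r in recipes], indent=2) + "\n")


def read_recipes_json(path) -> list[PhantomRecipe]:
    return [recipe_from_dict(d) for d in json.loads(Path(path).read_text())]
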