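"""Study-level summaries: water-fraction regression and the stability period.

Two analyses condense a phantom study.  First, a simple linear regression of
the spectroscopically estimated water fraction against the total water
fraction designed into the recipe, either unconstrained (OLS) or constrained
through the origin (a pure-gelatin phantom must present zero water).  Second,
a stability criterion: a chromophore is stable for as long as its mean
concentration stays within a threshold (default 10%) of its initial estimate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np


class RegressionError(ValueError):
    """Degenerate regression input."""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    constrained: bool
    n_points: int


@dataclass(frozen=True)
class StabilityResult:
    component: str
    initial_value: float
    threshold_fraction: float
    last_stable_timepoint: float
    stable_through: float
    timepoints: tuple
    relative_deviations: tuple


def regress_water_fraction(
    pairs: list[tuple[float, float]], constrained: bool = False
) -> RegressionResult:
    """Fit estimated = slope * total (+ intercept) over the study phantoms.

    Unconstrained: ordinary least squares.  Constrained: intercept fixed at
    zero, slope = sum(xy)/sum(x^2).  R^2 is reported against the grand-mean
    null model in both cases, so a constrained fit can in principle go
    negative; RMSE is the root mean squared residual.
    """
    if not pairs:
        raise RegressionError("no points")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if constrained:
        if x.size < 1 or np.all(x == 0):
            raise RegressionError("constrained fit needs at least one nonzero x")
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        if x.size < 2 or np.ptp(x) == 0:
            raise RegressionError("unconstrained fit needs >= 2 distinct x values")
        slope, intercept = np.polyfit(x, y, 1)
        slope, intercept = float(slope), float(intercept)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / max(ss_tot, 1e-300)
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(r_squared),
        rmse=float(np.sqrt(ss_res / x.size)),
        constrained=constrained,
        n_points=int(x.size),
    )


def stability_period(
    timepoints: np.ndarray,
    values: np.ndarray,
    threshold: float = 0.10,
    component: str = "",
) -> StabilityResult:
    """Longest initial window within ``threshold`` of the first estimate.

    ``values`` may be 1-D (one measurement per timepoint) or 2-D
    (timepoints x replicates); replicates are averaged before thresholding.
    The deviation at time t is |c(t) - c(t0)| / |c(t0)|; the last stable
    timepoint is the latest t such that every timepoint up to and including t
    deviates by at most the threshold.  The first timepoint is stable by
    definition.
    """
    t = np.asarray(timepoints, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.ndim == 2:
        v = v.mean(axis=1)
    if t.size == 0 or v.shape != t.shape:
        raise ValueError("timepoints and values must be congruent and non-empty")
    if not np.all(np.diff(t) > 0):
        raise ValueError("timepoints must be strictly increasing")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    initial = v[0]
    if initial == 0:
        raise ZeroDivisionError("initial estimate is zero; stability undefined")
    dev = np.abs(v - initial) / abs(initial)
    within = dev <= threshold + 1e-15
    # prefix rule: stability ends at the first excursion
    stable_mask = np.cumprod(within).astype(bool)
    last_idx = int(np.max(np.nonzero(stable_mask)[0]))
    return StabilityResult(
        component=component,
        initial_value=float(initial),
        threshold_fraction=float(threshold),
        last_stable_timepoint=float(t[last_idx]),
        stable_through=float(t[last_idx] - t[0]),
        timepoints=tuple(float(tt) for tt in t),
        relative_deviations=tuple(float(d) for d in dev),
    )


def write_report(
    path_json,
    path_txt,
    regressions: dict[str, RegressionResult],
    stabilities: dict[str, StabilityResult],
    extra: dict | None = None,
) -> dict:
    """Serialize the study summary as JSON plus a human-readable text mirror."""
    payload = {
        "regressions": {k: asdict(v) for k, v in regressions.items()},
        "stability": {k: asdict(v) for k, v in stabilities.items()},
    }
    if extra:
        payload.update(extra)
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2)
    lines = ["phantom study report", "===================", ""]
    for name, reg in regressions.items():
        form = f"y = {reg.slope:.4g}*x" + (
            "" if reg.constrained else f" {reg.intercept:+.4g}"
        )
        lines.append(
            f"regression [{name}] ({'constrained' if reg.constrained else 'unconstrained'}): "
            f"{form}, R^2 = {reg.r_squared:.4g}, RMSE = {reg.rmse:.3g}, n = {reg.n_points}"
        )
    for name, st in stabilities.items():
        lines.append(
            f"stability [{name}]: within {st.threshold_fraction:.0%} of initial "
            f"{st.initial_value:.4g} through t = {st.last_stable_timepoint:g}"
        )
    with open(path_txt, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return payload
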