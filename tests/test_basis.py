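import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfdphantom.basis import (
    ABSORPTION,
    ChromophoreBasis,
    DilutionSeriesPoint,
    GridError,
    SPECABS_VOLFRAC,
    Spectrum,
    estimate_gelatin_spectrum,
    make_reference_basis,
    resample_basis,
)


class TestSpectrum:
    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(np.array([500.0, 500.0]), np.array([1.0, 2.0]))

    def test_rejects_negative_absorption(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum(np.array([500.0, 600.0]), np.array([1.0, -0.1]), unit=ABSORPTION)

    def test_rejects_out_of_band_wavelengths(self):
        with pytest.raises(ValueError, match="1100"):
            Spectrum(np.array([500.0, 1150.0]), np.array([1.0, 1.0]))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 600.0]), np.array([1.0]))


class TestResample:
    def test_identity_on_shared_grid(self):
        grid = np.linspace(500.0, 700.0, 21)
        basis = ChromophoreBasis(
            {"water": Spectrum(grid, np.linspace(0.1, 1.0, 21), unit=SPECABS_VOLFRAC)}
        )
        out = resample_basis(basis, grid)
        np.testing.assert_array_equal(out.components["water"].values, basis.components["water"].values)
        assert out.components["water"].unit == SPECABS_VOLFRAC

    def test_linear_midpoint(self):
        basis = ChromophoreBasis(
            {"c": Spectrum(np.array([500.0, 502.0]), np.array([1.0, 2.0]), unit=SPECABS_VOLFRAC)}
        )
        out = resample_basis(basis, np.array([501.0]))
        assert out.components["c"].values[0] == pytest.approx(1.5)

    def test_extrapolation_names_component(self):
        basis = ChromophoreBasis(
            {"hb": Spectrum(np.array([450.0, 600.0]), np.array([1.0, 2.0]), unit=SPECABS_VOLFRAC)}
        )
        with pytest.raises(GridError, match="hb"):
            resample_basis(basis, np.array([449.0, 500.0]))

    def test_monotone_between_nodes(self):
        grid = np.array([500.0, 510.0])
        basis = ChromophoreBasis({"c": Spectrum(grid, np.array([1.0, 3.0]), unit=SPECABS_VOLFRAC)})
        fine = resample_basis(basis, np.linspace(500.0, 510.0, 50))
        assert np.all(np.diff(fine.components["c"].values) >= 0)


class TestReferenceBasis:
    def test_water_peak_near_970(self, reference_basis):
        water = reference_basis.components["water"]
        band = (water.wavelengths_nm >= 900) & (water.wavelengths_nm <= 1000)
        peak = water.wavelengths_nm[band][np.argmax(water.values[band])]
        assert 960 <= peak <= 980

    def test_methb_local_maximum_near_630(self, reference_basis):
        methb = reference_basis.components["MetHb"]
        band = (methb.wavelengths_nm >= 620) & (methb.wavelengths_nm <= 640)
        inner = methb.values[band]
        edge_lo = methb.values[np.searchsorted(methb.wavelengths_nm, 620) - 1]
        edge_hi = methb.values[np.searchsorted(methb.wavelengths_nm, 640) + 1]
        assert inner.max() > edge_lo and inner.max() > edge_hi

    def test_components_non_negative_and_finite(self, reference_basis):
        for name, spec in reference_basis.components.items():
            assert np.all(spec.values >= 0), name
            assert np.all(np.isfinite(spec.values)), name

    def test_minimum_component_set(self, reference_basis):
        assert {"HbO2", "Hb", "MetHb", "water"} <= set(reference_basis.names)

    def test_out_of_span_grid_rejected(self):
        with pytest.raises(GridError, match="span"):
            make_reference_basis(np.array([400.0, 500.0]))


def _dilution_series(grid, water, gelatin, levels):
    return [
        DilutionSeriesPoint(
            Spectrum(grid, fw * water.values + fg * gelatin.values), fw, fg
        )
        for fw, fg in levels
    ]


LADDER_LEVELS = [(0.97, 0.01), (0.88, 0.10), (0.68, 0.30), (0.48, 0.50)]


class TestGelatinEstimator:
    def test_recovers_generating_spectrum(self, reference_basis, coarse_grid):
        water = reference_basis.components["water"]
        gelatin = reference_basis.components["gelatin_research_grade"]
        series = _dilution_series(coarse_grid, water, gelatin, LADDER_LEVELS)
        est = estimate_gelatin_spectrum(series, water)
        assert np.max(np.abs(est.values - gelatin.values)) < 1e-6

    @pytest.mark.parametrize("joint", [False, True])
    def test_joint_and_mean_agree_when_noiseless(self, reference_basis, coarse_grid, joint):
        water = reference_basis.components["water"]
        gelatin = reference_basis.components["gelatin_store_bought"]
        series = _dilution_series(coarse_grid, water, gelatin, LADDER_LEVELS)
        est = estimate_gelatin_spectrum(series, water, joint=joint)
        assert np.max(np.abs(est.values - gelatin.values)) < 1e-6

    def test_pure_water_series_gives_zero(self, reference_basis, coarse_grid):
        water = reference_basis.components["water"]
        series = [
            DilutionSeriesPoint(Spectrum(coarse_grid, fw * water.values), fw, fg)
            for fw, fg in [(0.9, 0.1), (0.7, 0.3)]
        ]
        est = estimate_gelatin_spectrum(series, water)
        np.testing.assert_allclose(est.values, 0.0, atol=1e-12)

    @given(scale=st.floats(0.0, 5.0), fitted=st.booleans())
    def test_output_never_negative(self, reference_basis, coarse_grid, scale, fitted):
        water = reference_basis.components["water"]
        rng = np.random.default_rng(7)
        noisy = np.clip(
            0.8 * water.values + scale * 1e-3 * rng.standard_normal(coarse_grid.size),
            0.0,
            None,
        )
        series = [
            DilutionSeriesPoint(Spectrum(coarse_grid, noisy), 0.8, 0.1),
            DilutionSeriesPoint(Spectrum(coarse_grid, 0.5 * noisy), 0.4, 0.3),
        ]
        est = estimate_gelatin_spectrum(
            series, water, water_mode="fitted" if fitted else "known"
        )
        assert est.values.min() >= 0.0

    def test_all_zero_gelatin_fraction_rejected(self, reference_basis, coarse_grid):
        water = reference_basis.components["water"]
        series = [
            DilutionSeriesPoint(Spectrum(coarse_grid, water.values), 1.0, 0.0),
            DilutionSeriesPoint(Spectrum(coarse_grid, 0.5 * water.values), 0.5, 0.0),
        ]
        with pytest.raises(ValueError, match="distinct nonzero gelatin"):
            estimate_gelatin_spectrum(series, water)

    def test_grid_mismatch_rejected(self, reference_basis, coarse_grid):
        water = reference_basis.components["water"]
        other = Spectrum(coarse_grid[:-1], water.values[:-1])
        series = [
            DilutionSeriesPoint(other, 0.9, 0.1),
            DilutionSeriesPoint(other, 0.7, 0.3),
        ]
        with pytest.raises(GridError):
            estimate_gelatin_spectrum(series, water)
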