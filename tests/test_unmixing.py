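import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfdphantom.basis import ChromophoreBasis, Spectrum
from sfdphantom.inverse import OpticalProperties
from sfdphantom.recipe import expected_absorption
from sfdphantom.simulate import methb_drift
from sfdphantom.unmixing import (
    ChromophoreUnmixer,
    CollinearityError,
    MODE_NONNEGATIVE,
    MODE_UNCONSTRAINED,
    fit_concentrations,
    unmix_timecourse,
)

PANEL = ["HbO2", "Hb", "MetHb", "water", "gelatin_store_bought"]


def _mix(basis, conc):
    return expected_absorption(basis, conc)


class TestFitConcentrations:
    def test_noiseless_exact_recovery(self, reference_basis):
        truth = {"HbO2": 2.0, "MetHb": 1.1, "water": 0.8}
        fit = fit_concentrations(_mix(reference_basis, truth), reference_basis, PANEL)
        for name in PANEL:
            assert fit.concentrations[name] == pytest.approx(truth.get(name, 0.0), abs=1e-8)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_unconstrained_water_can_exceed_unity(self, reference_basis):
        mu_a = _mix(reference_basis, {"water": 1.09})
        fit = fit_concentrations(
            mu_a, reference_basis, ["water", "gelatin_store_bought"], mode=MODE_UNCONSTRAINED
        )
        assert fit.concentrations["water"] == pytest.approx(1.09, abs=1e-10)

    @given(k=st.floats(0.01, 10.0))
    def test_single_component_projection_is_exact(self, reference_basis, k):
        mu_a = _mix(reference_basis, {"MetHb": k})
        fit = fit_concentrations(mu_a, reference_basis, ["MetHb"])
        assert fit.concentrations["MetHb"] == pytest.approx(k, rel=1e-10)

    @given(
        conc=st.tuples(
            st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 1.0)
        )
    )
    def test_nonnegative_identifiability(self, reference_basis, conc):
        truth = dict(zip(["HbO2", "Hb", "MetHb", "water"], conc))
        fit = fit_concentrations(_mix(reference_basis, truth), reference_basis, PANEL)
        for name, value in truth.items():
            assert fit.concentrations[name] == pytest.approx(value, abs=1e-8)
        assert min(fit.concentrations.values()) >= 0.0

    def test_unconstrained_matches_normal_equations(self, reference_basis):
        rng = np.random.default_rng(5)
        design = reference_basis.design_matrix(PANEL)
        y = design @ rng.uniform(0, 2, len(PANEL)) + 1e-4 * rng.standard_normal(design.shape[0])
        y = np.clip(y, 0, None)
        mu_a = Spectrum(reference_basis.grid, y)
        fit = fit_concentrations(mu_a, reference_basis, PANEL, mode=MODE_UNCONSTRAINED)
        normal = np.linalg.solve(design.T @ design, design.T @ y)
        got = np.array([fit.concentrations[n] for n in PANEL])
        np.testing.assert_allclose(got, normal, atol=1e-10)

    def test_uncertainties_calibrated_against_replicates(self, reference_basis):
        # chi2-scaled covariance should match the empirical scatter of estimates
        rng = np.random.default_rng(17)
        sigma = 5e-4
        design = reference_basis.design_matrix(PANEL)
        truth = np.array([2.0, 0.5, 1.1, 0.8, 0.1])
        clean = design @ truth
        estimates, reported = [], []
        for _ in range(300):
            y = clean + sigma * rng.standard_normal(clean.size)
            fit = fit_concentrations(
                Spectrum(reference_basis.grid, np.clip(y, 0, None)),
                reference_basis,
                PANEL,
                mode=MODE_UNCONSTRAINED,
            )
            estimates.append([fit.concentrations[n] for n in PANEL])
            reported.append([fit.uncertainties[n] for n in PANEL])
        empirical = np.std(np.asarray(estimates), axis=0)
        mean_reported = np.mean(np.asarray(reported), axis=0)
        np.testing.assert_allclose(mean_reported, empirical, rtol=0.2)

    def test_pinned_species_keeps_unconstrained_uncertainty(self, reference_basis):
        design = reference_basis.design_matrix(PANEL)
        y = design @ np.array([2.0, 0.0, 1.1, 0.8, 0.0])
        # a small negative Hb component forces the non-negativity bound active
        y = np.clip(y - 0.02 * design[:, 1], 0.0, None)
        fit = fit_concentrations(
            Spectrum(reference_basis.grid, np.clip(y, 0, None)), reference_basis, PANEL
        )
        assert fit.concentrations["Hb"] == 0.0
        assert fit.uncertainties["Hb"] > 0.0

    def test_collinear_basis_names_offending_pair(self, reference_basis, coarse_grid):
        twin = dict(reference_basis.components)
        twin["water_twin"] = Spectrum(
            coarse_grid, twin["water"].values.copy(), unit=twin["water"].unit
        )
        basis = ChromophoreBasis(twin)
        with pytest.raises(CollinearityError, match="water"):
            fit_concentrations(
                _mix(basis, {"water": 0.5}), basis, ["water", "water_twin"]
            )

    def test_fixed_component_subtracted(self, reference_basis):
        truth = {"water": 0.88, "gelatin_store_bought": 0.10}
        fit = fit_concentrations(
            _mix(reference_basis, truth),
            reference_basis,
            ["water", "gelatin_store_bought"],
            mode=MODE_UNCONSTRAINED,
            fixed={"gelatin_store_bought": 0.10},
        )
        assert fit.concentrations["water"] == pytest.approx(0.88, abs=1e-10)
        assert fit.uncertainties["gelatin_store_bought"] == 0.0

    def test_needs_more_wavelengths_than_components(self, reference_basis):
        small_grid = reference_basis.grid[:4]
        from sfdphantom.basis import resample_basis

        tiny = resample_basis(reference_basis, small_grid)
        with pytest.raises(ValueError, match="wavelength"):
            fit_concentrations(_mix(tiny, {"water": 1.0}), tiny, PANEL)


class TestTimecourse:
    def _series(self, reference_basis, times, concs):
        out = []
        for t, conc in zip(times, concs):
            mu_a = _mix(reference_basis, conc)
            props = OpticalProperties(
                reference_basis.grid, mu_a.values, np.full(reference_basis.grid.size, 1.0)
            )
            out.append((t, props))
        return out

    def test_singleton_matches_direct_fit(self, reference_basis):
        conc = {"HbO2": 2.0, "water": 0.8}
        series = self._series(reference_basis, [0.5], [conc])
        out = unmix_timecourse(series, reference_basis, PANEL)
        direct = fit_concentrations(_mix(reference_basis, conc), reference_basis, PANEL)
        assert len(out) == 1
        assert out[0][1].concentrations == direct.concentrations

    def test_drift_series_shows_conversion(self, reference_basis):
        times = [0.0, 0.5, 1.0, 2.0, 3.0]
        hbo2, methb = methb_drift(2.5, 0.7, 1.0, np.asarray(times))
        concs = [
            {"HbO2": float(h), "MetHb": float(m), "water": 0.8}
            for h, m in zip(hbo2, methb)
        ]
        out = unmix_timecourse(self._series(reference_basis, times, concs), reference_basis, PANEL)
        fitted_methb = [fit.concentrations["MetHb"] for _, fit in out]
        fitted_hbo2 = [fit.concentrations["HbO2"] for _, fit in out]
        assert np.all(np.diff(fitted_methb) > 0)
        assert np.all(np.diff(fitted_hbo2) < 0)

    def test_output_sorted_regardless_of_input_order(self, reference_basis):
        times = [2.0, 0.5, 1.0]
        concs = [{"water": 0.8}] * 3
        series = self._series(reference_basis, times, concs)
        out = unmix_timecourse(series, reference_basis, PANEL)
        assert [t for t, _ in out] == sorted(times)

    def test_empty_series_rejected(self, reference_basis):
        with pytest.raises(ValueError):
            unmix_timecourse([], reference_basis)


class TestChromophoreUnmixerEstimator:
    def test_transform_matches_function_api(self, reference_basis):
        unmixer = ChromophoreUnmixer(basis=reference_basis, components=PANEL).fit()
        truth = {"HbO2": 1.5, "MetHb": 0.6, "water": 0.7}
        mu_a = _mix(reference_basis, truth)
        row = unmixer.transform(mu_a.values[None, :])[0]
        fit = fit_concentrations(mu_a, reference_basis, PANEL)
        np.testing.assert_allclose(row, [fit.concentrations[n] for n in PANEL], atol=1e-10)

    def test_params_round_trip(self, reference_basis):
        unmixer = ChromophoreUnmixer(basis=reference_basis, mode=MODE_UNCONSTRAINED)
        unmixer.set_params(**unmixer.get_params())
        assert unmixer.mode == MODE_UNCONSTRAINED

    def test_unfitted_raises(self, reference_basis):
        with pytest.raises(RuntimeError):
            ChromophoreUnmixer(basis=reference_basis).transform(np.zeros((1, 3)))
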