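import math

import numpy as np
import pytest

from fluorodimer import (
    AssignmentTable,
    BiasParameters,
    MixingSpec,
    Spectrum,
    assign_species_integrals,
    dimer_species_fractions,
    expected_peak_areas,
    fit_lorentzians,
    get_preset_table,
    lorentzian_profile,
    plot_fit,
    simulate_sample_spectrum,
)
from fluorodimer.deconvolution import FitComponent, FitResult


def make_spectrum(components, axis, noise_sigma=0.0, seed=0, baseline=0.0):
    """Direct synthetic spectrum, bypassing the sample generator."""
    y = np.full_like(axis, baseline)
    for center, fwhm, area in components:
        y += lorentzian_profile(center, fwhm, area, axis)
    if noise_sigma:
        y = y + np.random.default_rng(seed).normal(0, noise_sigma, axis.size)
    return Spectrum(axis, y, {"noise_sigma": noise_sigma})


def make_fit_result(areas_by_species, table, sigma=0.01):
    """Hand-built FitResult with the given species -> area mapping."""
    components, seen = [], set()
    for group in table.sorted_groups():
        sp = tuple(sorted(group))
        area = sum(areas_by_species[s] for s in sp)
        components.append(
            FitComponent(
                label="+".join(sp), species=sp,
                center=table.group_center(group), fwhm=0.15, area=area,
                center_err=0.0, fwhm_err=0.0, area_err=sigma,
            )
        )
        seen |= set(sp)
    assert seen == set(areas_by_species)
    n = len(components)
    return FitResult(
        components=components, baseline=0.0, baseline_err=0.0,
        residual_rms=0.0, reduced_chi_square=1.0, converged=True,
        n_points=1000, area_covariance=np.eye(n) * sigma**2,
    )


class TestFitLorentzians:
    def test_noiseless_single_lorentzian_exact(self):
        axis = np.linspace(-130.0, -118.0, 4096)
        spec = make_spectrum([(-124.0, 0.15, 1.0)], axis)
        table = AssignmentTable.build({"A_1F": (-124.0, 0.3)})
        fit = fit_lorentzians(spec, table)
        assert fit.converged
        comp = fit.component_for("A_1F")
        assert comp.area == pytest.approx(1.0, abs=1e-6)
        assert comp.center == pytest.approx(-124.0, abs=1e-6)
        assert comp.fwhm == pytest.approx(0.15, abs=1e-6)

    def test_two_resolved_peaks_snr50(self):
        axis = np.linspace(-132.0, -116.0, 4096)
        truth = [(-124.8, 0.15, 1.0), (-123.2, 0.15, 1.0)]
        clean = make_spectrum(truth, axis)
        sigma = clean.intensity.max() / 50.0
        spec = make_spectrum(truth, axis, noise_sigma=sigma, seed=7)
        table = AssignmentTable.build(
            {"A_2F": (-124.8, 0.3), "B_2F": (-123.2, 0.3)}
        )
        fit = fit_lorentzians(spec, table)
        # oracle: quadrature of each isolated noiseless peak over its own
        # window, corrected for the Lorentzian tail outside the window
        tail = (2 / math.pi) * math.atan(2 * 0.75 / 0.15)
        for sp, (center, fwhm, area) in zip(("A_2F", "B_2F"), truth):
            isolated = make_spectrum([(center, fwhm, area)], axis)
            oracle = isolated.window_integral(center - 0.75, center + 0.75) / tail
            assert fit.component_for(sp).area == pytest.approx(oracle, rel=0.02)

    def test_three_peak_mixture_recovers_generator_areas(
        self, one_to_three, label_only_bias, table_5fw
    ):
        spec = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=3, snr=100.0
        )
        fit = fit_lorentzians(spec, table_5fw)
        truth = spec.metadata["true_areas"]
        assert fit.component_for("A_2F").area == pytest.approx(truth["A_2F"], rel=0.03)
        assert fit.component_for("A_1F").area == pytest.approx(truth["A_1F"], rel=0.03)
        b_total = truth["B_2F"] + truth["B_1F"]
        assert fit.component_for("B_1F").area == pytest.approx(b_total, rel=0.03)

    def test_noiseless_oracle_equivalence(
        self, one_to_three, label_only_bias, table_5fw
    ):
        # same model class: fitted areas equal generator areas to <= 1e-4
        spec = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=0, noise_sigma=0.0
        )
        fit = fit_lorentzians(spec, table_5fw)
        truth = spec.metadata["true_areas"]
        assert fit.component_for("A_2F").area == pytest.approx(truth["A_2F"], rel=1e-4)
        assert fit.component_for("A_1F").area == pytest.approx(truth["A_1F"], rel=1e-4)
        assert fit.component_for("B_1F").area == pytest.approx(
            truth["B_2F"] + truth["B_1F"], rel=1e-4
        )

    def test_rescaling_invariance(self, one_to_three, label_only_bias, table_5fw):
        spec = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=5, snr=30.0
        )
        scaled = Spectrum(spec.axis, spec.intensity * 1000.0, dict(spec.metadata))
        fit = fit_lorentzians(spec, table_5fw)
        fit_scaled = fit_lorentzians(scaled, table_5fw)
        for c, cs in zip(fit.components, fit_scaled.components):
            assert cs.area == pytest.approx(1000.0 * c.area, rel=1e-6)
        # downstream K is scale-free
        dist = dimer_species_fractions(one_to_three)
        i1 = assign_species_integrals(fit, table_5fw, dist)
        i2 = assign_species_integrals(fit_scaled, table_5fw, dist)
        k1 = (i1.I_B - i1.I_A_homo) / i1.I_A_het
        k2 = (i2.I_B - i2.I_A_homo) / i2.I_A_het
        assert k2 == pytest.approx(k1, rel=1e-6)

    def test_sigma_matches_empirical_spread(self, one_to_three, label_only_bias, table_5fw):
        # covariance sigma within a factor 2 of the spread over 200 noise draws
        clean = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=0, noise_sigma=0.0,
        )
        sigma = clean.intensity.max() / 20.0
        rng = np.random.default_rng(99)
        areas, sigmas = [], []
        for _ in range(200):
            noisy = Spectrum(
                clean.axis,
                clean.intensity + rng.normal(0, sigma, clean.n_points),
                {"noise_sigma": sigma},
            )
            fit = fit_lorentzians(noisy, table_5fw)
            comp = fit.component_for("A_1F")
            areas.append(comp.area)
            sigmas.append(comp.area_err)
        empirical = np.std(areas, ddof=1)
        predicted = np.mean(sigmas)
        assert 0.5 < predicted / empirical < 2.0

    def test_bootstrap_uncertainty_close_to_covariance(
        self, one_to_three, label_only_bias, table_5fw
    ):
        spec = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=11, snr=20.0
        )
        fit_cov = fit_lorentzians(spec, table_5fw)
        fit_boot = fit_lorentzians(
            spec, table_5fw, uncertainty="bootstrap", n_bootstrap=60, seed=1
        )
        e_cov = fit_cov.component_for("A_1F").area_err
        e_boot = fit_boot.component_for("A_1F").area_err
        assert 0.4 < e_boot / e_cov < 2.5

    def test_nonconvergence_is_flagged_not_silent(
        self, one_to_three, label_only_bias, table_5fw
    ):
        spec = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=2, snr=10.0
        )
        fit = fit_lorentzians(spec, table_5fw, max_nfev=1)
        assert not fit.converged
        assert any("converge" in w for w in fit.warnings)
        with pytest.raises(ValueError, match="non-converged"):
            assign_species_integrals(fit, table_5fw)

    def test_pinned_parameter_warns(self):
        axis = np.linspace(-130.0, -118.0, 8192)
        spec = make_spectrum([(-124.0, 0.01, 1.0)], axis)  # below fwhm bound
        table = AssignmentTable.build({"A_1F": (-124.0, 0.3)})
        fit = fit_lorentzians(spec, table, fwhm_init=0.15)
        assert any("pinned" in w for w in fit.warnings)
        assert fit.component_for("A_1F").at_bound

    def test_contaminant_component_excluded_from_species(
        self, one_to_three, label_only_bias, table_5fw
    ):
        spec = simulate_sample_spectrum(
            one_to_three, label_only_bias, table_5fw, seed=0,
            contaminant=(-121.0, 0.1, 0.2),
        )
        fit = fit_lorentzians(spec, table_5fw, contaminant_window=(-121.5, -120.5))
        extra = [c for c in fit.components if c.label == "contaminant"]
        assert len(extra) == 1
        assert extra[0].area == pytest.approx(0.2, rel=0.05)
        assert extra[0].species == ()

    def test_missing_window_coverage_rejected(self, table_5fw):
        axis = np.linspace(-124.0, -120.0, 1024)
        spec = Spectrum(axis, np.zeros(1024))
        with pytest.raises(ValueError, match="does not cover"):
            fit_lorentzians(spec, table_5fw)

    def test_coarse_grid_rejected(self, table_5fw):
        axis = np.linspace(-140.0, -110.0, 256)  # ~0.12 ppm/point
        spec = Spectrum(axis, np.zeros(256))
        with pytest.raises(ValueError, match="grid too coarse"):
            fit_lorentzians(spec, table_5fw)

    def test_plot_writes_file(self, tmp_path, simulated_1to3, table_5fw):
        fit = fit_lorentzians(simulated_1to3, table_5fw)
        out = tmp_path / "fit.png"
        plot_fit(simulated_1to3, fit, out)
        assert out.stat().st_size > 0


class TestAssignSpeciesIntegrals:
    def test_arithmetic_example(self, table_5fw):
        # constructed from f_homo = 1/7, p_A = 1/3 (arithmetic oracle)
        fit = make_fit_result(
            {"A_2F": 0.143, "A_1F": 0.286, "B_2F": 0.5, "B_1F": 0.214},
            table_5fw,
        )
        integrals = assign_species_integrals(fit, table_5fw)
        assert integrals.I_B == pytest.approx(0.714)
        assert integrals.I_B_het == pytest.approx(0.571)
        assert not integrals.resolved_B

    def test_resolved_case_reads_b_het_directly(self, table_e14q):
        fit = make_fit_result(
            {"A_2F": 0.125, "A_1F": 0.2, "B_2F": 0.125, "B_1F": 0.55},
            table_e14q,
        )
        integrals = assign_species_integrals(fit, table_e14q)
        assert integrals.resolved_B
        assert integrals.I_B_het == pytest.approx(0.55)
        assert integrals.I_B == pytest.approx(0.675)

    def test_consistency_between_routes(self, table_5fw, table_e14q):
        # algebraic identity I_B = I_B,homo + I_B,het: both routes agree
        areas = {"A_2F": 0.125, "A_1F": 0.5, "B_2F": 0.125, "B_1F": 0.25}
        merged = assign_species_integrals(
            make_fit_result(areas, table_5fw), table_5fw
        )
        resolved = assign_species_integrals(
            make_fit_result(areas, table_e14q), table_e14q
        )
        assert merged.I_B_het == pytest.approx(resolved.I_B_het, abs=1e-12)

    def test_homodimer_only_flagged(self, table_5fw):
        fit = make_fit_result(
            {"A_2F": 0.5, "A_1F": 0.0, "B_2F": 0.5, "B_1F": 0.0}, table_5fw
        )
        integrals = assign_species_integrals(fit, table_5fw)
        assert not integrals.heterodimer_present
        assert integrals.I_B == pytest.approx(integrals.I_A_homo)

    def test_negative_heterodimer_intensity_rejected(self, table_5fw):
        fit = make_fit_result(
            {"A_2F": 0.5, "A_1F": 0.1, "B_2F": 0.2, "B_1F": 0.0}, table_5fw
        )
        with pytest.raises(ValueError, match="negative heterodimer B intensity"):
            assign_species_integrals(fit, table_5fw)

    def test_consistency_score(self, one_to_three, table_5fw):
        dist = dimer_species_fractions(one_to_three)
        # exact generator areas: perfect consistency
        p = expected_peak_areas(dist.with_populations(0.6))
        fit = make_fit_result(p, table_5fw)
        integrals = assign_species_integrals(fit, table_5fw, dist)
        assert integrals.consistency == pytest.approx(0.0, abs=1e-12)
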