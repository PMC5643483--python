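"""Determinism and fidelity of the synthetic-data generators."""

import numpy as np
import pytest

from exomet.assign import assign_spectrum
from exomet.chem import monoisotopic_mass, parse_formula
from exomet.growth import growth_rate, stimulation
from exomet.metabolites import match_formulas
from exomet.simulate import (
    SimulationError,
    SpectrumSimConfig,
    simulate_batch_growth,
    simulate_diatom_experiment,
    simulate_spectrum,
)
from exomet.spectra import filter_peaks, neutral_mass, subtract_blank


class TestSimulateSpectrum:
    def test_deterministic_under_seed(self, db):
        cfg = SpectrumSimConfig(n_true=10, n_decoys=10, blank_contaminants=3, seed=42)
        out1 = simulate_spectrum(cfg, db)
        out2 = simulate_spectrum(cfg, db)
        assert out1[0].peaks == out2[0].peaks
        assert out1[1].peaks == out2[1].peaks
        assert out1[2].peaks == out2[2].peaks

    def test_empty_config(self, db):
        cfg = SpectrumSimConfig(n_true=0, n_decoys=0, seed=1)
        sample, blank, manifest = simulate_spectrum(cfg, db)
        assert len(sample) == 0 and len(blank) == 0 and manifest.peaks == []

    def test_blank_shares_exactly_the_contaminants(self, db):
        cfg = SpectrumSimConfig(n_true=5, n_decoys=5, blank_contaminants=4, seed=2)
        sample, blank, manifest = simulate_spectrum(cfg, db)
        blank_formulas = manifest.formula_set(kinds=("contaminant",))
        assert len(blank_formulas) == 4
        assert len(blank) == 4
        sample_formulas = {p.formula for p in manifest.peaks}
        assert blank_formulas <= sample_formulas

    def test_noiseless_true_peaks_sit_at_exact_masses(self, db):
        cfg = SpectrumSimConfig(n_true=43, n_decoys=0, ppm_sigma=0.0, seed=3,
                                mode="positive")
        sample, _, manifest = simulate_spectrum(cfg, db)
        for p in manifest.peaks:
            m = monoisotopic_mass(parse_formula(p.formula))
            assert neutral_mass(p.mz, "positive") == pytest.approx(m, abs=1e-9)

    def test_too_many_true_formulas(self, db):
        with pytest.raises(SimulationError):
            simulate_spectrum(SpectrumSimConfig(n_true=100, seed=1), db)

    def test_noiseless_roundtrip_recovers_all_records(self, db):
        """With zero mass error and no decoys the full chain
        (assign → blank-subtract → match) returns every matchable record."""
        cfg = SpectrumSimConfig(n_true=43, n_decoys=0, ppm_sigma=0.0,
                                blank_contaminants=0, seed=4)
        sample, blank, manifest = simulate_spectrum(cfg, db)
        spec = assign_spectrum(filter_peaks(sample))
        detected = subtract_blank(spec.formula_set, assign_spectrum(filter_peaks(blank)).formula_set)
        matched = {m.record.name for m in match_formulas(detected, db)}
        # the two ion-composition misprints in the table (odd H parity)
        # cannot be assigned under the even-electron rule
        unmatchable = {"2,3-dihydroxybenzoate", "Dethiobiotin"}
        assert matched == {rec.name for rec in db} - unmatchable


class TestMonod:
    def test_conservation_and_monotonicity(self):
        curve, substrate, truth = simulate_batch_growth(
            mu_max=0.25, ks=0.05, yield_coeff=0.1, s0=10.0, x0=0.01,
            dt=0.04, t_end=20.0,
        )
        x = truth["x_noise_free"]
        s = substrate.values
        # X + Y*S conserved by the ODE system
        assert x[-1] - x[0] == pytest.approx(0.1 * (10.0 - s[-1]), rel=1e-9)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all(np.diff(x) >= -1e-12)

    def test_small_ks_limit_is_exponential(self):
        curve, substrate, truth = simulate_batch_growth(
            mu_max=0.2, ks=1e-6, yield_coeff=0.1, s0=10.0, x0=0.01,
            dt=0.05, t_end=10.0,
        )
        x = truth["x_noise_free"]
        mask = substrate.values > 5.0  # S >> Ks
        expected = 0.01 * np.exp(0.2 * curve.times[mask])
        assert np.allclose(x[mask], expected, rtol=1e-3)

    def test_growth_rate_recovers_mu_max(self):
        curve, _, truth = simulate_batch_growth(
            mu_max=0.25, ks=0.05, yield_coeff=0.1, s0=10.0, x0=0.01,
            dt=0.04, t_end=20.0,
        )
        fit = growth_rate(curve)
        assert abs(fit.rate - 0.25) / 0.25 < 0.05

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_batch_growth(0.25, 0.05, 0.1, 10.0, 0.01, dt=1.0, t_end=20.0)
        with pytest.raises(ValueError):
            simulate_batch_growth(-0.1, 0.05, 0.1, 10.0, 0.01, dt=0.01, t_end=20.0)

    def test_noise_is_seeded(self):
        kwargs = dict(mu_max=0.2, ks=0.1, yield_coeff=0.1, s0=10.0, x0=0.01,
                      dt=0.05, t_end=10.0, noise_cv=0.05)
        c1, _, _ = simulate_batch_growth(seed=9, **kwargs)
        c2, _, _ = simulate_batch_growth(seed=9, **kwargs)
        c3, _, _ = simulate_batch_growth(seed=10, **kwargs)
        assert np.array_equal(c1.values, c2.values)
        assert not np.array_equal(c1.values, c3.values)


class TestDiatoms:
    def test_null_factor_gives_zero_enhancement(self):
        exp = simulate_diatom_experiment(stimulation_factor=1.0, noise_cv=0.0, seed=1)
        rates_t = [growth_rate(c).rate for c in exp.treated]
        rates_c = [growth_rate(c).rate for c in exp.control]
        result = stimulation(rates_t, rates_c)
        assert result.percent_enhancement == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_22_percent_exact(self):
        exp = simulate_diatom_experiment(stimulation_factor=1.22, noise_cv=0.0, seed=1)
        rates_t = [growth_rate(c).rate for c in exp.treated]
        rates_c = [growth_rate(c).rate for c in exp.control]
        result = stimulation(rates_t, rates_c)
        assert result.percent_enhancement == pytest.approx(22.0, abs=1e-6)

    def test_manifest_records_true_rates(self):
        exp = simulate_diatom_experiment(stimulation_factor=1.35, noise_cv=0.02, seed=7)
        assert len(exp.manifest["true_rates_treated"]) == 3
        ratio = np.mean(exp.manifest["true_rates_treated"]) / np.mean(
            exp.manifest["true_rates_control"]
        )
        assert abs(ratio - 1.35) < 0.1

    def test_replicate_validation(self):
        with pytest.raises(ValueError):
            simulate_diatom_experiment(n_replicates=1)
        with pytest.raises(ValueError):
            simulate_diatom_experiment(stimulation_factor=0.0)
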