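"""Spectra, attenuation tables, the empirical decomposition model, scanner
calibration, and HU conversion."""

import numpy as np
import pytest

from meercbct import spectral as sp


class TestSpectrum:
    def test_no_fluence_above_kvp(self):
        s = sp.generate_spectrum(80.0)
        assert s.energies_kev.max() <= 80.0
        assert not (s.weights[s.energies_kev > 80.0] > 0).any()

    def test_weights_normalized_and_nonnegative(self):
        s = sp.generate_spectrum(100.0)
        assert s.weights.min() >= 0
        assert s.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_energy_increases_with_kvp(self):
        e = [sp.generate_spectrum(k).mean_energy for k in (80.0, 100.0, 120.0)]
        assert e[0] < e[1] < e[2]

    def test_filtration_hardens_beam(self):
        soft = sp.generate_spectrum(100.0, filtration_mm_al=1.0)
        hard = sp.generate_spectrum(100.0, filtration_mm_al=8.0)
        assert hard.mean_energy > soft.mean_energy

    def test_kvp_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="kvp"):
            sp.generate_spectrum(30.0)


class TestAttenuationTables:
    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError, match="Pu"):
            sp.mass_attenuation("Pu", np.array([60.0]))

    def test_iodine_k_edge_jump(self):
        below = sp.mass_attenuation("I", 33.0)
        above = sp.mass_attenuation("I", 33.5)
        assert above > 3.0 * below

    def test_iodine_decreasing_above_k_edge(self):
        e = np.linspace(34.0, 150.0, 40)
        v = sp.mass_attenuation("I", e)
        assert (np.diff(v) < 0).all()

    def test_water_attenuation_matches_reference(self):
        # 0.112 mu_H + 0.888 mu_O should land near the known water value
        # of ~0.2059 cm^2/g at 60 keV
        mu = 0.111894 * sp.mass_attenuation("H", 60.0) + 0.888106 * sp.mass_attenuation(
            "O", 60.0
        )
        assert mu == pytest.approx(0.2059, rel=0.01)


class TestEffectiveAttenuation:
    def test_monoenergetic_returns_tabulated_value(self):
        s = sp.Spectrum(kvp=80.0, energies_kev=np.array([60.0]), weights=np.array([1.0]))
        mu = sp.effective_channel_attenuation(sp.WATER, s)
        expect = (
            0.111894 * sp.mass_attenuation("H", 60.0)
            + 0.888106 * sp.mass_attenuation("O", 60.0)
        )
        assert mu == pytest.approx(expect, rel=1e-12)

    def test_water_in_physical_range_at_80kvp(self, spectra):
        mu = sp.effective_channel_attenuation(sp.WATER, spectra[0])
        assert 0.15 < mu < 0.30  # cm^-1

    def test_linearity_in_density(self, spectra):
        m1 = sp.Material("half_water", dict(sp.WATER_COMPOSITION), 0.5)
        m2 = sp.Material("water", dict(sp.WATER_COMPOSITION), 1.0)
        a = sp.effective_channel_attenuation(m1, spectra[0])
        b = sp.effective_channel_attenuation(m2, spectra[0])
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_unknown_element_in_composition_rejected(self):
        with pytest.raises(KeyError):
            sp.Material("mystery", {"Xx": 1.0}, 1.0)


class TestHounsfield:
    @pytest.mark.parametrize(
        "mu_factor,expected_hu", [(1.0, 0.0), (0.0, -1000.0), (1.1, 100.0)]
    )
    def test_linear_map(self, mu_factor, expected_hu):
        ref = 0.02
        assert sp.mu_to_hu(mu_factor * ref, ref) == pytest.approx(expected_hu, abs=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sp.mu_to_hu(np.ones(3), 0.0)


def scalar_form_oracle(rho, lam, params, z):
    """Per-voxel evaluation through the effective-Z form (independent route)."""
    out = np.empty((len(rho), params.n_channels))
    for j in range(len(rho)):
        z_tilde = float(lam[j] @ z**sp.PE_EXPONENT) ** (1 / sp.PE_EXPONENT)
        z_hat = float(lam[j] @ z**sp.RAYLEIGH_EXPONENT) ** (1 / sp.RAYLEIGH_EXPONENT)
        for i in range(params.n_channels):
            out[j, i] = rho[j] * (
                params.k_pe[i] * z_tilde**sp.PE_EXPONENT
                + params.k_rayleigh[i] * z_hat**sp.RAYLEIGH_EXPONENT
                + params.k_compton[i]
            )
    return out


class TestDecompositionModel:
    def _random_inputs(self, rng, m=30):
        rho = rng.uniform(0.2, 2.0, size=m)
        lam = rng.dirichlet([3.0, 5.0, 0.5], size=m)
        return rho, lam

    def test_scalar_and_matrix_forms_agree(self, rng, calibration):
        rho, lam = self._random_inputs(rng)
        mat = sp.attenuation_from_composition(rho, lam, calibration.params)
        sca = scalar_form_oracle(rho, lam, calibration.params, sp.HOI_Z)
        assert np.allclose(mat, sca, rtol=1e-12, atol=1e-15)

    def test_compton_only_collapses_to_rho(self):
        params = sp.AttenuationModelParams(
            k_pe=[0.0, 0.0], k_rayleigh=[0.0, 0.0], k_compton=[0.017, 0.02]
        )
        rho = np.array([0.5, 1.0, 1.5])
        lam = np.tile([0.1, 0.9, 0.0], (3, 1))
        f = sp.attenuation_from_composition(rho, lam, params)
        assert np.allclose(f, rho[:, None] * np.array([0.017, 0.02]))

    def test_pure_iodine_voxel(self):
        params = sp.AttenuationModelParams(
            k_pe=[2e-7], k_rayleigh=[1e-4], k_compton=[0.015]
        )
        f = sp.attenuation_from_composition(
            np.array([1.0]), np.array([[0.0, 0.0, 1.0]]), params
        )
        expect = (
            2e-7 * 53.0**sp.PE_EXPONENT + 1e-4 * 53.0**sp.RAYLEIGH_EXPONENT + 0.015
        )
        assert f[0, 0] == pytest.approx(expect, rel=1e-12)

    def test_bad_row_sums_rejected(self, calibration):
        with pytest.raises(ValueError, match="sum"):
            sp.attenuation_from_composition(
                np.array([1.0]), np.array([[0.5, 0.3, 0.1]]), calibration.params
            )


class TestCalibration:
    def test_exact_recovery_on_model_data(self, rng):
        true = sp.AttenuationModelParams(
            k_pe=[4e-7, 3e-7], k_rayleigh=[3e-4, 2e-4], k_compton=[0.014, 0.015]
        )
        rho = rng.uniform(0.5, 1.5, size=4)
        lam = rng.dirichlet([3.0, 5.0, 0.5], size=4)
        f = sp.attenuation_from_composition(rho, lam, true)
        mats = [(rho[j], lam[j], f[j]) for j in range(4)]
        est = sp.calibrate_model(mats)
        assert np.allclose(est.k_pe, true.k_pe, rtol=1e-10)
        assert np.allclose(est.k_rayleigh, true.k_rayleigh, rtol=1e-10)
        assert np.allclose(est.k_compton, true.k_compton, rtol=1e-10)

    def test_two_materials_underdetermined(self):
        mats = [
            (1.0, np.array([0.1, 0.9, 0.0]), np.array([0.02])),
            (1.1, np.array([0.2, 0.8, 0.0]), np.array([0.021])),
        ]
        with pytest.raises(ValueError, match="3 materials"):
            sp.calibrate_model(mats)

    def test_degenerate_design_detected(self):
        # water and iodine dilutions alone span a rank-2 regressor space
        mats = []
        for c in (0.0, 0.01, 0.03, 0.05):
            m = sp.iodine_solution(c)
            mats.append((m.relative_electron_density, m.hoi_fractions, np.array([0.02])))
        with pytest.raises(ValueError, match="rank-deficient"):
            sp.calibrate_model(mats)

    def test_noisy_fit_matches_normal_equations_oracle(self, rng):
        true = sp.AttenuationModelParams(
            k_pe=[4e-7], k_rayleigh=[3e-4], k_compton=[0.014]
        )
        rho = rng.uniform(0.5, 1.5, size=8)
        lam = rng.dirichlet([3.0, 5.0, 0.5], size=8)
        f = sp.attenuation_from_composition(rho, lam, true)
        f_noisy = f + 1e-4 * rng.normal(size=f.shape)
        est = sp.calibrate_model([(rho[j], lam[j], f_noisy[j]) for j in range(8)])
        # dense normal-equations oracle
        design = np.stack(
            [
                rho * (lam @ sp.HOI_Z**sp.PE_EXPONENT),
                rho * (lam @ sp.HOI_Z**sp.RAYLEIGH_EXPONENT),
                rho,
            ],
            axis=1,
        )
        coef = np.linalg.solve(design.T @ design, design.T @ f_noisy[:, 0])
        got = np.array([est.k_pe[0], est.k_rayleigh[0], est.k_compton[0]])
        assert np.allclose(got, coef, rtol=1e-8)
        resid = np.linalg.norm(design @ coef - f_noisy[:, 0])
        assert resid >= 0.0

    def test_calibration_inverts_forward_model_for_solutions(self, calibration, spectra):
        # the calibrated model must reproduce the linearized in-phantom
        # attenuation (the quantity the scanner calibration is referenced
        # to) of any water-iodine solution to a small fraction of a percent
        eff = [sp.harden_spectrum(s, sp.DEFAULT_CALIBRATION_WATER_PATH_CM) for s in spectra]
        mu_w0 = np.array([sp.effective_channel_attenuation(sp.WATER, s) for s in spectra])
        mu_wL = np.array([sp.effective_channel_attenuation(sp.WATER, s) for s in eff])
        for c in (0.0, 0.002, 0.02, 0.08):
            m = sp.iodine_solution(c)
            f_true = mu_w0 * np.array(
                [sp.effective_channel_attenuation(m, s) for s in eff]
            ) / mu_wL
            f_model = sp.attenuation_from_composition(
                np.array([m.relative_electron_density]),
                m.hoi_fractions[None, :],
                calibration.params,
            )[0]
            assert np.allclose(f_model, f_true, rtol=2e-3)


class TestIodineSolution:
    def test_dilution_iodine_density(self):
        m = sp.iodine_solution(0.025)
        assert 1000 * m.density * m.composition["I"] == pytest.approx(4.375, rel=1e-12)

    def test_zero_concentration_is_water(self):
        m = sp.iodine_solution(0.0)
        assert m.composition == pytest.approx(sp.WATER_COMPOSITION)
        assert m.relative_electron_density == pytest.approx(1.0, abs=1e-12)

    def test_enhancement_near_170_hu_anchor(self, spectra, calibration):
        # 2.5% dilution of the 175 mgI/ml stock: channel-averaged thin-limit
        # enhancement should sit in the 120-220 HU window
        m = sp.iodine_solution(0.025)
        hu = []
        for s, muw in zip(spectra, calibration.mu_water):
            f = sp.effective_channel_attenuation(m, s)
            hu.append(1000.0 * (f - muw) / muw)
        assert 120.0 < np.mean(hu) < 220.0
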