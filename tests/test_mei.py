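"""MEI synthesis and characterisation."""

import numpy as np
import pytest

from rgctwin.mei import (
    MEIError,
    MEIOptions,
    MEIRecord,
    centre_gaussian,
    centre_mask,
    centre_size,
    decompose,
    dog_model,
    fit_dog,
    mei_contrast,
    opponency_flag,
    synthesize_mei,
    temporal_frequency,
)


class TestSynthesis:
    def test_linear_neuron_mei_aligns_with_filter(self, linear_model_results):
        # closed form: the maximiser of a linear functional on an L2 ball is
        # the scaled filter (range box non-binding at b=10)
        res = linear_model_results
        _, F = res.activation_and_gradient(
            np.zeros((2, 50, 18, 16)), 0, centered=True
        )
        rec = synthesize_mei(res, 0, MEIOptions(norm_budget=10.0, seed=1))
        cos = float(
            (rec.tensor * F).sum()
            / (np.linalg.norm(rec.tensor) * np.linalg.norm(F))
        )
        assert cos >= 0.99

    def test_norm_equals_budget_when_range_nonbinding(self,
                                                      linear_model_results):
        rec = synthesize_mei(linear_model_results, 0,
                             MEIOptions(norm_budget=10.0, seed=1))
        assert rec.norm == pytest.approx(10.0, abs=1e-6)

    def test_constraints_hold_on_every_mei(self, linear_model_results):
        rec = synthesize_mei(linear_model_results, 0, MEIOptions(seed=3))
        assert rec.norm <= rec.norm_budget + 1e-6
        for c in range(2):
            assert rec.tensor[c].min() >= rec.range_box[c, 0] - 1e-9
            assert rec.tensor[c].max() <= rec.range_box[c, 1] + 1e-9

    def test_final_activation_monotone_in_budget(self, linear_model_results):
        finals = [
            synthesize_mei(linear_model_results, 0,
                           MEIOptions(norm_budget=b, seed=1)).activations[-1]
            for b in (10.0, 20.0, 30.0)
        ]
        assert finals[0] <= finals[1] <= finals[2]

    def test_two_seeds_agree_for_single_optimum(self, linear_model_results):
        r1 = synthesize_mei(linear_model_results, 0,
                            MEIOptions(norm_budget=10.0, seed=1))
        r2 = synthesize_mei(linear_model_results, 0,
                            MEIOptions(norm_budget=10.0, seed=2))
        rel = np.linalg.norm(r1.tensor - r2.tensor) / np.linalg.norm(r1.tensor)
        assert rel < 0.01


class TestDecomposition:
    def _record(self, tensor):
        return MEIRecord(
            tensor=tensor, activations=np.zeros(1), converged=True, n_iter=1,
            norm_budget=30.0, window=(30, 50), seed=0,
            range_box=np.array([[-5, 5], [-5, 5]]),
        )

    def test_rank1_input_recovered_exactly(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(50)
        v = rng.standard_normal(288)
        tensor = np.stack([np.outer(u, v).reshape(50, 18, 16)] * 2)
        dec = decompose(self._record(tensor))
        recon = dec.singular_values[0] * np.einsum(
            "t,ij->tij", dec.temporal[0], dec.spatial[0]
        )
        np.testing.assert_allclose(recon, tensor[0], atol=1e-10)
        assert dec.rank1_residual[0] < 1e-10

    def test_rank2_energy_capture_follows_eckart_young(self):
        rng = np.random.default_rng(1)
        u1, u2 = rng.standard_normal((2, 50))
        v1, v2 = rng.standard_normal((2, 288))
        u1, u2 = u1 / np.linalg.norm(u1), u2 / np.linalg.norm(u2)
        # orthogonalise so singular values are exactly (10, 1)
        u2 -= (u1 @ u2) * u1
        u2 /= np.linalg.norm(u2)
        v1 /= np.linalg.norm(v1)
        v2 -= (v1 @ v2) * v1
        v2 /= np.linalg.norm(v2)
        M = 10.0 * np.outer(u1, v1) + 1.0 * np.outer(u2, v2)
        tensor = np.stack([M.reshape(50, 18, 16)] * 2)
        dec = decompose(self._record(tensor))
        captured = dec.singular_values[0] ** 2 / (M**2).sum()
        assert captured >= 100.0 / 101.0 - 1e-12

    def test_components_unit_norm(self):
        rng = np.random.default_rng(2)
        dec = decompose(self._record(rng.standard_normal((2, 50, 18, 16))))
        for c in range(2):
            assert np.linalg.norm(dec.spatial[c]) == pytest.approx(1.0)
            assert np.linalg.norm(dec.temporal[c]) == pytest.approx(1.0)

    def test_zero_channel_flagged(self):
        tensor = np.zeros((2, 50, 18, 16))
        tensor[1] = np.random.default_rng(3).standard_normal((50, 18, 16))
        dec = decompose(self._record(tensor))
        assert any("green" in f for f in dec.flags)


class TestDoG:
    TRUTH = np.array([0.5, -0.3, 1.0, 0.3, 2.0, 3.0, 5.0, 6.0, 0.4, 0.4])

    def test_parameter_recovery_within_five_percent(self):
        fit = fit_dog(dog_model(self.TRUTH))
        est = np.array(
            [fit.mu[0], fit.mu[1], fit.amplitude_center,
             fit.amplitude_surround, *fit.sigma_center, *fit.sigma_surround,
             fit.theta_center, fit.theta_surround]
        )
        rel = np.abs(est - self.TRUTH) / np.abs(self.TRUTH)
        assert rel.max() < 0.05
        assert fit.cost < 1e-4

    def test_pure_gaussian_has_negligible_surround(self):
        g = dog_model(np.array([0, 0, 1.0, 0.0, 2.0, 2.0, 4.0, 4.0, 0, 0]))
        fit = fit_dog(g)
        assert abs(fit.amplitude_surround) < 0.05 * abs(fit.amplitude_center)

    def test_constant_input_gives_flagged_failure(self):
        fit = fit_dog(np.zeros((18, 16)))
        assert not fit.success
        assert np.isinf(fit.cost)


class TestCentreGeometry:
    def test_centre_size_is_sum_of_sigmas_scaled(self):
        fit = fit_dog(dog_model(np.array([0, 0, 1, 0.2, 1.0, 1.0,
                                          3, 3, 0, 0])))
        # sigma_x = sigma_y = 1 px at 50 um/px -> mean diameter 100 um
        assert centre_size(fit, px_to_um=50.0) == pytest.approx(100.0,
                                                                rel=0.02)

    def test_anisotropic_size_is_mean_of_diameters(self):
        from rgctwin.mei import DoGParams

        dog = DoGParams(mu=(0, 0), amplitude_center=1, amplitude_surround=0,
                        sigma_center=(0.8, 1.2), sigma_surround=(2, 2),
                        theta_center=0, theta_surround=0, cost=0)
        assert centre_size(dog, px_to_um=50.0) == pytest.approx(100.0)

    def test_mask_matches_rasterisation_oracle(self):
        from rgctwin.mei import DoGParams

        dog = DoGParams(mu=(0.5, -0.5), amplitude_center=1.0,
                        amplitude_surround=0.0, sigma_center=(2.0, 2.0),
                        sigma_surround=(4, 4), theta_center=0.0,
                        theta_surround=0.0, cost=0)
        mask = centre_mask(dog)
        # oracle: pixels where the centre Gaussian is above its value at the
        # 1-SD diagonal point (level exp(-1) for an isotropic Gaussian)
        G = centre_gaussian(dog)
        oracle = G >= np.exp(-1.0) * dog.amplitude_center
        np.testing.assert_array_equal(mask, oracle)

    def test_mask_contains_pixel_nearest_mu(self):
        from rgctwin.mei import DoGParams

        dog = DoGParams(mu=(3.2, -2.1), amplitude_center=0.5,
                        amplitude_surround=0.1, sigma_center=(1.0, 1.5),
                        sigma_surround=(3, 3), theta_center=0.3,
                        theta_surround=0.3, cost=0)
        mask = centre_mask(dog)
        i = int(round(dog.mu[1] + 8.5))
        j = int(round(dog.mu[0] + 7.5))
        assert mask[i, j]

    def test_mask_invariant_under_theta_plus_pi(self):
        from dataclasses import replace

        from rgctwin.mei import DoGParams

        dog = DoGParams(mu=(0, 0), amplitude_center=1.0,
                        amplitude_surround=0.2, sigma_center=(1.5, 2.5),
                        sigma_surround=(4, 5), theta_center=0.7,
                        theta_surround=0.7, cost=0)
        rotated = replace(dog, theta_center=dog.theta_center + np.pi)
        np.testing.assert_array_equal(centre_mask(dog), centre_mask(rotated))


class TestTemporalFrequency:
    def test_pure_sinusoid_frequency_recovered(self):
        t = np.arange(50) / 30.0
        assert temporal_frequency(np.sin(2 * np.pi * 2.0 * t)) == pytest.approx(
            2.0, abs=0.3
        )

    def test_dc_input_gives_zero(self):
        assert temporal_frequency(np.ones(50)) == pytest.approx(0.0, abs=1e-6)

    def test_zero_vector_flagged_zero(self):
        with pytest.warns(UserWarning):
            assert temporal_frequency(np.zeros(50)) == 0.0


class TestContrast:
    def test_hand_built_opponent_tensor(self):
        # UV ramps +0.4 between its final extrema, green ramps -0.3
        T, H, W = 50, 18, 16
        tensor = np.zeros((2, T, H, W))
        t = np.arange(T) / 30.0
        uv_course = 0.2 * np.sin(2 * np.pi * 1.2 * t)  # final trough->peak
        green_course = -0.75 * uv_course
        spatial = np.zeros((H, W))
        spatial[7:11, 6:10] = 1.0
        tensor[1] = uv_course[:, None, None] * spatial
        tensor[0] = green_course[:, None, None] * spatial
        dec = decompose(tensor)
        mask = spatial.astype(bool)
        gamma, opponent, (t1, t2) = mei_contrast(tensor, dec, mask)
        assert t1 < t2
        assert gamma["uv"] * gamma["green"] < 0
        assert abs(gamma["green"] / gamma["uv"]) == pytest.approx(0.75,
                                                                  rel=1e-6)
        assert opponent

    def test_flat_uv_component_flagged(self):
        tensor = np.zeros((2, 50, 18, 16))
        tensor[1, :, 9, 8] = 1.0  # constant in time: no extrema pair
        dec = decompose(tensor)
        with pytest.raises(MEIError):
            mei_contrast(tensor, dec, np.ones((18, 16), dtype=bool))

    def test_opponency_flag_rejects_near_zero_channel(self):
        assert opponency_flag({"green": -1.0, "uv": 2.0})
        assert not opponency_flag({"green": -0.01, "uv": 2.0})
        assert not opponency_flag({"green": 1.0, "uv": 2.0})
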