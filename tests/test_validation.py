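"""Rank-1 MEI stimuli, setup calibration, grid experiment, selectivity."""

import numpy as np
import pytest

from rgctwin.mei import decompose
from rgctwin.validation import (
    GridExperiment,
    SetupCalibration,
    reconstruct_rank1,
    selectivity_index,
    setup_transform,
    weighted_response,
)


class TestRank1Reconstruction:
    def test_rank1_input_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(50)
        v = rng.standard_normal(288)
        tensor = np.stack([np.outer(u, v).reshape(50, 18, 16)] * 2)
        recon = reconstruct_rank1(decompose(tensor))
        np.testing.assert_allclose(recon, tensor, atol=1e-9)

    def test_residual_orthogonal_to_components(self):
        # SVD orthogonality oracle: the rank-1 part is the best rank-1
        # approximation, so the residual is orthogonal to both components
        rng = np.random.default_rng(1)
        tensor = rng.standard_normal((2, 50, 18, 16))
        dec = decompose(tensor)
        recon = reconstruct_rank1(dec)
        for c in range(2):
            resid = (tensor[c] - recon[c]).reshape(50, -1)
            assert abs(dec.temporal[c] @ resid @ dec.spatial[c].ravel()) < 1e-9
            # and the rank-1 error is not improvable along the components
            assert np.linalg.norm(resid) <= np.linalg.norm(
                tensor[c].reshape(50, -1)
            )

    def test_display_mapping_stays_in_stimulator_range(self):
        rng = np.random.default_rng(2)
        tensor = 3.0 * rng.standard_normal((2, 50, 18, 16))
        out = reconstruct_rank1(
            decompose(tensor),
            movie_mean=np.array([0.13, 0.13]),
            movie_sd=np.array([0.05, 0.05]),
        )
        assert out.min() >= 0.0 and out.max() <= 255.0


class TestSetupTransform:
    def test_identical_setups_are_identity(self):
        cal = SetupCalibration(A=np.eye(2), B=np.eye(2))
        x = np.random.default_rng(0).standard_normal((2, 7))
        np.testing.assert_allclose(setup_transform(x, cal), x)

    def test_printed_matrices_hand_computed(self):
        # oracle: explicit 2x2 inversion, det B = 1 - 0.9*0.035
        out = setup_transform(np.array([1.0, 0.0]))
        det = 1 - 0.9 * 0.035
        expected = np.array([(1 - 0.9 * 0.035 * 0 - 0.9 * 0.0) / det * 1.0
                             - 0.0, 0.0])
        # x' = B^-1 A x with A x = (1, 0): B^-1 = [[1, -0.9], [-0.035, 1]]/det
        expected = np.array([1.0 / det, -0.035 / det])
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, [1.0325, -0.0361], atol=1e-3)

    def test_cone_activation_equivalence(self):
        cal = SetupCalibration()
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal(2)
            xp = setup_transform(x, cal)
            np.testing.assert_allclose(cal.A @ x, cal.B @ xp, atol=1e-12)

    def test_range_restoration_bounds(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 100))
        out = setup_transform(x, restore_range=(0.0, 255.0))
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(255.0)

    def test_singular_b_rejected(self):
        with pytest.raises(ValueError):
            SetupCalibration(B=np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestGridExperiment:
    def test_total_duration_matches_protocol(self):
        exp = GridExperiment()
        assert exp.total_duration_s(11) == pytest.approx(11 * 25 * 2.0)

    def test_presentation_order_is_seeded_permutation(self):
        exp = GridExperiment(order_seed=5)
        order = exp.presentation_order(11)
        assert order.shape == (11 * 25, 3)
        again = GridExperiment(order_seed=5).presentation_order(11)
        np.testing.assert_array_equal(order, again)
        assert not np.array_equal(
            order, GridExperiment(order_seed=6).presentation_order(11)
        )

    def test_grey_padding_after_stimulus(self):
        exp = GridExperiment()
        assert exp.frames_per_presentation == 60
        assert exp.frames_per_presentation / exp.frame_rate == pytest.approx(2.0)


class TestWeightedResponse:
    def test_collapsed_gaussian_selects_single_node(self):
        rng = np.random.default_rng(0)
        responses = rng.standard_normal((3, 5, 5, 60))
        offs = np.linspace(-1.0, 1.0, 5)
        out = weighted_response(responses, mu=(offs[3], offs[1]),
                                sigma=1e-3, grid_offsets=offs)
        expected = responses[:, 1, 3, 30:50].mean(axis=1)
        dens_peak = 1.0 / (2 * np.pi * 1e-6)
        np.testing.assert_allclose(out / dens_peak, expected, rtol=1e-3)

    def test_uniform_responses_scale_with_summed_density(self):
        responses = np.ones((2, 5, 5, 60)) * 4.0
        offs = np.linspace(-1.0, 1.0, 5)
        out = weighted_response(responses, mu=(0, 0), sigma=0.7,
                                grid_offsets=offs)
        gx = offs[None, :]
        gy = offs[:, None]
        dens = np.exp(-(gx**2 + gy**2) / (2 * 0.7**2)) / (2 * np.pi * 0.7**2)
        np.testing.assert_allclose(out, 4.0 * dens.sum())

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            weighted_response(np.ones((1, 5, 5, 60)), (0, 0), 0.0,
                              np.linspace(-1, 1, 5))


class TestSelectivityIndex:
    def test_own_equal_to_others_gives_zero(self):
        r = np.array([1.0] + [1.0] * 10)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert selectivity_index(r, 0) == 0.0

    def test_eleven_term_hand_calculation(self):
        r = np.zeros(11)
        r[0] = 2.0
        # standardised: mean 2/11, sd sqrt(mean(r^2)-mean^2)
        mean = 2.0 / 11
        sd = np.sqrt((4.0 / 11) - mean**2)
        z_own = (2.0 - mean) / sd
        z_other = (0.0 - mean) / sd
        expected = z_own - z_other
        assert selectivity_index(r, 0) == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        r = rng.standard_normal(11)
        si = selectivity_index(r, 4)
        assert selectivity_index(3.7 * r - 12.0, 4) == pytest.approx(si)

    def test_in_silico_selectivity_for_distinct_rfs(self, small_movie):
        # a cell whose RF sits on the grid centre ranks its own stimulus first
        from rgctwin.population import SimulatedCell, biphasic_kernel, gaussian_rf
        from rgctwin.validation import simulate_grid_responses

        k = biphasic_kernel()
        cells = []
        for loc in [(8.5, 7.5), (6.0, 5.0)]:
            g = gaussian_rf(loc, 2.0)
            cells.append(
                SimulatedCell(
                    cell_id=0, family="ON", spatial_filter=np.stack([g, g]),
                    temporal_filter=np.stack([k, k]),
                    chromatic_weights=(1.0, 1.0), rf_location=loc,
                )
            )
        # stimulus s: a flash confined to cell s's RF area
        T = 50
        stims = np.zeros((2, 2, T, 18, 16))
        course = np.zeros(T)
        course[30:] = 3.0
        for s, cell in enumerate(cells):
            stims[s] = course[None, :, None, None] * cell.spatial_filter[:,
                                                                         None]
        exp = GridExperiment(order_seed=0)
        resp = simulate_grid_responses(cells, stims, exp, px_to_um=50.0)
        offs = exp.grid_offsets_px(50.0)
        for ci, cell in enumerate(cells):
            mu = (cell.rf_location[1] - 7.5, cell.rf_location[0] - 8.5)
            rtilde = weighted_response(resp[ci], mu, 1.0, offs)
            assert int(np.argmax(rtilde)) == ci


class TestInSilicoConfusion:
    def test_opponent_cell_prefers_opponent_stimulus_and_dips_below_rest(
        self,
    ):
        # the opponent cell responds maximally to a UV-ON/green-OFF flash
        # and below its resting rate to an OFF-family (both-dark) flash
        from rgctwin import PopulationConfig, generate_population

        cell = generate_population(
            PopulationConfig(counts={"opponent-SbC": 1}), seed=2
        )[0]
        T = 50
        course = np.zeros(T)
        course[30:] = 3.0
        blob = (cell.spatial_filter[:, None, :, :]
                * course[None, :, None, None])
        opponent_stim = np.stack([-blob[0], blob[1]])
        off_stim = np.stack([-blob[0], -blob[1]])
        on_stim = np.stack([blob[0], blob[1]])
        r_opp = cell.rates(opponent_stim)[30:].max()
        r_off = cell.rates(off_stim)[30:].min()
        r_on = cell.rates(on_stim)[30:].max()
        assert r_opp > r_on
        assert r_off < cell.resting_rate
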