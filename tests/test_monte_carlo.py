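"""Synthetic transformations, noise mixing, calibration and bracketing."""

import numpy as np
import pandas as pd
import pytest

from patrans import (
    PatternMatrix,
    compute_gof,
    rdsv,
    select_lambda,
    znormalise,
)
from patrans.monte_carlo import (
    BracketEstimate,
    CalibrationGrid,
    SimulationConfig,
    bracket_estimate,
    calibrate,
    mix_noise,
    simulate_decay_transform,
    simulate_pattern_pair,
    simulate_sparse_transform,
)


class TestSimulateSparseTransform:
    def test_exact_zero_count_at_90_percent(self, rng):
        T = simulate_sparse_transform(100, 100, 90.0, rng)
        assert np.count_nonzero(T == 0) == 9000

    def test_zero_sparsity_has_no_zeros(self, rng):
        T = simulate_sparse_transform(50, 40, 0.0, rng)
        assert np.count_nonzero(T == 0) == 0

    def test_nonzero_entries_standard_normal(self, rng):
        T = simulate_sparse_transform(500, 400, 50.0, rng)
        nz = T[T != 0]
        n = nz.size
        assert abs(nz.mean()) < 3.0 / np.sqrt(n)
        assert abs(nz.var() - 1.0) < 3.0 * np.sqrt(2.0 / n)

    def test_invalid_percent_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_sparse_transform(5, 5, 100.0, rng)


class TestSimulateDecayTransform:
    def test_spectrum_matches_construction(self, rng):
        T = simulate_decay_transform(10, 10, -1.0, rng)
        sv = np.linalg.svd(T, compute_uv=False)
        np.testing.assert_allclose(
            sv, np.exp(-np.arange(1, 11)), atol=1e-8
        )

    def test_b_zero_gives_equal_singular_values(self, rng):
        T = simulate_decay_transform(8, 12, 0.0, rng)
        sv = np.linalg.svd(T, compute_uv=False)
        np.testing.assert_allclose(sv, sv[0], rtol=1e-10)

    def test_rdsv_closed_loop_recovery(self, rng):
        for b in (0.0, -0.1, -1.0):
            T = simulate_decay_transform(20, 20, b, rng)
            assert rdsv(T) == pytest.approx(b, abs=1e-6)

    def test_positive_b_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_decay_transform(5, 5, 0.5, rng)


class TestMixNoise:
    def test_gamma_zero_proportional_to_signal(self, rng):
        X = znormalise(PatternMatrix(rng.standard_normal((6, 8))))
        T = rng.standard_normal((5, 6))
        Y = mix_noise(T, X, 0.0, rng)
        expected = znormalise(PatternMatrix(T @ X.values))
        np.testing.assert_allclose(Y.values, expected.values, atol=1e-10)

    def test_output_is_normalised_pattern_matrix(self, rng):
        X = znormalise(PatternMatrix(rng.standard_normal((7, 9))))
        Y = mix_noise(rng.standard_normal((4, 7)), X, 0.5, rng)
        assert Y.normalised
        assert Y.stimulus_ids == X.stimulus_ids
        np.testing.assert_allclose(np.sum(Y.values**2, axis=0), 4.0, rtol=1e-10)

    def test_premix_frobenius_bounded_by_one(self, rng):
        # triangle inequality on the two unit-norm terms
        X = znormalise(PatternMatrix(rng.standard_normal((6, 10))))
        T = rng.standard_normal((5, 6))
        for gamma in (0.0, 0.3, 0.8):
            S = T @ X.values
            E = rng.standard_normal(S.shape)
            pre = (1 - gamma) * S / np.linalg.norm(S)
            pre = pre + gamma * E / np.linalg.norm(E)
            assert np.linalg.norm(pre) <= 1.0 + 1e-12

    def test_gof_drops_with_noise(self):
        drops = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = znormalise(PatternMatrix(r.standard_normal((15, 40))))
            T = r.standard_normal((12, 15))
            gofs = {}
            for gamma in (0.0, 0.9):
                Y = mix_noise(T, X, gamma, r)
                lam = select_lambda(X, Y, np.logspace(-2, 4, 20)).lam
                gofs[gamma] = compute_gof(X, Y, lam).gof_percent
            drops += gofs[0.9] < gofs[0.0]
        assert drops >= 4  # monotone trend over seeds

    def test_zero_signal_rejected(self, rng):
        X = znormalise(PatternMatrix(rng.standard_normal((4, 6))))
        with pytest.raises(ValueError, match="zero"):
            mix_noise(np.zeros((3, 4)), X, 0.2, rng)


@pytest.fixture(scope="module")
def small_setup():
    r = np.random.default_rng(9)
    X, Y, _ = simulate_pattern_pair(24, 24, 20, r, sparsity_percent=70,
                                    gamma=0.2)
    lam = select_lambda(X, Y, np.logspace(-2, 4, 20)).lam
    return X, lam


class TestCalibrate:
    def test_smoke_grid_complete(self, small_setup):
        X, lam = small_setup
        cfg = SimulationConfig(n_sims=2, seed=1, gamma_levels=(0.0, 0.4))
        grid = calibrate("sparsity", X, lam, cfg, n_out=24)
        assert len(grid.table) == 6 * 2  # six levels x two gammas
        assert (grid.table["n"] == 2).all()
        assert grid.table[["mean_decay", "mean_gof"]].notna().all().all()

    def test_deterministic_from_seed(self, small_setup):
        X, lam = small_setup
        cfg = SimulationConfig(
            n_sims=2, seed=5, sparsity_levels=(50.0, 90.0),
            gamma_levels=(0.0, 0.5),
        )
        g1 = calibrate("sparsity", X, lam, cfg, n_out=24)
        g2 = calibrate("sparsity", X, lam, cfg, n_out=24)
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_mean_gof_decreases_with_gamma(self, small_setup):
        X, lam = small_setup
        cfg = SimulationConfig(
            n_sims=15, seed=3, sparsity_levels=(80.0,),
            gamma_levels=(0.0, 0.3, 0.6, 0.9),
        )
        grid = calibrate("sparsity", X, lam, cfg, n_out=24)
        gofs = grid.table.sort_values("gamma")["mean_gof"].to_numpy()
        assert np.all(np.diff(gofs) < 0)

    def test_rdd_ordering_follows_sparsity_at_zero_noise(self, small_setup):
        X, lam = small_setup
        cfg = SimulationConfig(n_sims=15, seed=4, gamma_levels=(0.0,))
        grid = calibrate("sparsity", X, lam, cfg, n_out=24)
        sub = grid.table.sort_values("level")
        decays = sub["mean_decay"].to_numpy()
        assert np.all(np.diff(decays) < 0)  # sparser -> more negative RDD

    def test_deformation_ordering_at_zero_noise(self, small_setup):
        X, lam = small_setup
        cfg = SimulationConfig(n_sims=15, seed=6, gamma_levels=(0.0,))
        grid = calibrate("deformation", X, lam, cfg, n_out=24)
        sub = grid.table.set_index("level")["mean_decay"]
        # steeper simulated decay -> steeper estimated decay
        assert sub[-1.0] < sub[-0.1] < sub[-0.01]


class TestBracketEstimate:
    @staticmethod
    def grid_from_curves(kind, level_curves):
        """level_curves: {level: [(gof, decay), ...]}"""
        rows = []
        for level, pts in level_curves.items():
            for gamma, (gof, dec) in enumerate(pts):
                rows.append(
                    {
                        "level": level, "gamma": gamma / 10.0,
                        "mean_decay": dec, "mean_gof": gof,
                        "sd_decay": 0.1, "sd_gof": 1.0, "n": 10,
                    }
                )
        return CalibrationGrid(kind=kind, table=pd.DataFrame(rows))

    def test_point_between_two_levels(self):
        grid = self.grid_from_curves(
            "sparsity",
            {
                50.0: [(60.0, -4.0), (20.0, -3.0)],
                60.0: [(60.0, -5.0), (20.0, -4.0)],
                70.0: [(60.0, -6.0), (20.0, -5.0)],
            },
        )
        # interpolated decays at GOF 40: -3.5 (50%), -4.5 (60%), -5.5 (70%)
        br = bracket_estimate(grid, observed_decay=-4.2, observed_gof=40.0)
        assert (br.lower_level, br.upper_level) == (50.0, 60.0)
        assert br.contains(60.0) and not br.not_sparse

    def test_not_sparse_flag_below_lowest_level(self):
        grid = self.grid_from_curves(
            "sparsity",
            {50.0: [(60.0, -4.0), (20.0, -3.0)],
             60.0: [(60.0, -5.0), (20.0, -4.0)]},
        )
        br = bracket_estimate(grid, observed_decay=-2.0, observed_gof=40.0)
        assert br.not_sparse
        assert br.lower_level is None and br.upper_level == 50.0

    def test_point_exactly_on_curve_degenerate(self):
        grid = self.grid_from_curves(
            "sparsity",
            {50.0: [(60.0, -4.0), (20.0, -3.0)],
             60.0: [(60.0, -5.0), (20.0, -4.0)]},
        )
        br = bracket_estimate(grid, observed_decay=-3.5, observed_gof=40.0)
        assert br.lower_level == br.upper_level == 50.0

    def test_deformation_levels_keep_numeric_order(self):
        grid = self.grid_from_curves(
            "deformation",
            {0.0: [(60.0, -0.02), (20.0, -0.01)],
             -0.1: [(60.0, -0.06), (20.0, -0.04)],
             -1.0: [(60.0, -0.30), (20.0, -0.20)]},
        )
        br = bracket_estimate(grid, observed_decay=-0.04, observed_gof=40.0)
        assert (br.lower_level, br.upper_level) == (-0.1, 0.0)
        shallow = bracket_estimate(grid, observed_decay=-0.001, observed_gof=40.0)
        assert (shallow.lower_level, shallow.upper_level) == (0.0, None)
        assert not shallow.not_sparse
        steep = bracket_estimate(grid, observed_decay=-0.9, observed_gof=40.0)
        assert (steep.lower_level, steep.upper_level) == (None, -1.0)

    def test_gof_outside_curves_warns(self):
        grid = self.grid_from_curves(
            "sparsity",
            {50.0: [(60.0, -4.0), (20.0, -3.0)],
             60.0: [(60.0, -5.0), (20.0, -4.0)]},
        )
        with pytest.warns(UserWarning, match="extrapolation"):
            br = bracket_estimate(grid, observed_decay=-4.5, observed_gof=90.0)
        assert br.extrapolated

    def test_contains_handles_open_ends(self):
        br = BracketEstimate(90.0, None, -8.0, 30.0)
        assert br.contains(99.0) and not br.contains(80.0)


class TestSimulatePatternPair:
    def test_shapes_and_normalisation(self, rng):
        X, Y, T = simulate_pattern_pair(12, 10, 8, rng, sparsity_percent=50)
        assert X.values.shape == (12, 8)
        assert Y.values.shape == (10, 8)
        assert T.shape == (10, 12)
        assert X.normalised and Y.normalised

    def test_mutually_exclusive_ground_truths(self, rng):
        with pytest.raises(ValueError):
            simulate_pattern_pair(5, 5, 5, rng, sparsity_percent=50, decay_b=-1)
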