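"""PCA projection and least-squares driver decomposition."""

import numpy as np
import pytest

from cbgtlearn import drivers as dr
from cbgtlearn import synth


class TestPcaDelta:
    def test_rank_one_single_pc(self, rng):
        u = rng.standard_normal(16)
        scores = rng.standard_normal(40)
        delta = np.outer(scores, u)
        V, frac = dr.pca_delta(delta, k=5)
        assert frac[0] == pytest.approx(1.0)
        assert V.shape == (16, 5)

    def test_planted_five_factors_explain_90pct(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((16, 5)))
        delta = rng.standard_normal((200, 5)) @ Q.T + 0.05 * rng.standard_normal((200, 16))
        _, frac = dr.pca_delta(delta, k=5)
        assert frac.sum() >= 0.9

    def test_orthonormal_components(self, rng):
        delta = rng.standard_normal((60, 16))
        V, _ = dr.pca_delta(delta, k=5)
        np.testing.assert_allclose(V.T @ V, np.eye(5), atol=1e-10)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            dr.pca_delta(rng.standard_normal((5, 16)), k=5)


class TestProject:
    def test_zero_delta(self, rng):
        V = rng.standard_normal((16, 5))
        U = rng.standard_normal((16, 3))
        P, C = dr.project(np.zeros((10, 16)), V, U)
        assert not P.any() and not C.any()

    def test_single_component_delta(self, rng):
        V, _ = np.linalg.qr(rng.standard_normal((16, 5)))
        delta = np.tile(V[:, 2], (7, 1))
        P, _ = dr.project(delta, V, V[:, :3])
        assert np.allclose(P[:, [0, 1, 3, 4]], 0, atol=1e-12)
        assert np.allclose(P[:, 2], 1.0)


class TestSolveDrivers:
    def test_exact_recovery(self, rng):
        C = rng.standard_normal((50, 3))
        S0 = rng.standard_normal((3, 5))
        S, cond, used_pinv = dr.solve_drivers(C @ S0, C)
        np.testing.assert_allclose(S, S0, atol=1e-12)
        assert not used_pinv

    def test_orthonormal_C_gives_CtP(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        P = rng.standard_normal((30, 5))
        S, _, _ = dr.solve_drivers(P, Q)
        np.testing.assert_allclose(S, Q.T @ P, atol=1e-12)

    def test_least_squares_optimality_vs_perturbations(self, rng):
        """Brute-force check: no perturbed S' on a sampled grid beats the
        normal-equation solution's residual."""
        C = rng.standard_normal((40, 3))
        S0 = rng.standard_normal((3, 5))
        P = C @ S0 + 0.3 * rng.standard_normal((40, 5))
        S, _, _ = dr.solve_drivers(P, C)
        best = np.linalg.norm(P - C @ S)
        for _ in range(200):
            Sp = S + rng.standard_normal(S.shape) * rng.choice([1e-3, 1e-2, 0.1])
            assert np.linalg.norm(P - C @ Sp) >= best - 1e-12

    def test_ill_conditioned_falls_back_to_pinv(self, rng):
        C = np.zeros((20, 3))
        C[:, 0] = rng.standard_normal(20)
        C[:, 1] = C[:, 0]  # exactly collinear
        C[:, 2] = rng.standard_normal(20)
        P = rng.standard_normal((20, 5))
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            S, cond, used_pinv = dr.solve_drivers(P, C)
        assert used_pinv


class TestWeightedDriver:
    def test_single_pc(self):
        S = np.arange(15.0).reshape(3, 5)
        w = np.array([1.0, 0, 0, 0, 0])
        np.testing.assert_allclose(dr.weighted_driver(S, w), S[:, 0])

    def test_zero_matrix(self):
        assert not dr.weighted_driver(np.zeros((3, 5)), np.full(5, 0.2)).any()

    def test_linearity(self):
        col = np.array([1.0, -2.0, 3.0])
        S = np.tile(col[:, None], (1, 5))
        w = np.array([0.6, 0.3, 0, 0, 0])
        np.testing.assert_allclose(dr.weighted_driver(S, w), 0.9 * col)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dr.weighted_driver(np.zeros((3, 5)), np.zeros(4))


class TestPipelineLinearity:
    def test_scaling_delta_leaves_S_unchanged(self):
        delta, U, V, S0 = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=80, noise_scale=0.1, seed=3)
        )
        P1, C1 = dr.project(delta, V, U)
        S1, _, _ = dr.solve_drivers(P1, C1)
        P2, C2 = dr.project(3.7 * delta, V, U)
        S2, _, _ = dr.solve_drivers(P2, C2)
        np.testing.assert_allclose(S1, S2, atol=1e-10)

    def test_noiseless_recovery_and_rmse_scaling(self):
        rng = np.random.default_rng(0)
        S0 = rng.standard_normal((3, 5))
        delta, U, V, _ = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=50, S0=S0, noise_scale=0.0, seed=1)
        )
        P, C = dr.project(delta, V, U)
        S, _, _ = dr.solve_drivers(P, C)
        np.testing.assert_allclose(S, S0, atol=1e-10)
        # estimator error decreases with cohort size under noise
        rmses = {}
        for n in (30, 100, 300):
            errs = []
            for seed in range(5):
                d, Un, Vn, S0n = synth.gen_driver_cohort(synth.SurrogateDriverSpec(
                    n_networks=n, S0=S0, noise_scale=0.5, seed=100 * n + seed
                ))
                Pn, Cn = dr.project(d, Vn, Un)
                Sn, _, _ = dr.solve_drivers(Pn, Cn)
                errs.append(np.mean((Sn - S0n) ** 2))
            rmses[n] = np.sqrt(np.mean(errs))
        assert rmses[30] > rmses[100] > rmses[300]


class TestReconstruction:
    def test_rank_correlation_of_consistent_system(self, rng):
        delta, U, V, S0 = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=60, noise_scale=0.05, seed=8)
        )
        res = dr.DriverResult(
            S=S0, V=V, variance_fractions=np.full(5, 0.2),
            P=delta @ V, C=delta @ U, condition_number=1.0,
        )
        rc = dr.reconstruction_rank_corr(res)
        assert np.all(rc > 0.9)


class TestSequenceDrivers:
    def test_opposite_planted_effects(self):
        rng = np.random.default_rng(4)
        S0 = rng.standard_normal((3, 5))
        d_uu, U, V, _ = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=40, S0=S0, score_mean=1.0, seed=10)
        )
        d_rr, _, _, _ = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=40, S0=-S0, V=V, score_mean=1.0, seed=11)
        )
        # R-R cohort has the sign-flipped driver structure of U-U
        delta = np.vstack([d_uu, d_rr])
        seqs = np.array(["U-U"] * 40 + ["R-R"] * 40)
        out = dr.sequence_drivers(delta, seqs, U, k=5, min_group=5)
        w_uu = out["groups"]["U-U"]["weighted_driver"]
        w_rr = out["groups"]["R-R"]["weighted_driver"]
        # same structure, opposite sign: strongly anticorrelated drivers
        cos = np.dot(w_uu, w_rr) / (np.linalg.norm(w_uu) * np.linalg.norm(w_rr))
        assert cos < -0.9
        assert set(out["flagged"]) == {"U-R", "R-U"}

    def test_identical_delta_rr_gives_zero_F(self):
        rng = np.random.default_rng(1)
        delta, U, V, _ = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=60, seed=2)
        )
        seqs = np.array((["U-U"] * 15) + (["U-R"] * 15) + (["R-U"] * 15) + (["R-R"] * 15))
        speed = np.array((["fast", "intermediate", "slow"] * 20))
        out = dr.sequence_drivers(
            delta, seqs, U, delta_rr=np.full(60, 0.3), speed_class=speed, k=5
        )
        anova = out["anova"]
        assert float(anova["F"].iloc[0]) == pytest.approx(0.0, abs=1e-10)

    def test_single_group_flags_others(self):
        delta, U, V, _ = synth.gen_driver_cohort(
            synth.SurrogateDriverSpec(n_networks=30, seed=5)
        )
        out = dr.sequence_drivers(delta, np.array(["R-R"] * 30), U, k=5)
        assert set(out["flagged"]) == {"U-U", "U-R", "R-U"}
        assert list(out["groups"]) == ["R-R"]
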