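import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import covpcn as cp
from covpcn.recurrent import (
    RecurrentParams,
    energy_recurrent,
    error_recurrent,
    recurrent_gradients,
)


def make_params(W, nu, variant="implicit", nonlinearity="identity"):
    return RecurrentParams(W=np.asarray(W, float), nu=np.asarray(nu, float),
                           variant=variant, nonlinearity=nonlinearity)


class TestErrorAndEnergy:
    def test_zero_weights_error_is_activity(self):
        p = RecurrentParams.zeros(3)
        x = np.array([1.0, -2.0, 0.5])
        npt.assert_array_equal(error_recurrent(x, p), x)

    def test_symmetric_half_coupling(self):
        p = make_params([[0.0, 0.5], [0.5, 0.0]], [0.0, 0.0])
        npt.assert_allclose(error_recurrent(np.ones(2), p), [0.5, 0.5])
        assert energy_recurrent(np.ones(2), p) == pytest.approx(-0.25)

    def test_tanh_error_vanishes_at_origin(self):
        p = make_params(np.random.default_rng(0).normal(size=(4, 4)), np.zeros(4),
                        nonlinearity="tanh")
        npt.assert_allclose(error_recurrent(np.zeros(4), p), 0.0)

    def test_energy_invariant_under_variant_toggle(self):
        rng = np.random.default_rng(1)
        W, nu, x = rng.normal(size=(3, 3)), rng.normal(size=3), rng.normal(size=3)
        e_im = energy_recurrent(x, make_params(W, nu, "implicit"))
        e_den = energy_recurrent(x, make_params(W, nu, "dendritic"))
        assert e_im == e_den


class TestLearning:
    def test_convergence_identities(self, gaussian_patterns, trained_recurrent):
        """ν = (I-W)x̄ and off-diag[(I-W)S] = 0 at learning convergence."""
        s = cp.sample_stats(gaussian_patterns)
        W, nu = trained_recurrent.W, trained_recurrent.nu
        I = np.eye(gaussian_patterns.d)
        npt.assert_allclose(nu, (I - W) @ s.mean, rtol=1e-4, atol=1e-8)
        R = (I - W) @ s.cov
        off = ~np.eye(gaussian_patterns.d, dtype=bool)
        assert np.abs(R[off]).max() < 1e-5

    def test_single_pattern_becomes_zero_error(self):
        x_star = np.array([0.7, -0.3, 1.2])
        pats = cp.PatternMatrix(x_star[None, :])
        p = cp.learn_recurrent(pats, cp.TrainConfig(max_epochs=100_000,
                                                    convergence_tol=1e-13))
        npt.assert_allclose(p.W @ x_star + p.nu, x_star, atol=1e-8)

    def test_diagonal_stays_zero(self, trained_recurrent):
        npt.assert_array_equal(np.diag(trained_recurrent.W), 0.0)

    def test_stop_gradient_training_equivalence(self, gaussian_patterns):
        """Implicit and dendritic variants share the learning rule exactly."""
        cfg = cp.TrainConfig(max_epochs=500, convergence_tol=0.0)
        im = cp.learn_recurrent(gaussian_patterns, cfg,
                                RecurrentParams.zeros(6, "implicit"))
        den = cp.learn_recurrent(gaussian_patterns, cfg,
                                 RecurrentParams.zeros(6, "dendritic"))
        npt.assert_array_equal(im.W, den.W)
        npt.assert_array_equal(im.nu, den.nu)

    def test_hebbian_locality(self):
        """ΔW_ab is the product of post-synaptic error a and pre-synaptic
        activity b summed over patterns — no other entries involved."""
        rng = np.random.default_rng(5)
        pats = cp.PatternMatrix(rng.normal(size=(7, 4)))
        params = make_params(rng.normal(size=(4, 4)), rng.normal(size=4))
        gW, gnu = recurrent_gradients(pats, params)
        eps = np.array([error_recurrent(x, params) for x in pats.values])
        for a in range(4):
            for b in range(4):
                expected = 0.0 if a == b else np.sum(eps[:, a] * pats.values[:, b])
                assert gW[a, b] == pytest.approx(expected, rel=1e-12)
        npt.assert_allclose(gnu, eps.sum(axis=0))

    @pytest.mark.parametrize("nonlinearity", ["identity", "tanh"])
    def test_updates_match_finite_differences(self, nonlinearity):
        rng = np.random.default_rng(8)
        pats = cp.PatternMatrix(rng.normal(size=(5, 3)) * 0.5)
        params = make_params(rng.normal(size=(3, 3)) * 0.3, rng.normal(size=3),
                             nonlinearity=nonlinearity)
        gW, gnu = recurrent_gradients(pats, params)
        h = 1e-6

        def total(W, nu):
            p = make_params(W, nu, nonlinearity=nonlinearity)
            return sum(energy_recurrent(x, p) for x in pats.values)

        for a in range(3):
            e = np.zeros(3)
            e[a] = h
            fd = (total(params.W, params.nu + e) - total(params.W, params.nu - e)) / (2 * h)
            assert gnu[a] == pytest.approx(fd, rel=1e-5, abs=1e-7)
            for b in range(3):
                if a == b:
                    continue  # constrained to zero, no free gradient
                E = np.zeros((3, 3))
                E[a, b] = h
                fd = (total(params.W + E, params.nu) - total(params.W - E, params.nu)) / (2 * h)
                assert gW[a, b] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestInference:
    def test_zero_weight_implicit_decays_to_origin(self):
        p = RecurrentParams.zeros(3)
        cue = cp.CueSpec(cue=np.array([1.0, 2.0, -1.0]), corrupted_idx=np.arange(3),
                         kind="none")
        res = cp.infer_recurrent(cue, p, cp.InferConfig(step_size=0.5, max_iters=10_000,
                                                        convergence_tol=1e-12,
                                                        relax_set="all"))
        assert res.converged
        npt.assert_allclose(res.x_final, 0.0, atol=1e-8)

    def test_completion_matches_theorem_oracle(self, gaussian_patterns,
                                               trained_recurrent, tight_infer):
        stats = cp.sample_stats(gaussian_patterns)
        for cue in cp.corrupt_mask(gaussian_patterns, [0, 3])[:5]:
            oracle = cp.theorem_retrieval_oracle(stats, cue)
            res = cp.infer_recurrent(cue, trained_recurrent, tight_infer)
            assert res.converged
            npt.assert_allclose(res.x_final[cue.corrupted_idx], oracle, rtol=1e-4,
                                atol=1e-8)

    def test_two_dim_retrieval_lies_on_ols_regression_line(self):
        """Masked-x2 retrieval equals the independently fitted least-squares
        prediction of x2 from x1."""
        rng = np.random.default_rng(17)
        x1 = rng.normal(size=60)
        x2 = 0.8 * x1 + rng.normal(scale=0.4, size=60)
        pats = cp.PatternMatrix(np.column_stack([x1, x2]))
        params = cp.learn_recurrent(pats, cp.TrainConfig(max_epochs=200_000,
                                                         convergence_tol=1e-13))
        slope, intercept = np.polyfit(x1, x2, 1)  # independent OLS oracle
        cues = cp.corrupt_mask(pats, [1])
        for cue in cues[:8]:
            res = cp.infer_recurrent(cue, params,
                                     cp.InferConfig(max_iters=100_000,
                                                    convergence_tol=1e-13))
            expected = slope * cue.cue[0] + intercept
            assert res.x_final[1] == pytest.approx(expected, rel=1e-4, abs=1e-8)

    def test_dendritic_and_implicit_share_fixed_points(self, gaussian_patterns,
                                                       trained_recurrent, tight_infer):
        den = RecurrentParams(trained_recurrent.W, trained_recurrent.nu, "dendritic")
        cue = cp.corrupt_mask(gaussian_patterns, [2, 5])[0]
        r_im = cp.infer_recurrent(cue, trained_recurrent, tight_infer)
        r_den = cp.infer_recurrent(cue, den, tight_infer)
        assert r_im.converged and r_den.converged
        npt.assert_allclose(r_im.x_final, r_den.x_final, rtol=1e-3, atol=1e-8)

    def test_cross_model_equivalence(self, gaussian_patterns, trained_recurrent,
                                     trained_explicit, tight_infer):
        """Explicit, implicit, and dendritic converge to the same retrieval."""
        cue = cp.corrupt_mask(gaussian_patterns, [1, 2, 4])[3]
        outs = [
            cp.infer_explicit(cue, trained_explicit, tight_infer).x_final,
            cp.infer_recurrent(cue, trained_recurrent, tight_infer).x_final,
            cp.infer_recurrent(
                cue, RecurrentParams(trained_recurrent.W, trained_recurrent.nu,
                                     "dendritic"), tight_infer).x_final,
        ]
        for a in outs[1:]:
            npt.assert_allclose(a, outs[0], rtol=1e-3, atol=1e-6)

    def test_energy_nondecreasing_for_small_fixed_step(self, trained_recurrent,
                                                       gaussian_patterns):
        """Full relaxation ascends F = -1/2 ||eps||^2 monotonically whenever
        the step stays below the 2/lambda_max(M^T M) stability bound."""
        M = trained_recurrent.W - np.eye(6)
        beta = 1.0 / np.linalg.eigvalsh(M.T @ M)[-1]
        cue = cp.CueSpec(cue=gaussian_patterns.values[1] + 0.5,
                         corrupted_idx=np.arange(6), kind="none")
        res = cp.infer_recurrent(cue, trained_recurrent,
                                 cp.InferConfig(step_size=beta, max_iters=2_000,
                                                convergence_tol=1e-13,
                                                relax_set="all"))
        assert np.all(np.diff(res.energy_trace) >= -1e-10)

    def test_divergence_is_flagged_not_raised(self):
        # dendritic dynamics with a strongly positive eigenvalue of M
        W = np.array([[0.0, 3.0], [3.0, 0.0]])
        p = make_params(W, np.zeros(2), variant="dendritic")
        cue = cp.CueSpec(cue=np.array([1.0, 1.0]), corrupted_idx=[0, 1], kind="none")
        res = cp.infer_recurrent(cue, p, cp.InferConfig(step_size=0.5, max_iters=10_000,
                                                        relax_set="all"))
        assert res.diverged and not res.converged

    def test_noise_cue_relaxes_all_coordinates(self, trained_recurrent,
                                               gaussian_patterns):
        cue = cp.corrupt_noise(gaussian_patterns, 0.1, seed=0)[0]
        res = cp.infer_recurrent(cue, trained_recurrent,
                                 cp.InferConfig(max_iters=20_000,
                                                convergence_tol=1e-10))
        # every coordinate moved: denoising is full relaxation
        assert np.all(res.x_final != cue.cue)


class TestNonlinear:
    def test_toy_memories_become_fixed_points(self):
        pats = cp.generate_toy_3d(seed=0)
        p = cp.learn_recurrent(pats, cp.TrainConfig(max_epochs=300_000,
                                                    convergence_tol=1e-13),
                               RecurrentParams.zeros(3, nonlinearity="tanh"))
        for x in pats.values:
            assert np.linalg.norm(error_recurrent(x, p)) < 1e-3

    def test_literal_presynaptic_mode_differs_under_tanh(self):
        rng = np.random.default_rng(2)
        pats = cp.PatternMatrix(rng.normal(size=(4, 3)))
        params = make_params(rng.normal(size=(3, 3)), np.zeros(3), nonlinearity="tanh")
        gW_grad, _ = recurrent_gradients(pats, params, literal_presynaptic=False)
        gW_lit, _ = recurrent_gradients(pats, params, literal_presynaptic=True)
        assert not np.allclose(gW_grad, gW_lit)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_diagonal_zero_after_every_training_mode(seed):
    rng = np.random.default_rng(seed)
    n, d = int(rng.integers(2, 10)), int(rng.integers(2, 6))
    pats = cp.PatternMatrix(rng.normal(size=(n, d)))
    mode = ["full_batch", "online", "minibatch"][seed % 3]
    cfg = cp.TrainConfig(mode=mode, max_epochs=20, convergence_tol=0.0,
                         batch_size=max(1, n // 2), seed=seed)
    p = cp.learn_recurrent(pats, cfg)
    npt.assert_array_equal(np.diag(p.W), 0.0)
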