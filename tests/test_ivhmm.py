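import numpy as np
import pytest

from conftest import random_likelihoods
from oracles import (
    dense_fb_oracle,
    emission_oracle,
    path_sum_oracle,
    viterbi_oracle,
)
from pedcaller.genmap import transition_matrix
from pedcaller.ivhmm import (
    EmissionEngine,
    emission,
    fast_transition_apply,
    forward_backward,
    founder_prior,
    viterbi,
)
from pedcaller.simulate import pedigree_template


class TestEmission:
    def test_uniform_likelihoods_emit_one_everywhere(self, nuc4):
        eng = EmissionEngine(nuc4)
        e = eng.state_emission(np.ones((4, 3)), q=0.37)
        assert np.allclose(e, 1.0, atol=1e-12)

    def test_trio_perfect_opposite_homozygotes(self, trio):
        # RR father x AA mother forces a het child; emission = (1-q)^2 q^2
        q = 0.3
        L = np.full((3, 3), 1e-12)
        L[0, 0] = L[1, 2] = L[2, 1] = 1.0
        eng = EmissionEngine(trio)
        e = eng.state_emission(L, q)
        assert np.allclose(e, (1 - q) ** 2 * q**2, rtol=1e-9)

    @pytest.mark.parametrize("structure", ["Sib2", "Nuc4", "Ext10"])
    def test_engine_matches_enumeration_oracle(self, structure, rng):
        ped = pedigree_template(structure)
        eng = EmissionEngine(ped)
        for _ in range(3):
            L = random_likelihoods(rng, ped.size)
            q = float(rng.uniform(0.01, 0.5))
            got = eng.state_emission(L, q)
            states = rng.integers(0, ped.n_states, size=8)
            for k in states:
                assert got[k] == pytest.approx(
                    emission_oracle(ped, int(k), L, q), rel=1e-10
                )

    def test_constant_within_founder_symmetry_class(self, sib2, rng):
        eng = EmissionEngine(sib2)
        L = random_likelihoods(rng, sib2.size)
        e = eng.state_emission(L, 0.2)
        for cls in range(eng.n_classes):
            vals = e[eng.classes.class_of == cls]
            assert np.ptp(vals) <= 1e-12 * max(vals.max(), 1e-300)

    def test_reference_emission_agrees_with_oracle(self, nuc4, rng):
        L = random_likelihoods(rng, nuc4.size)
        for k in (0, 7, 12):
            assert emission(nuc4, k, L, 0.25) == pytest.approx(
                emission_oracle(nuc4, k, L, 0.25), rel=1e-12
            )

    def test_founder_prior_sums_to_one(self):
        for q in (0.001, 0.3, 0.9):
            assert founder_prior(q).sum() == pytest.approx(1.0)


class TestFastTransitionApply:
    def test_theta_zero_is_identity(self, rng):
        v = rng.random(16)
        assert np.allclose(fast_transition_apply(v, 0.0), v)

    def test_theta_half_fully_mixes(self, rng):
        v = rng.random(16)
        out = fast_transition_apply(v, 0.5)
        assert np.allclose(out, v.mean(), atol=1e-12)

    @pytest.mark.parametrize("nb,theta", [(2, 0.1), (4, 0.1), (4, 0.37), (6, 0.02)])
    def test_matches_dense_matrix(self, nb, theta, rng):
        v = rng.random(1 << nb)
        dense = transition_matrix(theta, nb) @ v
        assert np.allclose(fast_transition_apply(v, theta), dense, atol=1e-12)

    def test_rejects_bad_length(self):
        with pytest.raises(ValueError):
            fast_transition_apply(np.ones(5), 0.1)


class TestForwardBackward:
    def test_single_site_posterior_proportional_to_emission(self, rng):
        E = rng.random((1, 16))
        post, ll = forward_backward(E, np.empty(0))
        assert np.allclose(post[0], E[0] / E[0].sum())
        assert ll == pytest.approx(np.log(E[0].mean()))

    def test_uniform_emissions_stay_uniform(self):
        E = np.ones((5, 16))
        post, _ = forward_backward(E, np.full(4, 0.1))
        assert np.allclose(post, 1 / 16)

    @pytest.mark.parametrize("nb,M", [(2, 6), (4, 4), (4, 6)])
    def test_matches_dense_oracle(self, nb, M, rng):
        E = rng.random((M, 1 << nb)) + 1e-3
        thetas = rng.uniform(0.0, 0.45, M - 1)
        post, ll = forward_backward(E, thetas)
        post_o, ll_o = dense_fb_oracle(E, thetas, nb)
        assert np.allclose(post, post_o, atol=1e-10)
        assert ll == pytest.approx(ll_o, abs=1e-10)

    @pytest.mark.parametrize("nb,M", [(2, 5), (4, 3)])
    def test_loglik_matches_path_enumeration(self, nb, M, rng):
        E = rng.random((M, 1 << nb)) + 1e-3
        thetas = rng.uniform(0.01, 0.4, M - 1)
        _, ll = forward_backward(E, thetas)
        assert ll == pytest.approx(np.log(path_sum_oracle(E, thetas, nb)), abs=1e-8)

    def test_posteriors_normalized(self, rng):
        E = rng.random((8, 64)) + 1e-6
        post, _ = forward_backward(E, rng.uniform(0, 0.5, 7))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_all_zero_emission_names_site(self):
        E = np.ones((3, 4))
        E[1] = 0.0
        with pytest.raises(ValueError, match="site 1"):
            forward_backward(E, np.full(2, 0.1))


class TestViterbi:
    def test_single_dominant_emission(self):
        E = np.full((1, 16), 0.01)
        E[0, 11] = 1.0
        assert viterbi(E, np.empty(0)).best[0] == 11

    def test_uniform_ties_break_to_state_zero(self):
        E = np.ones((4, 16))
        path = viterbi(E, np.full(3, 0.2))
        assert np.all(path.best == 0)
        assert np.all(path.marg == 0)

    @pytest.mark.parametrize("nb,M", [(2, 6), (4, 4)])
    def test_matches_exhaustive_path_search(self, nb, M, rng):
        E = rng.random((M, 1 << nb)) + 1e-3
        thetas = rng.uniform(0.01, 0.4, M - 1)
        got = viterbi(E, thetas)
        assert np.array_equal(got.best, viterbi_oracle(E, thetas, nb))


class TestTransitionProperties:
    """Randomized invariants of the factorized transition operator."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        theta=st.floats(0.0, 0.5),
        seed=st.integers(0, 2**16),
        nb=st.sampled_from([2, 4]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_fast_apply_equals_dense_and_preserves_mass(self, theta, seed, nb):
        v = np.random.default_rng(seed).random(1 << nb)
        out = fast_transition_apply(v, theta)
        dense = transition_matrix(theta, nb) @ v
        assert np.allclose(out, dense, atol=1e-12)
        assert out.sum() == pytest.approx(v.sum())  # doubly stochastic kernel


class TestPosteriorSymmetry:
    def test_posterior_mass_equal_within_classes(self, sib2, rng):
        """IV posteriors inherit founder-flip invariance from emissions."""
        eng = EmissionEngine(sib2)
        M = 5
        E = np.empty((M, sib2.n_states))
        for j in range(M):
            E[j] = eng.state_emission(random_likelihoods(rng, sib2.size), 0.3)
        post, _ = forward_backward(E, np.full(M - 1, 0.05))
        for j in range(M):
            for cls in range(eng.n_classes):
                vals = post[j][eng.classes.class_of == cls]
                assert np.ptp(vals) <= 1e-12
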