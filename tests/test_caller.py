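import numpy as np
import pytest

from conftest import random_likelihoods
from oracles import (
    genotype_posterior_oracle,
    haplotype_oracle,
    site_poly_posterior_oracle,
)
from pedcaller.caller import (
    PhasingUnsupported,
    assign_interval_ivs,
    call_haplotypes,
    estimate_af,
    genotype_posteriors,
    poly_prior,
    site_poly_posterior,
)
from pedcaller.ivhmm import EmissionEngine
from pedcaller.simulate import pedigree_template


def _state_to_class_post(engine, state_post):
    return engine.class_posterior(np.asarray(state_post, dtype=float))


class TestPolyPrior:
    def test_one_founder(self):
        assert poly_prior(1).p_poly == pytest.approx(0.0015)

    def test_two_founders(self):
        assert poly_prior(2).p_poly == pytest.approx(0.001 * (1 + 1 / 2 + 1 / 3 + 1 / 4))

    @pytest.mark.parametrize("f", range(1, 11))
    def test_harmonic_closed_form(self, f):
        expect = 0.001 * sum(1.0 / i for i in range(1, 2 * f + 1))
        assert poly_prior(f).p_poly == expect

    def test_degenerate_theta_rejected(self):
        with pytest.raises(ValueError):
            poly_prior(2, theta_mut=0.0)


class TestSitePolyPosterior:
    def test_uninformative_data_returns_prior(self, nuc4):
        eng = EmissionEngine(nuc4)
        prior = poly_prior(nuc4.f)
        w = np.full(eng.n_classes, 1.0 / eng.n_classes)
        p, vq, _ = site_poly_posterior(eng, np.ones((4, 3)), w, prior, q=0.2)
        assert p == pytest.approx(prior.p_poly, rel=1e-9)

    def test_confident_reference_kills_vq(self, nuc4):
        eng = EmissionEngine(nuc4)
        prior = poly_prior(nuc4.f)
        L = np.full((4, 3), 1e-12)
        L[:, 0] = 1.0
        w = np.full(eng.n_classes, 1.0 / eng.n_classes)
        p, vq, _ = site_poly_posterior(eng, L, w, prior, q=0.01)
        assert p < 1e-6 and vq < 1e-4

    def test_matches_brute_force_bayes(self, trio, rng):
        eng = EmissionEngine(trio)
        prior = poly_prior(trio.f)
        for _ in range(5):
            L = random_likelihoods(rng, 3)
            sp = rng.random(trio.n_states)
            sp /= sp.sum()
            p, _, _ = site_poly_posterior(
                eng, L, _state_to_class_post(eng, sp), prior, q=0.05
            )
            expect = site_poly_posterior_oracle(trio, L, sp, 0.05, prior.p_poly)
            assert p == pytest.approx(expect, abs=1e-10)

    def test_interval_site_takes_max_side(self, trio, rng):
        eng = EmissionEngine(trio)
        prior = poly_prior(trio.f)
        L = random_likelihoods(rng, 3)
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0, 0, 0, 1.0])
        ca, cb = _state_to_class_post(eng, a), _state_to_class_post(eng, b)
        pa, _, _ = site_poly_posterior(eng, L, ca, prior, 0.05)
        pb, _, _ = site_poly_posterior(eng, L, cb, prior, 0.05)
        p, _, side = site_poly_posterior(eng, L, (ca, cb), prior, 0.05)
        assert p == pytest.approx(max(pa, pb))
        assert side == ("left" if pa >= pb else "right")


class TestGenotypePosteriors:
    def test_uninformative_founders_get_hwe_prior(self, nuc4):
        eng = EmissionEngine(nuc4)
        q = 0.3
        w = np.full(eng.n_classes, 1.0 / eng.n_classes)
        post, _, _ = genotype_posteriors(eng, np.ones((4, 3)), w, q, truncation=1.0)
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        assert np.allclose(post[0], hwe, atol=1e-12)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_ibd2_sib_borrows_evidence(self, sib2):
        """An unsequenced-depth sib inherits the confident het call of its
        IBD-2 sibling -- the depth-sharing effect motivating the method."""
        eng = EmissionEngine(sib2)
        L = np.ones((4, 3))
        L[2] = [1e-8, 1.0, 1e-8]  # S1 confidently het
        # state 0: both sibs receive identical meioses -> IBD 2
        w = np.zeros(eng.n_classes)
        w[eng.classes.class_of[0]] = 1.0
        post, calls, _ = genotype_posteriors(eng, L, w, q=0.2, truncation=1.0)
        assert calls[3] == 1
        assert post[3, 1] > 0.95

    def test_matches_enumeration_oracle(self, sib2, rng):
        eng = EmissionEngine(sib2)
        for _ in range(4):
            L = random_likelihoods(rng, 4)
            sp = rng.random(sib2.n_states)
            sp /= sp.sum()
            post, _, _ = genotype_posteriors(
                eng, L, _state_to_class_post(eng, sp), q=0.1, truncation=1.0
            )
            expect = genotype_posterior_oracle(sib2, L, sp, 0.1)
            assert np.allclose(post, expect, atol=1e-10)

    def test_single_best_equals_full_when_degenerate(self, nuc4, rng):
        eng = EmissionEngine(nuc4)
        L = random_likelihoods(rng, 4)
        w = np.zeros(eng.n_classes)
        w[2] = 1.0 - 1e-12
        w[0] = 1e-12
        _, full_calls, _ = genotype_posteriors(eng, L, w, 0.2, truncation=1.0)
        _, best_calls, _ = genotype_posteriors(eng, L, w, 0.2, truncation="best")
        assert np.array_equal(full_calls, best_calls)

    def test_bad_truncation_rejected(self, nuc4, rng):
        eng = EmissionEngine(nuc4)
        w = np.full(eng.n_classes, 1 / eng.n_classes)
        with pytest.raises(ValueError):
            genotype_posteriors(eng, np.ones((4, 3)), w, 0.2, truncation=0.0)


class TestCallHaplotypes:
    def test_perfect_trio_transmission(self, trio):
        q = 0.4
        L = np.full((3, 3), 1e-12)
        L[0, 0] = L[1, 2] = L[2, 1] = 1.0  # RR x AA -> het child
        eng = EmissionEngine(trio)
        ordered, gq = call_haplotypes(eng, L, best_state=0, q=q)
        # child: paternal ref, maternal alt
        assert tuple(ordered[2]) == (0, 1)
        assert (gq >= 0).all()

    def test_matches_argmax_oracle(self, nuc4, rng):
        eng = EmissionEngine(nuc4)
        for state in (0, 6, 11):
            L = random_likelihoods(rng, 4)
            ordered, _ = call_haplotypes(eng, L, state, q=0.3)
            assert np.array_equal(ordered, haplotype_oracle(nuc4, L, state, 0.3))

    def test_sibship_phasing_rejected(self):
        sib4 = pedigree_template("Sib4")
        eng = EmissionEngine(sib4)
        with pytest.raises(PhasingUnsupported):
            call_haplotypes(eng, np.ones((6, 3)), 0, 0.2)


class TestIntervalAssignment:
    def test_scaffold_sites_marked_self(self):
        pos = np.array([10, 20, 30, 40, 50])
        ia = assign_interval_ivs(pos, np.array([1, 3]))
        assert list(ia.chosen_side) == [-1, 2, -1, 2, -1]

    def test_flanks_are_nearest_scaffold(self):
        pos = np.array([10, 20, 30, 40, 50])
        ia = assign_interval_ivs(pos, np.array([1, 3]))
        assert ia.left[0] == -1 and ia.right[0] == 0
        assert ia.left[2] == 0 and ia.right[2] == 1
        assert ia.left[4] == 1 and ia.right[4] == -1


class TestCoverageMonotonicity:
    def test_more_confident_reads_never_hurt_in_expectation(self, nuc4):
        """Sharpening one member's likelihoods (more reads pointing the same
        way) must not decrease that member's mean posterior mass on the true
        genotype, over a fixed 500-site ensemble."""
        from pedcaller.simulate import SimConfig, simulate_family

        cfg = SimConfig(structure="Nuc4", n_sites=500, coverage=4.0)
        truth, L, _d = simulate_family(cfg, np.random.default_rng(99))
        eng = EmissionEngine(truth.ped)
        uniform = np.full(eng.n_classes, 1.0 / eng.n_classes)
        member = 2
        base, sharp = [], []
        for j in range(500):
            Lj = L[:, j, :].copy()
            post, _, _ = genotype_posteriors(eng, Lj, uniform, float(truth.q[j]), 1.0)
            base.append(post[member, truth.genotypes[member, j]])
            Lj2 = Lj.copy()
            Lj2[member] = Lj[member] ** 2  # doubled evidence, same direction
            Lj2[member] /= Lj2[member].max()
            post2, _, _ = genotype_posteriors(eng, Lj2, uniform, float(truth.q[j]), 1.0)
            sharp.append(post2[member, truth.genotypes[member, j]])
        assert np.mean(sharp) >= np.mean(base) - 1e-12


class TestEstimateAf:
    def test_recovers_frequency_from_confident_genotypes(self, rng):
        q_true = 0.3
        n = 400
        g = rng.binomial(2, q_true, size=n)
        L = np.full((n, 1, 3), 1e-9)
        L[np.arange(n), 0, g] = 1.0
        q_hat = estimate_af(L)
        assert q_hat[0] == pytest.approx(g.mean() / 2, abs=1e-4)
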