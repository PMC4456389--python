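"""Independent brute-force oracles used by the test suite.

Everything here is written by direct enumeration (paths, founder
configurations, genotype configurations) without reusing the package's
vectorized machinery, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def hamming(a: int, b: int) -> int:
    return bin(a ^ b).count("1")


def trans(a: int, b: int, theta: float, nb: int) -> float:
    h = hamming(a, b)
    return theta**h * (1 - theta) ** (nb - h)


# ---------------------------------------------------------------------- #
# allele flow by explicit recursive tracing


def trace_labels(ped, state: int):
    """Founder-allele labels per member by walking up the pedigree."""
    labels = {}

    def get(i):
        if i in labels:
            return labels[i]
        if i < ped.f:
            labels[i] = (2 * i, 2 * i + 1)
            return labels[i]
        t = i - ped.f
        pbit = (state >> (2 * t)) & 1
        mbit = (state >> (2 * t + 1)) & 1
        fa = get(int(ped.father_idx[i]))
        mo = get(int(ped.mother_idx[i]))
        labels[i] = (fa[pbit], mo[mbit])
        return labels[i]

    return [get(i) for i in range(ped.size)]


def iter_founder_configs(f: int):
    """Yield (hap alleles tuple of length 2f) over all 4^f configurations."""
    for hap in itertools.product((0, 1), repeat=2 * f):
        yield hap


def config_prior(hap, q: float) -> float:
    p = 1.0
    for a in hap:
        p *= q if a else (1 - q)
    return p


def member_genotypes(ped, state: int, hap) -> list[int]:
    lab = trace_labels(ped, state)
    return [hap[l0] + hap[l1] for l0, l1 in lab]


def emission_oracle(ped, state: int, L: np.ndarray, q: float) -> float:
    """Eq-1 style emission by full enumeration."""
    total = 0.0
    for hap in iter_founder_configs(ped.f):
        g = member_genotypes(ped, state, hap)
        like = config_prior(hap, q)
        for i, gi in enumerate(g):
            like *= L[i, gi]
        total += like
    return total


def poly_mono_oracle(ped, state: int, L: np.ndarray, q: float):
    """(P(R|I,poly), P(R|mono)) with the all-reference configuration
    excluded from the renormalized polymorphic founder prior."""
    num = 0.0
    norm = 0.0
    for hap in iter_founder_configs(ped.f):
        pr = config_prior(hap, q)
        if all(a == 0 for a in hap):
            continue
        norm += pr
        like = pr
        for i, gi in enumerate(member_genotypes(ped, state, hap)):
            like *= L[i, gi]
        num += like
    mono = float(np.prod(L[:, 0]))
    return num / norm, mono


def site_poly_posterior_oracle(ped, L, state_post, q, p_poly) -> float:
    total = 0.0
    for k, w in enumerate(state_post):
        if w == 0:
            continue
        poly, mono = poly_mono_oracle(ped, k, L, q)
        total += w * (poly * p_poly) / (poly * p_poly + mono * (1 - p_poly))
    return total


def genotype_posterior_oracle(ped, L, state_post, q) -> np.ndarray:
    """Per-member genotype posterior over {0,1,2}, averaging the per-state
    conditional posteriors under ``state_post`` (no truncation)."""
    out = np.zeros((ped.size, 3))
    for k, w in enumerate(state_post):
        if w == 0:
            continue
        mass = np.zeros((ped.size, 3))
        denom = 0.0
        for hap in iter_founder_configs(ped.f):
            like = config_prior(hap, q)
            g = member_genotypes(ped, k, hap)
            for i, gi in enumerate(g):
                like *= L[i, gi]
            denom += like
            for i, gi in enumerate(g):
                mass[i, gi] += like
        out += w * mass / denom
    return out


def haplotype_oracle(ped, L, state: int, q: float):
    """Argmax ordered genotype configuration given one inheritance vector."""
    best, best_p = None, -1.0
    for hap in iter_founder_configs(ped.f):
        like = config_prior(hap, q)
        for i, gi in enumerate(member_genotypes(ped, state, hap)):
            like *= L[i, gi]
        if like > best_p:
            best_p, best = like, hap
    lab = trace_labels(ped, state)
    return np.array([(best[l0], best[l1]) for l0, l1 in lab], dtype=np.int8)


# ---------------------------------------------------------------------- #
# chain oracles


def dense_fb_oracle(E: np.ndarray, thetas, nb: int):
    """Forward-backward with explicit dense transition matrices."""
    M, N = E.shape
    T = [
        np.array([[trans(a, b, t, nb) for b in range(N)] for a in range(N)])
        for t in thetas
    ]
    alpha = [E[0] / N]
    for j in range(1, M):
        alpha.append((alpha[-1] @ T[j - 1]) * E[j])
    beta = [np.ones(N)]
    for j in range(M - 2, -1, -1):
        beta.insert(0, T[j] @ (beta[0] * E[j + 1]))
    post = np.array([a * b for a, b in zip(alpha, beta)])
    ll = float(np.log(alpha[-1].sum()))
    return post / post.sum(axis=1, keepdims=True), ll


def path_sum_oracle(E: np.ndarray, thetas, nb: int) -> float:
    """Total likelihood by explicit summation over every state path."""
    M, N = E.shape
    total = 0.0
    for path in itertools.product(range(N), repeat=M):
        p = E[0][path[0]] / N
        for j in range(1, M):
            p *= trans(path[j - 1], path[j], thetas[j - 1], nb) * E[j][path[j]]
        total += p
    return total


def viterbi_oracle(E: np.ndarray, thetas, nb: int):
    """Best path by explicit enumeration (ties toward lexicographically
    smallest path, matching lowest-state-index tie-breaking)."""
    M, N = E.shape
    best, best_p = None, -1.0
    for path in itertools.product(range(N), repeat=M):
        p = E[0][path[0]] / N
        for j in range(1, M):
            p *= trans(path[j - 1], path[j], thetas[j - 1], nb) * E[j][path[j]]
        if p > best_p:
            best_p, best = p, path
    return np.array(best)


# ---------------------------------------------------------------------- #
# single-site trio calling with explicit Mendelian transmission


_TRANSMIT = {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}


def trio_single_site_oracle(L: np.ndarray, q: float) -> np.ndarray:
    """Posterior genotype distribution for (father, mother, child) from a
    single-site pedigree model: HWE parents, Mendelian transmission child."""
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    post = np.zeros((3, 3))  # member x genotype for parents, child separate
    out = np.zeros((3, 3))
    for gf in range(3):
        for gm in range(3):
            for af, pf in _TRANSMIT[gf].items():
                for am, pm in _TRANSMIT[gm].items():
                    gc = af + am
                    w = hwe[gf] * hwe[gm] * pf * pm
                    like = w * L[0, gf] * L[1, gm] * L[2, gc]
                    out[0, gf] += like
                    out[1, gm] += like
                    out[2, gc] += like
    return out / out.sum(axis=1, keepdims=True)
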