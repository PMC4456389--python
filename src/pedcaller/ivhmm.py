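"""Lander-Green HMM over inheritance vectors.

The emission probability at one site is a sum over the ``4**f`` ordered
founder genotype configurations: given an inheritance vector, non-founder
genotypes are fully determined by the founder configuration, so

    P(R_j | I_j) = sum_configs prod_{i=1..f+n} P(R_ij | G_ij) *
                   prod_founders P(G_ij),

with the founder prior taken as ordered Hardy-Weinberg probabilities from
the alternative allele frequency ``q``.  Emissions are constant within a
founder-symmetry class, so they are computed once per class representative
and broadcast.

Chain arithmetic runs in scaled linear space: the transition kernel is a
Kronecker product of 2x2 kernels ``[[1-t, t], [t, 1-t]]`` over the meiosis
bits, so multiplying a state vector by it costs ``O(N log N)`` (one pass per
bit axis) instead of ``O(N^2)``.  Viterbi uses the same factorization in the
max-plus semiring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import (
    FounderClasses,
    InheritanceVector,
    Pedigree,
    allele_labels_all,
    founder_symmetry_classes,
)

__all__ = [
    "EmissionEngine",
    "IVPath",
    "emission",
    "founder_prior",
    "forward_backward",
    "viterbi",
    "fast_transition_apply",
]

#: exact emission computation is refused beyond this many founder configs
MAX_FOUNDER_CONFIGS = 65536

#: likelihood floor guarding against zero-probability lockout
LIKELIHOOD_FLOOR = 1e-30


def founder_prior(q: float) -> np.ndarray:
    """Ordered founder genotype prior (R|R, R|A, A|R, A|A) under HWE."""
    p = 1.0 - q
    return np.array([p * p, p * q, q * p, q * q])


# ---------------------------------------------------------------------- #
# emission engine


class EmissionEngine:
    """Per-pedigree precomputation for fast per-site likelihood sums.

    The central object is the genotype tensor ``G`` of shape
    ``(n_configs, n_classes, size)``: for founder-haplotype configuration
    ``c`` (2f bits, one allele per founder haplotype) and class-representative
    state ``k``, the unordered genotype (alt-allele count 0/1/2) of each
    member.  Per site, with member likelihoods ``L`` of shape ``(size, 3)``,
    the product tensor ``W[c, k] = prod_i L[i, G[c, k, i]]`` yields every
    quantity the caller needs: emissions, the polymorphic/monomorphic split,
    the de-novo screen, and genotype posteriors.
    """

    def __init__(self, ped: Pedigree, max_bits: int = 16):
        self.ped = ped
        if 4**ped.f > MAX_FOUNDER_CONFIGS:
            raise ValueError(
                f"4^f = {4**ped.f} founder configurations exceeds the exact-"
                f"computation cap of {MAX_FOUNDER_CONFIGS}; pedigrees this "
                "large need Monte-Carlo likelihood methods"
            )
        self.classes: FounderClasses = founder_symmetry_classes(ped, max_bits)
        self.labels = allele_labels_all(ped)  # (N, m, 2)
        reps = self.classes.reps
        self.n_classes = len(reps)
        nhap = 2 * ped.f
        self.n_configs = 1 << nhap
        configs = np.arange(self.n_configs, dtype=np.int64)
        # hap_alleles[c, l] = allele (0/1) carried by founder haplotype l
        self.hap_alleles = (
            (configs[:, None] >> np.arange(nhap)[None, :]) & 1
        ).astype(np.int8)
        self.hap_alt_count = self.hap_alleles.sum(axis=1)  # (n_configs,)
        lab_rep = self.labels[reps]  # (C, m, 2)
        self.G = (
            self.hap_alleles[:, lab_rep[..., 0]] + self.hap_alleles[:, lab_rep[..., 1]]
        ).astype(np.int8)  # (n_configs, C, m)
        self.class_sizes = self.classes.sizes()
        # indicator matrix turning the per-member likelihood products into a
        # single GEMM: logW[b, ck] = loglik[b, (i,g)] @ ind[(i,g), ck]
        m = ped.size
        ind = np.zeros((m * 3, self.n_configs * self.n_classes))
        Gflat = self.G.reshape(self.n_configs * self.n_classes, m)
        for i in range(m):
            for g in range(3):
                ind[i * 3 + g, :] = Gflat[:, i] == g
        self._indicator = ind

    # ------------------------------------------------------------------ #
    def config_priors(self, q) -> np.ndarray:
        """HWE prior of each founder-haplotype configuration.

        ``q`` scalar -> shape ``(n_configs,)``; array of sites -> ``(S, n_configs)``.
        """
        q = np.asarray(q, dtype=np.float64)
        a = self.hap_alt_count.astype(np.float64)
        nhap = 2 * self.ped.f
        return q[..., None] ** a * (1.0 - q[..., None]) ** (nhap - a)

    def site_products(self, L: np.ndarray) -> np.ndarray:
        """``W[c, k] = prod_i L[i, G[c, k, i]]`` for one site; shape (n_configs, C)."""
        L = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
        W = np.ones((self.n_configs, self.n_classes), dtype=np.float64)
        for i in range(self.ped.size):
            W *= L[i, self.G[:, :, i]]
        return W

    def class_emission(self, L: np.ndarray, q: float) -> np.ndarray:
        """Emission per class representative (full HWE founder prior)."""
        W = self.site_products(L)
        return self.config_priors(float(q)) @ W

    def state_emission(self, L: np.ndarray, q: float) -> np.ndarray:
        """Emission broadcast to all ``2**(2n)`` states."""
        return self.class_emission(L, q)[self.classes.class_of]

    # ------------------------------------------------------------------ #
    def poly_mono_terms(
        self, L: np.ndarray, q: float, W: np.ndarray | None = None
    ) -> tuple[np.ndarray, float]:
        """Per class: P(R|I, poly) with the all-reference configuration
        excluded from the (renormalized) founder prior; scalar P(R|mono)."""
        if W is None:
            W = self.site_products(L)
        pri = self.config_priors(float(q))
        full = pri @ W
        p0 = pri[0]  # all-reference configuration prior (1-q)^(2f)
        poly = (full - p0 * W[0]) / max(1.0 - p0, LIKELIHOOD_FLOOR)
        Lf = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
        mono = float(np.prod(Lf[:, 0]))
        return poly, mono

    def genotype_terms(
        self, L: np.ndarray, q: float, class_sel: np.ndarray
    ) -> np.ndarray:
        """``P(G_i = g, R_j | I in class)`` for selected classes.

        Returns shape ``(size, 3, len(class_sel))``; unordered genotypes are
        constant within a symmetry class, so class-level terms are exact.
        """
        L = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
        pri = self.config_priors(float(q))
        Gsel = self.G[:, class_sel, :]  # (n_configs, K, m)
        W = np.ones(Gsel.shape[:2], dtype=np.float64)
        for i in range(self.ped.size):
            W *= L[i, Gsel[:, :, i]]
        A = pri[:, None] * W  # (n_configs, K)
        out = np.empty((self.ped.size, 3, len(class_sel)))
        for g in range(3):
            mask = Gsel == g  # (n_configs, K, m)
            out[:, g, :] = np.einsum("ck,ckm->mk", A, mask)
        return out

    # ------------------------------------------------------------------ #
    # batched variants (sites axis first); batch size is chosen so the
    # working tensor stays ~tens of MB

    def batch_size(self, budget_elems: int = 4_000_000) -> int:
        return max(1, budget_elems // (self.n_configs * self.n_classes))

    def site_products_batch(self, Lb: np.ndarray) -> np.ndarray:
        """``W[b, c, k]`` for a batch of sites; ``Lb``: (B, size, 3)."""
        return np.exp(self.log_site_products_batch(Lb)).reshape(
            -1, self.n_configs, self.n_classes
        )

    def log_site_products_batch(self, Lb: np.ndarray) -> np.ndarray:
        """``log W`` flattened over (config, class); shape (B, n_configs*C)."""
        Lb = np.maximum(np.asarray(Lb, dtype=np.float64), LIKELIHOOD_FLOOR)
        B = Lb.shape[0]
        logL = np.log(Lb).reshape(B, self.ped.size * 3)
        return logL @ self._indicator

    def emission_poly_mono_batch(
        self, Lb: np.ndarray, qb: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-class full-prior emission, poly-model emission and scalar mono
        likelihood for a batch of sites.  Shapes: (B, C), (B, C), (B,)."""
        W = self.site_products_batch(Lb)
        pri = self.config_priors(np.asarray(qb, dtype=np.float64))  # (B, n_configs)
        full = np.einsum("bc,bck->bk", pri, W)
        p0 = pri[:, 0:1]
        poly = (full - p0 * W[:, 0, :]) / np.maximum(1.0 - p0, LIKELIHOOD_FLOOR)
        Lf = np.maximum(np.asarray(Lb, dtype=np.float64), LIKELIHOOD_FLOOR)
        mono = np.prod(Lf[:, :, 0], axis=1)
        return full, poly, mono

    def denovo_lod_batch(self, Lb: np.ndarray) -> np.ndarray:
        """Mendelian-violation LOD per site of a batch (see scaffold module)."""
        Lf = np.maximum(np.asarray(Lb, dtype=np.float64), LIKELIHOOD_FLOOR)
        free = np.log10(Lf.max(axis=2)).sum(axis=1)
        logW = self.log_site_products_batch(Lb)
        mendel = logW.max(axis=1) / np.log(10.0)
        return np.maximum(free - mendel, 0.0)

    def class_posterior(self, state_posterior: np.ndarray) -> np.ndarray:
        """Aggregate a state-level posterior to class masses."""
        return np.bincount(
            self.classes.class_of, weights=state_posterior, minlength=self.n_classes
        )


def emission(
    ped: Pedigree,
    iv: InheritanceVector | int,
    L: np.ndarray,
    prior: np.ndarray | float,
) -> float:
    """Reference per-state emission (Eq-1 style sum over founder configs).

    ``prior`` is either the alt allele frequency ``q`` or a 4-vector of
    ordered founder genotype priors (R|R, R|A, A|R, A|A), applied i.i.d.
    across founders.
    """
    from .pedigree import allele_labels

    if np.ndim(prior) == 0:
        pri4 = founder_prior(float(prior))
    else:
        pri4 = np.asarray(prior, dtype=np.float64)
    lab = allele_labels(ped, int(iv))
    L = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
    f, m = ped.f, ped.size
    total = 0.0
    for c in range(4**f):
        hap = np.empty(2 * f, dtype=np.int64)
        pw = 1.0
        cc = c
        for i in range(f):
            og = cc % 4  # ordered genotype: bit0 paternal-slot, bit1 maternal-slot
            cc //= 4
            hap[2 * i] = og & 1
            hap[2 * i + 1] = (og >> 1) & 1
            pw *= pri4[og]
        like = 1.0
        for i in range(m):
            g = hap[lab[i, 0]] + hap[lab[i, 1]]
            like *= L[i, g]
        total += pw * like
    return float(total)


# ---------------------------------------------------------------------- #
# chain algorithms


def fast_transition_apply(vec: np.ndarray, theta: float) -> np.ndarray:
    """Multiply a state vector by the transition kernel in O(N log N).

    Applies the 2x2 kernel ``[[1-t, t], [t, 1-t]]`` along each meiosis-bit
    axis of the vector reshaped to ``(2,) * 2n``; identical to the dense
    matrix product.
    """
    vec = np.asarray(vec, dtype=np.float64)
    N = vec.shape[0]
    nb = int(N).bit_length() - 1
    if N != 1 << nb:
        raise ValueError("state vector length must be a power of two")
    t = float(theta)
    v = vec.reshape((2,) * nb)
    for ax in range(nb):
        a0 = np.take(v, 0, axis=ax)
        a1 = np.take(v, 1, axis=ax)
        v = np.stack(((1 - t) * a0 + t * a1, t * a0 + (1 - t) * a1), axis=ax)
    return v.reshape(N)


def _maxplus_transition_apply(logvec: np.ndarray, theta: float) -> np.ndarray:
    """Max-plus analogue of :func:`fast_transition_apply` for Viterbi."""
    N = logvec.shape[0]
    nb = int(N).bit_length() - 1
    with np.errstate(divide="ignore"):
        l1 = np.log(1.0 - theta)
        lt = np.log(theta)
    v = logvec.reshape((2,) * nb)
    for ax in range(nb):
        a0 = np.take(v, 0, axis=ax)
        a1 = np.take(v, 1, axis=ax)
        v = np.stack(
            (np.maximum(a0 + l1, a1 + lt), np.maximum(a0 + lt, a1 + l1)), axis=ax
        )
    return v.reshape(N)


@dataclass
class IVPath:
    """Viterbi path plus per-site marginal argmax states."""

    best: np.ndarray  # (M,) global optimal path
    marg: np.ndarray  # (M,) per-site argmax of the marginal posterior


def forward_backward(
    emissions: np.ndarray, thetas: np.ndarray
) -> tuple[np.ndarray, float]:
    """Marginal state posteriors and total data log-likelihood.

    ``emissions``: (M, N) per-site, per-state linear emissions.
    ``thetas``: (M-1,) recombination fractions between adjacent sites.
    The initial distribution is uniform; per-site rescaling keeps the
    arithmetic stable, with scales accumulated in log for the likelihood.
    """
    E = np.asarray(emissions, dtype=np.float64)
    M, N = E.shape
    thetas = np.asarray(thetas, dtype=np.float64)
    if thetas.shape[0] != M - 1:
        raise ValueError("need M-1 transition parameters for M sites")
    alpha = np.empty((M, N))
    log_scale = 0.0
    cur = E[0] / N
    s = cur.sum()
    if s <= 0:
        raise ValueError("all-zero emission vector at site 0")
    alpha[0] = cur / s
    log_scale += np.log(s)
    for j in range(1, M):
        cur = fast_transition_apply(alpha[j - 1], thetas[j - 1]) * E[j]
        s = cur.sum()
        if s <= 0:
            raise ValueError(f"all-zero emission vector at site {j}")
        alpha[j] = cur / s
        log_scale += np.log(s)
    beta = np.ones(N)
    post = np.empty((M, N))
    post[M - 1] = alpha[M - 1]
    for j in range(M - 2, -1, -1):
        beta = fast_transition_apply(beta * E[j + 1], thetas[j])
        beta /= beta.sum()
        p = alpha[j] * beta
        post[j] = p / p.sum()
    return post, float(log_scale)


def viterbi(emissions: np.ndarray, thetas: np.ndarray) -> IVPath:
    """Global max-probability path; ties break toward the lowest state index.

    The per-site marginal argmax track is computed from
    :func:`forward_backward` on the same inputs.
    """
    E = np.asarray(emissions, dtype=np.float64)
    M, N = E.shape
    nb = int(N).bit_length() - 1
    thetas = np.asarray(thetas, dtype=np.float64)
    with np.errstate(divide="ignore"):
        logE = np.log(E)
    delta = np.empty((M, N))
    delta[0] = logE[0] - np.log(N)
    for j in range(1, M):
        delta[j] = _maxplus_transition_apply(delta[j - 1], thetas[j - 1]) + logE[j]
    best = np.empty(M, dtype=np.int64)
    best[M - 1] = int(np.argmax(delta[M - 1]))
    states = np.arange(N, dtype=np.int64)
    for j in range(M - 2, -1, -1):
        t = thetas[j]
        with np.errstate(divide="ignore"):
            l1, lt = np.log(1.0 - t), np.log(t)
        h = np.bitwise_count(states ^ best[j + 1]).astype(np.float64)
        with np.errstate(invalid="ignore"):
            cost = h * lt  # 0 * -inf at theta=0 means "no recombination": 0
        cost[h == 0] = 0.0
        score = delta[j] + cost + (nb - h) * l1
        best[j] = int(np.argmax(score))
    post, _ = forward_backward(E, thetas)
    marg = np.argmax(post, axis=1).astype(np.int64)
    return IVPath(best=best, marg=marg)
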