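"""Variant-site quality, genotype refinement and haplotype reconstruction.

Given the inheritance-vector posterior from the scaffold HMM, every
candidate site is scored and called:

* variant quality: Bayes factor of "polymorphic" (HWE founder prior with the
  all-reference configuration excluded and renormalized) against
  "monomorphic" (everyone homozygous reference), with a coalescent prior
  ``P(poly) = theta_mut * sum_{i=1..2f} 1/i``, averaged over the
  inheritance-vector posterior; ``VQ = -10 log10(1 - P(poly | data))``.
* non-scaffold sites sit in an interval between two scaffold sites; both
  flanking posteriors are evaluated and the side with the larger
  polymorphism posterior is chosen (at most one crossover per interval), so
  crossover breakpoints are localized to the interval where the chosen side
  switches.
* genotype posteriors: per inheritance vector, the probability mass of the
  founder configurations yielding each genotype, normalized by the emission
  and averaged over the (optionally truncated) posterior;
  ``GQ = -10 log10(1 - P_max)``.
* haplotypes (when a sequenced parent exists): the ordered founder
  configuration maximizing the posterior given the Viterbi-best inheritance
  vector fixes ordered genotypes for everyone, making Mendelian violations
  impossible by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, recomb_fraction
from .ivhmm import (
    LIKELIHOOD_FLOOR,
    EmissionEngine,
    IVPath,
    forward_backward,
    viterbi,
)
from .pedigree import Pedigree, allele_labels
from .scaffold import ScaffoldConfig, ScaffoldResult, select_scaffold

logger = logging.getLogger(__name__)

__all__ = [
    "PolyPrior",
    "CallerConfig",
    "FamilyCalls",
    "poly_prior",
    "site_poly_posterior",
    "genotype_posteriors",
    "call_haplotypes",
    "assign_interval_ivs",
    "call_family",
    "call_cohort",
    "estimate_af",
    "PhasingUnsupported",
]

PHRED_CAP = 255.0


class PhasingUnsupported(ValueError):
    """Haplotype mode requested for a pedigree without sequenced parents."""


@dataclass(frozen=True)
class PolyPrior:
    """Coalescent prior of polymorphism: theta * harmonic(2 * n_founders)."""

    p_poly: float
    theta_mut: float
    n_founders: int


def poly_prior(n_founders: int, theta_mut: float = 1e-3) -> PolyPrior:
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    p = theta_mut * sum(1.0 / i for i in range(1, 2 * n_founders + 1))
    if not 0 < p < 1:
        raise ValueError(f"degenerate polymorphism prior {p}")
    return PolyPrior(p_poly=p, theta_mut=theta_mut, n_founders=n_founders)


def estimate_af(
    L: np.ndarray, max_iter: int = 50, tol: float = 1e-6
) -> np.ndarray:
    """EM estimate of the alt allele frequency per site under HWE.

    ``L``: (samples, sites, 3) linear likelihoods of the samples used as the
    frequency panel (sequenced founders when available, otherwise all
    sequenced members treated as unrelated -- an approximation noted in the
    docs).  Returns per-site q clipped to [1e-4, 0.9999].
    """
    Lf = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
    nsamp = Lf.shape[0]
    q = np.full(Lf.shape[1], 0.1)
    g = np.arange(3.0)
    for _ in range(max_iter):
        pri = np.stack(
            [(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1
        )  # (S, 3)
        post = Lf * pri[None, :, :]
        post /= post.sum(axis=2, keepdims=True)
        q_new = (post @ g).sum(axis=0) / (2 * nsamp)
        q_new = np.clip(q_new, 1e-4, 0.9999)
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    return q


def _phred(p_err: np.ndarray | float) -> np.ndarray | float:
    with np.errstate(divide="ignore"):
        v = -10.0 * np.log10(np.maximum(p_err, 10 ** (-PHRED_CAP / 10.0)))
    return np.minimum(v, PHRED_CAP)


@dataclass
class CallerConfig:
    """Calling options; defaults mirror the documented design choices."""

    theta_mut: float = 1e-3
    truncation: float | str = 0.99  # cumulative-mass cutoff, or "best"
    phase: bool = False
    scaffold: ScaffoldConfig = field(default_factory=ScaffoldConfig)


# ---------------------------------------------------------------------- #
# single-site operations (class-level posteriors)


def site_poly_posterior(
    engine: EmissionEngine,
    L: np.ndarray,
    class_post,
    prior: PolyPrior,
    q: float,
) -> tuple[float, float, str]:
    """Polymorphism posterior and VQ for one site.

    ``class_post`` is either one class-mass vector (scaffold site) or a
    ``(left, right)`` pair of them (interval site); for a pair the maximum of
    the two posteriors is taken and the winning side reported.
    """
    poly, mono = engine.poly_mono_terms(L, q)
    pp = prior.p_poly
    bayes = poly * pp / np.maximum(poly * pp + mono * (1 - pp), LIKELIHOOD_FLOOR)
    if isinstance(class_post, tuple):
        left, right = class_post
        p_left = float(left @ bayes)
        p_right = float(right @ bayes)
        if p_left >= p_right:
            p, side = p_left, "left"
        else:
            p, side = p_right, "right"
    else:
        p, side = float(np.asarray(class_post) @ bayes), "self"
    p = min(max(p, 0.0), 1.0)
    return p, float(_phred(1.0 - p)), side


def _truncate(class_post: np.ndarray, truncation: float | str) -> np.ndarray:
    """Renormalized posterior keeping the top classes with cumulative mass
    >= the cutoff (or the single best class)."""
    post = np.asarray(class_post, dtype=np.float64)
    if truncation == "best":
        out = np.zeros_like(post)
        out[int(np.argmax(post))] = 1.0
        return out
    c = float(truncation)
    if not 0 < c <= 1:
        raise ValueError("truncation cutoff must be in (0, 1] or 'best'")
    order = np.argsort(post)[::-1]
    cum = np.cumsum(post[order])
    k = int(np.searchsorted(cum, c * post.sum() - 1e-15)) + 1
    out = np.zeros_like(post)
    sel = order[:k]
    out[sel] = post[sel]
    s = out.sum()
    return out / s if s > 0 else np.full_like(post, 1.0 / len(post))


def genotype_posteriors(
    engine: EmissionEngine,
    L: np.ndarray,
    class_post: np.ndarray,
    q: float,
    truncation: float | str = 0.99,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-member genotype posteriors over {RR, RA, AA} for one site.

    Returns ``(posterior (size, 3), calls (size,), gq (size,))``; ties in the
    argmax break toward RR < RA < AA.
    """
    w = _truncate(class_post, truncation)
    sel = np.flatnonzero(w > 0)
    terms = engine.genotype_terms(L, q, sel)  # (size, 3, K)
    denom = np.maximum(terms.sum(axis=1), LIKELIHOOD_FLOOR)  # (size, K) = P(R|I)
    post = np.einsum("mgk,k->mg", terms / denom[:, None, :], w[sel])
    post /= np.maximum(post.sum(axis=1, keepdims=True), LIKELIHOOD_FLOOR)
    calls = np.argmax(post, axis=1).astype(np.int8)
    gq = np.asarray(_phred(1.0 - post.max(axis=1)))
    return post, calls, gq


def call_haplotypes(
    engine: EmissionEngine,
    L: np.ndarray,
    best_state: int,
    q: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-posterior ordered genotypes for one site given the best
    inheritance vector.

    Returns ``(ordered (size, 2) paternal/maternal alt alleles, gq (size,))``
    with GQ from each member's marginal ordered-genotype posterior.  Requires
    at least one sequenced parent in the pedigree (phase is meaningless for
    pure unsequenced-parent sibships).
    """
    ped = engine.ped
    if not ped.has_parent_offspring_link():
        raise PhasingUnsupported(
            "haplotypes cannot be reconstructed without sequenced parental "
            "data (pure sibship); run in unphased mode"
        )
    lab = allele_labels(ped, int(best_state))  # (size, 2)
    hap = engine.hap_alleles  # (n_configs, 2f)
    G = hap[:, lab[:, 0]] + hap[:, lab[:, 1]]  # (n_configs, size)
    Lf = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
    W = np.ones(engine.n_configs, dtype=np.float64)
    for i in range(ped.size):
        W *= Lf[i, G[:, i]]
    A = engine.config_priors(float(q)) * W
    A /= max(A.sum(), LIKELIHOOD_FLOOR)
    c_star = int(np.argmax(A))
    ordered = np.stack(
        (hap[c_star, lab[:, 0]], hap[c_star, lab[:, 1]]), axis=1
    ).astype(np.int8)
    # marginal posterior of each member's ordered genotype
    og = hap[:, lab[:, 0]] + 2 * hap[:, lab[:, 1]]  # (n_configs, size) in 0..3
    marg = np.zeros((ped.size, 4))
    for v in range(4):
        marg[:, v] = A @ (og == v)
    gq = np.asarray(_phred(1.0 - marg.max(axis=1)))
    return ordered, gq


# ---------------------------------------------------------------------- #
# interval assignment and the family pipeline


@dataclass
class IntervalAssignment:
    """Flanking-scaffold bookkeeping for every site.

    ``left``/``right`` hold, per site, the index into the scaffold-site list
    of the flanking scaffold variant (-1 when absent on that side);
    ``chosen_side`` is filled after the polymorphism posteriors are compared.
    """

    left: np.ndarray
    right: np.ndarray
    chosen_side: np.ndarray  # 0 left, 1 right, 2 self(scaffold)


def assign_interval_ivs(
    positions: np.ndarray, scaffold_idx: np.ndarray
) -> IntervalAssignment:
    """Map every site to its flanking scaffold sites (by scaffold-list index)."""
    pos = np.asarray(positions)
    spos = pos[scaffold_idx]
    right = np.searchsorted(spos, pos, side="left")
    left = np.searchsorted(spos, pos, side="right") - 1
    right[right >= len(spos)] = -1
    chosen = np.full(len(pos), -1, dtype=np.int8)
    is_scaffold = np.zeros(len(pos), dtype=bool)
    is_scaffold[scaffold_idx] = True
    chosen[is_scaffold] = 2
    return IntervalAssignment(left=left, right=right, chosen_side=chosen)


@dataclass
class FamilyCalls:
    """Arrays of calls for one family across the site grid."""

    ped: Pedigree
    positions: np.ndarray
    q: np.ndarray
    vq: np.ndarray  # (S,)
    genotypes: np.ndarray  # (size, S) int8 in {0,1,2}
    gq: np.ndarray  # (size, S)
    scaffold_mask: np.ndarray  # (S,) bool
    chosen_side: np.ndarray  # (S,) 0/1/2
    best_state: np.ndarray  # (S,) Viterbi-derived state per site
    loglik: float
    phased: bool = False
    haplotypes: np.ndarray | None = None  # (size, 2, S) int8 when phased
    phased_gq: np.ndarray | None = None  # (size, S)

    def ibd_track(self, a: str, b: str) -> np.ndarray:
        from .pedigree import ibd_track

        return ibd_track(self.ped, self.best_state, a, b)


def _chain(
    engine: EmissionEngine,
    L: np.ndarray,
    q: np.ndarray,
    positions: np.ndarray,
    gmap: GeneticMap,
) -> tuple[np.ndarray, IVPath, float]:
    """Run the HMM on scaffold sites; returns class-level posteriors
    ``(M, C)``, the Viterbi/marginal path, and the total log-likelihood."""
    M = len(positions)
    C = engine.n_classes
    emis_cls = np.empty((M, C))
    bs = engine.batch_size()
    Lsites = np.transpose(L, (1, 0, 2))  # (M, size, 3)
    for s in range(0, M, bs):
        full, _poly, _mono = engine.emission_poly_mono_batch(
            Lsites[s : s + bs], q[s : s + bs]
        )
        emis_cls[s : s + bs] = full
    emis = emis_cls[:, engine.classes.class_of]  # broadcast to states
    thetas = recomb_fraction(gmap.distances_cm(positions.astype(np.float64)))
    post, loglik = forward_backward(emis, np.atleast_1d(thetas))
    path = viterbi(emis, np.atleast_1d(thetas))
    cls_post = np.empty((M, C))
    for j in range(M):
        cls_post[j] = engine.class_posterior(post[j])
    return cls_post, path, loglik


def call_family(
    ped: Pedigree,
    positions: np.ndarray,
    q: np.ndarray,
    L: np.ndarray,
    gmap: GeneticMap,
    scaffold_mask: np.ndarray,
    config: CallerConfig | None = None,
    engine: EmissionEngine | None = None,
) -> FamilyCalls:
    """Score and call every site for one family.

    ``L``: (size, S, 3) linear likelihoods; ``scaffold_mask``: (S,) bool.
    """
    config = config or CallerConfig()
    engine = engine or EmissionEngine(ped)
    S = len(positions)
    C = engine.n_classes
    prior = poly_prior(ped.f, config.theta_mut)

    scaffold_idx = np.flatnonzero(scaffold_mask)
    if len(scaffold_idx) == 0:
        warnings.warn(
            "no scaffold sites selected; falling back to a uniform "
            "inheritance-vector distribution at every site"
        )
        cls_post = np.empty((0, C))
        path = IVPath(best=np.empty(0, dtype=np.int64), marg=np.empty(0, dtype=np.int64))
        loglik = 0.0
    else:
        cls_post, path, loglik = _chain(
            engine,
            L[:, scaffold_idx, :],
            q[scaffold_idx],
            positions[scaffold_idx],
            gmap,
        )

    iv_assign = assign_interval_ivs(positions, scaffold_idx)
    class_sizes = engine.class_sizes.astype(np.float64)
    uniform_cls = class_sizes / class_sizes.sum()

    # batched poly/mono over all sites
    bs = engine.batch_size()
    Lsites = np.transpose(L, (1, 0, 2))
    bayes = np.empty((S, C))
    pp = prior.p_poly
    for s in range(0, S, bs):
        _full, poly, mono = engine.emission_poly_mono_batch(
            Lsites[s : s + bs], q[s : s + bs]
        )
        num = poly * pp
        bayes[s : s + bs] = num / np.maximum(
            num + mono[:, None] * (1 - pp), LIKELIHOOD_FLOOR
        )

    def _post_row(scaffold_j: int) -> np.ndarray:
        return cls_post[scaffold_j] if scaffold_j >= 0 else uniform_cls

    p_poly_site = np.empty(S)
    chosen_rows = np.empty((S, C))
    chosen_state = np.empty(S, dtype=np.int64)
    side = iv_assign.chosen_side
    own = np.searchsorted(scaffold_idx, np.arange(S))  # scaffold-list index
    for j in range(S):
        if side[j] == 2:
            row = cls_post[own[j]]
            p_poly_site[j] = float(row @ bayes[j])
            chosen_rows[j] = row
            chosen_state[j] = path.best[own[j]]
        else:
            lf, rf = iv_assign.left[j], iv_assign.right[j]
            if lf < 0 and rf < 0:
                row_l = row_r = uniform_cls
            else:
                row_l = _post_row(lf)
                row_r = _post_row(rf)
            p_l = float(row_l @ bayes[j])
            p_r = float(row_r @ bayes[j])
            if p_l >= p_r:
                p_poly_site[j] = p_l
                chosen_rows[j] = row_l
                side[j] = 0
                chosen_state[j] = path.best[lf] if lf >= 0 else 0
            else:
                p_poly_site[j] = p_r
                chosen_rows[j] = row_r
                side[j] = 1
                chosen_state[j] = path.best[rf] if rf >= 0 else 0
    vq = np.asarray(_phred(1.0 - np.clip(p_poly_site, 0.0, 1.0)))

    genotypes = np.empty((ped.size, S), dtype=np.int8)
    gq = np.empty((ped.size, S))
    for j in range(S):
        _post, genotypes[:, j], gq[:, j] = genotype_posteriors(
            engine, L[:, j, :], chosen_rows[j], float(q[j]), config.truncation
        )

    calls = FamilyCalls(
        ped=ped,
        positions=positions,
        q=q,
        vq=vq,
        genotypes=genotypes,
        gq=gq,
        scaffold_mask=scaffold_mask,
        chosen_side=side,
        best_state=chosen_state,
        loglik=loglik,
    )

    if config.phase:
        if not ped.has_parent_offspring_link():
            raise PhasingUnsupported(
                "--phase requested but the pedigree has no sequenced parents "
                "(sibship-only): haplotypes cannot be reconstructed"
            )
        hap = np.empty((ped.size, 2, S), dtype=np.int8)
        pgq = np.empty((ped.size, S))
        for j in range(S):
            ordered, g = call_haplotypes(engine, L[:, j, :], int(chosen_state[j]), float(q[j]))
            hap[:, 0, j] = ordered[:, 0]
            hap[:, 1, j] = ordered[:, 1]
            pgq[:, j] = g
        calls.phased = True
        calls.haplotypes = hap
        calls.phased_gq = pgq
        calls.genotypes = hap.sum(axis=1).astype(np.int8)
        calls.gq = pgq
    return calls


def call_cohort(
    peds: list[Pedigree],
    positions: np.ndarray,
    q: np.ndarray,
    likelihoods: list[np.ndarray],
    gmap: GeneticMap,
    config: CallerConfig | None = None,
    regions: list[tuple[int, int]] | None = None,
    indels: np.ndarray | None = None,
) -> tuple[list[FamilyCalls], ScaffoldResult]:
    """Scaffold selection over the cohort, then per-family calling."""
    config = config or CallerConfig()
    engines = [EmissionEngine(p) for p in peds]
    q = np.asarray(q, dtype=np.float64).copy()
    missing = ~np.isfinite(q)
    if missing.any():
        panels = []
        for ped, L in zip(peds, likelihoods):
            fmask = ped.sequenced.copy()
            fmask[ped.f :] = False
            mask = fmask if fmask.any() else ped.sequenced
            if mask.any():
                panels.append(L[mask][:, missing, :])
        if panels:
            q[missing] = estimate_af(np.concatenate(panels, axis=0))
        else:
            q[missing] = 0.01
    mean_f = float(np.mean([p.f for p in peds]))
    prior = poly_prior(max(int(round(mean_f)), 1), config.theta_mut)
    sel = select_scaffold(
        engines,
        likelihoods,
        positions,
        q,
        config.scaffold,
        regions=regions,
        indels=indels,
        p_poly=prior.p_poly,
    )
    logger.info("scaffold selection counts: %s", sel.counts)
    out = []
    for ped, L, eng in zip(peds, likelihoods, engines):
        out.append(
            call_family(ped, positions, q, L, gmap, sel.mask, config, engine=eng)
        )
    return out, sel
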