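"""Selection of scaffold variants for inheritance-vector inference.

The HMM needs a sparse set of confidently polymorphic, mutually independent
sites located outside alignment-artifact-prone regions.  Selection proceeds
as: (1) drop sites in excluded regions or within a pad of known indels,
(2) prescreen for polymorphism evidence, (3) screen out sites whose
likelihoods strongly violate Mendelian transmission (putative de-novo or
artifact sites), (4) greedy LD pruning on posterior-mean dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ivhmm import EmissionEngine, LIKELIHOOD_FLOOR

__all__ = [
    "ScaffoldConfig",
    "exclude_by_region",
    "ld_prune",
    "denovo_screen",
    "dosage_matrix",
    "select_scaffold",
]


@dataclass
class ScaffoldConfig:
    r2_max: float = 0.2
    window: int = 100  # trailing window, in variant count
    indel_pad: int = 50  # bp around known indels
    min_vq_prescreen: float = 20.0  # phred evidence of polymorphism
    denovo_lod_max: float = 3.0  # log10 Mendelian-violation cap
    min_ld_panel: int = 20  # dosage samples below which r^2 is too noisy to prune on
    min_spacing_bp: int = 0  # optional physical-spacing fallback/extra

    def __post_init__(self) -> None:
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")
        if self.indel_pad < 0:
            raise ValueError("indel_pad must be non-negative")


def exclude_by_region(
    positions: np.ndarray,
    regions: list[tuple[int, int]] | None = None,
    indels: np.ndarray | list[int] | None = None,
    pad: int = 50,
) -> np.ndarray:
    """Boolean keep-mask: False inside a 0-based half-open excluded region or
    within ``pad`` bp of a listed indel position."""
    pos = np.asarray(positions, dtype=np.int64)
    keep = np.ones(pos.shape, dtype=bool)
    if regions:
        for start, end in regions:
            keep &= ~((pos - 1 >= start) & (pos - 1 < end))
    if indels is not None and len(indels):
        ind = np.sort(np.asarray(indels, dtype=np.int64))
        idx = np.searchsorted(ind, pos)
        near = np.zeros_like(keep)
        left_ok = idx > 0
        near[left_ok] |= pos[left_ok] - ind[idx[left_ok] - 1] <= pad
        right_ok = idx < len(ind)
        near[right_ok] |= ind[idx[right_ok]] - pos[right_ok] <= pad
        keep &= ~near
    return keep


def dosage_matrix(L: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Posterior-mean alt-allele dosage per sample per site under HWE.

    ``L``: (samples, sites, 3) linear likelihoods; ``q``: (sites,).
    """
    q = np.asarray(q, dtype=np.float64)
    pri = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)  # (S, 3)
    post = np.maximum(L, LIKELIHOOD_FLOOR) * pri[None, :, :]
    post /= post.sum(axis=2, keepdims=True)
    return post[:, :, 1] + 2 * post[:, :, 2]


def ld_prune(
    dosages: np.ndarray,
    r2_max: float = 0.2,
    window: int = 100,
) -> np.ndarray:
    """Greedy left-to-right pruning on squared Pearson correlation.

    ``dosages``: (samples, sites).  A site is kept iff its r^2 with every
    already-kept site in the trailing ``window`` kept-sites is <= ``r2_max``.
    Zero-variance sites correlate with nothing and are kept.
    Returns a boolean keep-mask over sites.

    With a small dosage panel the sample r^2 of truly independent sites is
    noisy (null mean 1/(n-1)), so the effective threshold is raised to the
    two-sided 1e-4 null quantile of r^2 (Fisher z) when that exceeds
    ``r2_max``: only correlations distinguishable from sampling noise prune.
    """
    D = np.asarray(dosages, dtype=np.float64)
    nsamp, S = D.shape
    if nsamp > 3:
        z_crit = 3.89  # two-sided 1e-4 normal quantile
        r_sig = np.tanh(z_crit / np.sqrt(nsamp - 3))
        r2_max = max(r2_max, r_sig * r_sig)
    Dc = D - D.mean(axis=0, keepdims=True)
    norm = np.sqrt((Dc**2).sum(axis=0))
    keep = np.zeros(S, dtype=bool)
    kept_idx: list[int] = []
    for j in range(S):
        ok = True
        if norm[j] > 0:
            for i in kept_idx[-window:]:
                if norm[i] == 0:
                    continue
                r = float(Dc[:, i] @ Dc[:, j]) / (norm[i] * norm[j])
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            keep[j] = True
            kept_idx.append(j)
    return keep


def spacing_prune(positions: np.ndarray, min_spacing_bp: int) -> np.ndarray:
    """Keep-mask enforcing a minimum physical spacing (greedy left-to-right)."""
    pos = np.asarray(positions, dtype=np.int64)
    keep = np.zeros(pos.shape, dtype=bool)
    last = -np.inf
    for j, p in enumerate(pos):
        if p - last >= min_spacing_bp:
            keep[j] = True
            last = p
    return keep


def denovo_screen(
    engine: EmissionEngine, L: np.ndarray, W: np.ndarray | None = None
) -> float:
    """Mendelian-violation LOD for one site.

    log10 of the best unconstrained genotype likelihood minus log10 of the
    best Mendelian-consistent likelihood (max over inheritance vectors and
    founder configurations of the product of member likelihoods, no priors).
    Non-negative; large values flag sites incompatible with transmission.
    """
    Lf = np.maximum(np.asarray(L, dtype=np.float64), LIKELIHOOD_FLOOR)
    free = float(np.sum(np.log10(Lf.max(axis=1))))
    if W is None:
        W = engine.site_products(L)
    mendel = float(np.log10(W.max()))
    return max(free - mendel, 0.0)


def _poly_prescreen_phred(L: np.ndarray, q: np.ndarray, p_poly: float) -> np.ndarray:
    """Cheap per-site polymorphism evidence treating sequenced samples as
    unrelated under HWE; used only to rank scaffold candidates."""
    q = np.asarray(q, dtype=np.float64)
    pri = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)
    Lf = np.maximum(L, LIKELIHOOD_FLOOR)
    per = (Lf * pri[None, :, :]).sum(axis=2)  # (samples, sites)
    with np.errstate(divide="ignore"):
        log_any = np.log(per).sum(axis=0)
        log_mono = np.log(Lf[:, :, 0]).sum(axis=0)
    # crude Bayes factor of "some non-reference configuration" vs mono
    log_bf = log_any - log_mono
    post = 1.0 / (1.0 + np.exp(-(log_bf + np.log(p_poly / (1 - p_poly)))))
    post = np.clip(post, 0.0, 1.0 - 1e-12)
    return -10.0 * np.log10(1.0 - post)


@dataclass
class ScaffoldResult:
    mask: np.ndarray  # keep-mask over the input sites
    counts: dict = field(default_factory=dict)  # per-stage kept counts


def select_scaffold(
    ped_engines: list[EmissionEngine],
    likelihoods: list[np.ndarray],
    positions: np.ndarray,
    q: np.ndarray,
    cfg: ScaffoldConfig | None = None,
    regions: list[tuple[int, int]] | None = None,
    indels: np.ndarray | None = None,
    p_poly: float = 0.005,
) -> ScaffoldResult:
    """Full scaffold selection over a cohort sharing one site grid.

    ``ped_engines`` / ``likelihoods`` are parallel per-family lists; the
    de-novo screen drops a site if any family strongly violates transmission,
    and LD dosages pool sequenced founders (falling back to all sequenced
    members) across families.
    """
    cfg = cfg or ScaffoldConfig()
    S = len(positions)
    counts: dict[str, int] = {"input": S}

    keep = exclude_by_region(positions, regions, indels, cfg.indel_pad)
    counts["after_region_exclusion"] = int(keep.sum())

    # polymorphism prescreen on pooled sequenced samples
    pooled = np.concatenate(
        [L[e.ped.sequenced] for e, L in zip(ped_engines, likelihoods)], axis=0
    )
    vq = _poly_prescreen_phred(pooled, q, p_poly)
    keep &= vq >= cfg.min_vq_prescreen
    counts["after_poly_prescreen"] = int(keep.sum())

    # de-novo / Mendelian-violation screen (drop if any family violates)
    idx = np.flatnonzero(keep)
    for e, L in zip(ped_engines, likelihoods):
        if not len(idx):
            break
        bs = e.batch_size()
        lods = np.empty(len(idx))
        Lsites = np.transpose(L[:, idx, :], (1, 0, 2))  # (S_kept, size, 3)
        for s in range(0, len(idx), bs):
            lods[s : s + bs] = e.denovo_lod_batch(Lsites[s : s + bs])
        bad = lods > cfg.denovo_lod_max
        if bad.any():
            keep[idx[bad]] = False
            idx = np.flatnonzero(keep)
    counts["after_denovo_screen"] = int(keep.sum())

    # LD pruning on pooled dosages
    founders, members = [], []
    for e, L in zip(ped_engines, likelihoods):
        seq = e.ped.sequenced
        fmask = seq.copy()
        fmask[e.ped.f :] = False
        if fmask.any():
            founders.append(L[fmask])
        if seq.any():
            members.append(L[seq])
    fpanel = np.concatenate(founders, axis=0) if founders else np.empty((0, S, 3))
    mpanel = np.concatenate(members, axis=0) if members else np.empty((0, S, 3))
    panel = fpanel if fpanel.shape[0] >= cfg.min_ld_panel else mpanel
    idx = np.flatnonzero(keep)
    if panel.shape[0] >= cfg.min_ld_panel and len(idx):
        dos = dosage_matrix(panel[:, idx, :], q[idx])
        keep_ld = ld_prune(dos, cfg.r2_max, cfg.window)
        keep[idx[~keep_ld]] = False
    elif cfg.min_spacing_bp > 0 and len(idx):
        keep[idx[~spacing_prune(positions[idx], cfg.min_spacing_bp)]] = False
    counts["after_ld_prune"] = int(keep.sum())
    return ScaffoldResult(mask=keep, counts=counts)
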