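"""End-to-end benchmark runs: simulate a cohort, call it, score it.

These runners tie the simulator, the calling pipeline and the metrics
together and are what the evaluation scripts and the acceptance checks
execute.  Truth and calls are compared over sequenced members only:
sibship structures carry unsequenced founder parents whose genotypes are
only partially identifiable and are not part of the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caller import CallerConfig, FamilyCalls, call_cohort
from .evaluate import MetricsReport, fnr_fdr, ibd_concordance, mendelian_inconsistency
from .simulate import SimConfig, SimTruth, simulate_cohort

__all__ = ["BenchmarkResult", "run_benchmark", "ibd_benchmark"]


@dataclass
class BenchmarkResult:
    config: SimConfig
    overall: MetricsReport
    het: MetricsReport
    mi_rate: float  # % over trios, min-GQ filtered; NaN without trios
    n_scaffold: int
    calls: list[FamilyCalls] = field(default_factory=list)
    truths: list[SimTruth] = field(default_factory=list)


def _stack(
    truths: list[SimTruth], calls: list[FamilyCalls]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate (truth, call, gq, site-frequency) tables over families,
    masking unsequenced members with truth = -1."""
    T, C, G, F = [], [], [], []
    for truth, fc in zip(truths, calls):
        t = truth.genotypes.astype(np.int64).copy()
        t[~truth.ped.sequenced, :] = -1
        T.append(t)
        C.append(fc.genotypes.astype(np.int64))
        G.append(fc.gq)
        F.append(np.broadcast_to(truth.q, t.shape))
    return (
        np.concatenate(T, axis=0),
        np.concatenate(C, axis=0),
        np.concatenate(G, axis=0),
        np.concatenate(F, axis=0),
    )


def run_benchmark(
    structure: str,
    coverage: float,
    seed: int,
    n_families: int = 20,
    n_sites: int = 5000,
    chrom_length_bp: int = 100_000_000,
    phased: bool = False,
    gq_min: float = 3.0,
    keep_calls: bool = False,
    caller_config: CallerConfig | None = None,
) -> BenchmarkResult:
    """Simulate ``n_families`` pedigrees of one structure at one coverage,
    run the full scaffold + HMM + calling pipeline, and score against truth
    at the given GQ filter."""
    cfg = SimConfig(
        structure=structure,
        n_families=n_families,
        n_sites=n_sites,
        coverage=coverage,
        chrom_length_bp=chrom_length_bp,
    )
    positions, q, fams = simulate_cohort(cfg, seed)
    truths = [t for t, _ in fams]
    likes = [L for _, L in fams]
    peds = [t.ped for t in truths]
    ccfg = caller_config or CallerConfig()
    ccfg.phase = phased
    calls, sel = call_cohort(peds, positions, q, likes, cfg.genetic_map(), ccfg)
    T, C, G, F = _stack(truths, calls)
    overall = fnr_fdr(T, C, G, gq_min=gq_min, het_only=False, freq=F)
    het = fnr_fdr(T, C, G, gq_min=gq_min, het_only=True, freq=F)
    mis = [
        mendelian_inconsistency(fc.genotypes, fc.gq, fc.ped, gq_min=gq_min)
        for fc in calls
    ]
    mis = [m for m in mis if np.isfinite(m)]
    mi = float(np.mean(mis)) if mis else float("nan")
    return BenchmarkResult(
        config=cfg,
        overall=overall,
        het=het,
        mi_rate=mi,
        n_scaffold=int(sel.mask.sum()),
        calls=calls if keep_calls else [],
        truths=truths if keep_calls else [],
    )


def ibd_benchmark(
    structure: str,
    coverage: float,
    seed: int,
    pair: tuple[str, str] = ("C1", "C2"),
    n_families: int = 20,
    n_sites: int = 4000,
    chrom_length_bp: int = 25_000_000,
    min_scaffold: int = 1000,
) -> tuple[float, int]:
    """Sib-pair IBD concordance between the Viterbi-inferred and true
    inheritance vectors over the scaffold sites, averaged across the
    families of a simulated cohort (scaffold sites are discovered from the
    pooled cohort, as in a real multi-family VCF).  The default site grid is
    denser (bp per site) than the genotype-accuracy benchmarks because
    crossover localization error is measured in scaffold sites: whole-genome
    data after pruning is far denser per cM than a desk-scale grid, and a
    25 Mb region at 4000 sites approximates that regime.

    Returns ``(mean concordance, n_scaffold_sites)``; ``n_sites`` should be
    large enough that at least ``min_scaffold`` scaffold sites survive.
    """
    res = run_benchmark(
        structure,
        coverage,
        seed,
        n_families=n_families,
        n_sites=n_sites,
        chrom_length_bp=chrom_length_bp,
        keep_calls=True,
    )
    idx = np.flatnonzero(res.calls[0].scaffold_mask)
    if len(idx) < min_scaffold:
        raise RuntimeError(
            f"only {len(idx)} scaffold sites survived selection; "
            "increase n_sites"
        )
    a, b = pair
    concs = [
        ibd_concordance(truth.ibd(a, b)[idx], fc.ibd_track(a, b)[idx])
        for truth, fc in zip(res.truths, res.calls)
    ]
    return float(np.mean(concs)), len(idx)
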