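"""Evaluation metrics for simulated or benchmarked call sets.

FNR is the percentage of true genotypes whose call is missing after the GQ
filter or differs from the truth (1 - sensitivity); FDR is the percentage of
filter-surviving calls that differ from the truth (1 - precision).  With no
filtering the two coincide for overall genotypes.  The Mendelian-
inconsistency rate is the percentage of evaluated parent-offspring trio
genotype triples impossible under Mendelian transmission, after filtering on
the minimum GQ within the trio.  IBD concordance is the fraction of sites at
which the pairwise IBD derived from the inferred inheritance vector equals
the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree

__all__ = [
    "MetricsReport",
    "fnr_fdr",
    "mendelian_inconsistency",
    "ibd_concordance",
    "gq_sweep",
    "DEFAULT_FREQ_BINS",
]

DEFAULT_FREQ_BINS = ((0.0, 0.01), (0.01, 0.02), (0.02, 0.05), (0.05, 0.1))


@dataclass
class MetricsReport:
    fnr: float
    fdr: float  # NaN when no calls survive the filter
    n_truth: int
    n_called: int
    by_bin: dict[tuple[float, float], "MetricsReport"] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        out = [
            {
                "stratum": "all",
                "fnr": self.fnr,
                "fdr": self.fdr,
                "n_truth": self.n_truth,
                "n_called": self.n_called,
            }
        ]
        for (lo, hi), r in self.by_bin.items():
            out.append(
                {
                    "stratum": f"({lo},{hi}]",
                    "fnr": r.fnr,
                    "fdr": r.fdr,
                    "n_truth": r.n_truth,
                    "n_called": r.n_called,
                }
            )
        return out


def _rates(
    truth: np.ndarray,
    calls: np.ndarray,
    kept: np.ndarray,
    het_only: bool,
    valid: np.ndarray,
) -> MetricsReport:
    truth_sel = valid & ((truth == 1) if het_only else True)
    call_sel = kept & valid & ((calls == 1) if het_only else True)
    n_truth = int(truth_sel.sum())
    wrong_or_missing = truth_sel & (~kept | (calls != truth))
    fnr = 100.0 * wrong_or_missing.sum() / n_truth if n_truth else float("nan")
    n_called = int(call_sel.sum())
    fdr = (
        100.0 * (call_sel & (calls != truth)).sum() / n_called
        if n_called
        else float("nan")
    )
    return MetricsReport(fnr=float(fnr), fdr=float(fdr), n_truth=n_truth, n_called=n_called)


def fnr_fdr(
    truth: np.ndarray,
    calls: np.ndarray,
    gq: np.ndarray,
    gq_min: float = 0.0,
    het_only: bool = False,
    freq: np.ndarray | None = None,
    freq_bins=None,
) -> MetricsReport:
    """FNR/FDR over aligned truth and call genotype tables.

    ``truth``/``calls``/``gq``: same shape, genotypes as alt-allele counts;
    entries may be masked out by setting truth < 0 (e.g. unsequenced
    members).  ``het_only`` restricts the truth set (FNR) and the call set
    (FDR) to heterozygotes.  ``freq`` (per-site, broadcast over samples)
    enables per-allele-frequency-bin stratification.
    """
    truth = np.asarray(truth)
    calls = np.asarray(calls)
    gq = np.asarray(gq)
    if truth.shape != calls.shape or truth.shape != gq.shape:
        raise ValueError("truth, calls and gq tables must be aligned")
    valid = truth >= 0
    kept = (gq >= gq_min) & valid
    rep = _rates(truth, calls, kept, het_only, valid)
    if freq is not None:
        freq = np.broadcast_to(np.asarray(freq), truth.shape)
        for lo, hi in freq_bins or DEFAULT_FREQ_BINS:
            m = (freq > lo) & (freq <= hi) & valid
            rep.by_bin[(lo, hi)] = _rates(truth, calls, kept, het_only, m)
    return rep


_MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
for _fa in range(3):
    for _mo in range(3):
        fa_alleles = {0: {0}, 1: {0, 1}, 2: {1}}[_fa]
        mo_alleles = {0: {0}, 1: {0, 1}, 2: {1}}[_mo]
        for _a in fa_alleles:
            for _b in mo_alleles:
                _MENDEL_OK[_fa, _mo, _a + _b] = True


def mendelian_inconsistency(
    calls: np.ndarray, gq: np.ndarray, ped: Pedigree, gq_min: float = 0.0
) -> float:
    """MI rate (%) over all parent-offspring trios and sites.

    A (father, mother, child) genotype triple is evaluated when the minimum
    GQ among the three is >= ``gq_min``; it is a violation iff the child
    genotype is impossible given the parents.  Returns NaN for pedigrees
    without trios or when nothing passes the filter.
    """
    trios = ped.trios()
    if not trios:
        return float("nan")
    n_eval = 0
    n_bad = 0
    for fa, mo, ch in trios:
        m = np.minimum(np.minimum(gq[fa], gq[mo]), gq[ch]) >= gq_min
        n_eval += int(m.sum())
        n_bad += int((~_MENDEL_OK[calls[fa][m], calls[mo][m], calls[ch][m]]).sum())
    return 100.0 * n_bad / n_eval if n_eval else float("nan")


def gq_sweep(
    truth: np.ndarray,
    calls: np.ndarray,
    gq: np.ndarray,
    gq_values=range(3, 31),
    het_only: bool = False,
) -> "pd.DataFrame":
    """FNR/FDR across a range of GQ cutoffs, as a tidy table (one row per
    cutoff) for FNR-FDR curve reports."""
    import pandas as pd

    rows = []
    for g in gq_values:
        rep = fnr_fdr(truth, calls, gq, gq_min=float(g), het_only=het_only)
        rows.append({"gq_min": g, "fnr": rep.fnr, "fdr": rep.fdr})
    return pd.DataFrame(rows)


def ibd_concordance(
    truth_ibd: np.ndarray, inferred_ibd: np.ndarray
) -> float:
    """Fraction of sites at which the inferred pairwise IBD equals the truth."""
    t = np.asarray(truth_ibd)
    i = np.asarray(inferred_ibd)
    if t.shape != i.shape:
        raise ValueError("truth and inferred IBD tracks must be aligned")
    return float(np.mean(t == i))
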