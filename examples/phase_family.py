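"""Reconstruct Mendelian-consistent haplotypes in a nuclear family.

Runs the caller in phased mode on one simulated Nuc4 family at 15X.  Phased
calls assign every member an ordered (paternal | maternal) genotype driven
by the best inheritance vector, which makes Mendelian violations impossible
by construction.
"""

import numpy as np

from pedcaller.caller import CallerConfig, call_cohort
from pedcaller.evaluate import fnr_fdr, mendelian_inconsistency
from pedcaller.simulate import SimConfig, simulate_cohort

cfg = SimConfig(structure="Nuc4", n_families=1, n_sites=1000, coverage=15.0)
positions, q, fams = simulate_cohort(cfg, seed=3)
truth, L = fams[0]
calls, _ = call_cohort(
    [truth.ped], positions, q, [L], cfg.genetic_map(), CallerConfig(phase=True)
)
fc = calls[0]

rep = fnr_fdr(truth.genotypes, fc.genotypes, fc.gq, gq_min=3.0)
mi = mendelian_inconsistency(fc.genotypes, fc.gq, fc.ped, gq_min=0.0)
hap_acc = float(np.mean(fc.haplotypes == truth.haplotypes))
print(f"phased genotype FNR at GQ>=3: {rep.fnr:.3f}%")
print(f"Mendelian inconsistency rate: {mi:.1f}% (zero by construction)")
print(f"per-allele haplotype agreement with truth: {hap_acc:.4f}")
# Allele-level agreement can dip below genotype accuracy only through
# phase-ambiguous double heterozygotes, whose ordering carries no signal.
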