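"""Simulate a small nuclear-family cohort and refine its genotypes.

Builds five Nuc4 families (two parents, two children) sequenced at 10X over
1,500 sites, runs scaffold selection + the inheritance-vector HMM + genotype
refinement, and reports the error rates against the simulated truth.
"""

import numpy as np

from pedcaller.caller import call_cohort
from pedcaller.evaluate import fnr_fdr
from pedcaller.simulate import SimConfig, simulate_cohort

cfg = SimConfig(structure="Nuc4", n_families=5, n_sites=1500, coverage=10.0)
positions, q, fams = simulate_cohort(cfg, seed=1)
peds = [t.ped for t, _ in fams]
calls, sel = call_cohort(peds, positions, q, [L for _, L in fams], cfg.genetic_map())

print("scaffold selection:", sel.counts)
truth = np.concatenate([t.genotypes for t, _ in fams])
called = np.concatenate([c.genotypes for c in calls])
gq = np.concatenate([c.gq for c in calls])
rep = fnr_fdr(truth, called, gq, gq_min=3.0)
het = fnr_fdr(truth, called, gq, gq_min=3.0, het_only=True)
print(f"overall FNR {rep.fnr:.3f}%  FDR {rep.fdr:.3f}%  (n={rep.n_truth} genotypes)")
print(f"het     FNR {het.fnr:.3f}%  FDR {het.fdr:.3f}%")
# FNR: % of true genotypes miscalled or filtered at GQ>=3; FDR: % of kept
# calls that are wrong.  IBD sharing lets relatives pool reads, so both
# should sit well below the error of independent per-sample calling.
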