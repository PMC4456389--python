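# Methods

## Model

`pedcaller` refines genotype calls in sequenced pedigrees by first inferring
how chromosomal segments flow through the family, then conditioning every
genotype call on that flow.

**Inheritance vectors.** For a pedigree with *f* founders and *n*
non-founders, the allele transmitted in each of the 2*n* meioses is recorded
as one bit (0 = grand-paternal, 1 = grand-maternal), giving an inheritance
vector `(p_1, m_1, ..., p_n, m_n)` and a state space of `N = 2^(2n)`
vectors.  A vector fully determines which of the 2*f* founder alleles every
member carries, and hence the pairwise identity-by-descent (IBD) sharing.

**Hidden Markov chain.** Along a chromosome the inheritance vector evolves
by recombination.  Assuming no crossover interference, transitions between
adjacent informative sites factorize over meioses:
`P(I_j | I_{j-1}) = theta^h (1-theta)^(2n-h)` where *h* is the Hamming
distance and *theta* is the recombination fraction from the genetic
distance via the Haldane map function `theta = (1 - exp(-2d))/2` (*d* in
Morgans) — the unique map function consistent with the independence
assumption.  The initial distribution is uniform.

**Emission.** At site *j* with per-member genotype likelihoods
`P(R_ij | G_ij)` (from VCF PL/GL fields or the simulator) and alternative
allele frequency *q*,

```
P(R_j | I_j) = sum over ordered founder genotype configurations of
               prod_i P(R_ij | G_ij) * prod_founders P(G_ij)
```

where non-founder genotypes are fixed by the founder configuration plus the
inheritance vector, and the founder prior is ordered Hardy–Weinberg from
*q*.  Emissions are invariant under flipping the (unobservable) phase of
any founder, so states fall into at most `2^(2n-f)` founder-symmetry
classes; emissions are computed once per class and broadcast.  The sum over
the `4^f` configurations is evaluated for all classes at once as a single
matrix product between the log-likelihood table and a precomputed 0/1
indicator matrix (`exp` afterwards), which is what makes desk-scale
pedigrees up to `2n = 16` meioses practical.  Computation is refused beyond
`4^f = 65,536` founder configurations; pedigrees that large need Monte
Carlo likelihood methods, which are out of scope.

**Chain algorithms.** Forward–backward gives per-site marginal posteriors
over inheritance vectors (Eq. normalization checked to 1e-9) and the total
data log-likelihood; arithmetic is in scaled linear space with per-site
renormalization so that the transition kernel — a Kronecker product of 2×2
kernels over meiosis bits — can be applied axis-by-axis in O(N log N).
Viterbi runs in the max-plus semiring with the same factorization; ties
break toward the lowest state index; traceback recomputes predecessors from
the stored score tables rather than storing backpointers.

## Scaffold selection

The chain is built on a sparse set of "scaffold" sites that should be
confidently polymorphic, mutually independent, and free of artifacts:

1. *Region exclusion*: sites inside user-supplied BED intervals (segmental
   duplications, repeats, ...) or within 50 bp (configurable) of known
   indels are dropped.
2. *Polymorphism prescreen*: a cheap HWE Bayes factor over the pooled
   sequenced samples must reach phred 20.
3. *De-novo / artifact screen*: a site is dropped when the best
   unconstrained explanation of any family's likelihoods beats the best
   Mendelian-consistent explanation by more than 3 log10 units (≥1000:1);
   such sites (de-novo mutations, unannotated structural variation) would
   corrupt the inferred inheritance vectors.
4. *LD pruning*: greedy left-to-right on posterior-mean dosages; a site
   enters the scaffold iff its squared Pearson correlation with every kept
   site in the trailing 100-variant window is ≤ 0.2.  Dosages come from
   sequenced founders pooled across all families of the run; when fewer
   than 20 founders carry data, all sequenced members are pooled instead,
   and with still smaller panels pruning falls back to (optional) physical
   spacing.  Because the sample r² of truly independent sites is noisy at
   small panel sizes (null mean 1/(n-1)), the pruning threshold is raised
   to the two-sided 1e-4 null quantile of r² (Fisher z) whenever that
   exceeds 0.2 — only correlations distinguishable from sampling noise
   prune.  Without this guard a 20-sample panel prunes almost everything,
   since the greedy window rule compounds per-pair false positives.

All other sites live in scaffold intervals.  Their polymorphism posterior
is evaluated under the left and right flanking scaffold posteriors
separately and the larger value wins (valid under at-most-one-crossover per
interval); the winning side also supplies the inheritance-vector
distribution for genotype calling, so crossover breakpoints are localized
to the interval where the chosen side switches.

## Variant and genotype calling

*Variant quality.* Polymorphic and monomorphic models are compared per
inheritance vector: the polymorphic emission uses the HWE founder prior
with the all-reference configuration removed and renormalized (so the two
hypotheses are disjoint); the monomorphic likelihood is the product of
homozygous-reference likelihoods.  The coalescent prior of polymorphism is
`theta_mut * sum_{i=1..2f} 1/i` with `theta_mut = 1/1000`.  The per-state
posteriors are averaged under the site's inheritance-vector distribution
and reported as `VQ = -10 log10(1 - P(poly | data))`, capped at 255.

*Genotypes.* Per state, the probability that member *i* has genotype *g* is
the configuration mass yielding *g* divided by the emission; averaging over
the (truncated) state posterior gives the genotype posterior.  Truncation
keeps the top classes reaching cumulative mass 0.99 by default
(`"best"` keeps the single best class).  The call is the argmax with ties
broken RR < RA < AA, and `GQ = -10 log10(1 - P_max)`, capped at 255.
Unordered genotypes are constant within a founder-symmetry class, so all
of this runs at class level exactly.

*Haplotypes.* When the pedigree contains a sequenced parent, the ordered
founder configuration maximizing the posterior given the Viterbi-best
inheritance vector is assigned to founders and propagated to non-founders;
stitching sites along the chromosome yields haplotypes with the paternal
allele written first (`1|0` in VCF).  Mendelian violations are impossible
by construction.  Phase at double-heterozygous parent/offspring sites is
not identifiable from inheritance alone; such sites receive an arbitrary
but deterministic phase and should not be interpreted without LD
information.  For sibships without sequenced parents phasing is refused
with an explicit error.

*Allele frequencies.*  INFO/AF (or a sidecar table) is used when present;
otherwise *q* is estimated per site by an EM fit under HWE (≤50 iterations,
tolerance 1e-6) on the pooled sequenced founders, falling back to all
sequenced members treated as unrelated — an approximation that slightly
overweights shared haplotypes.

## Synthetic data

The simulator emulates family shotgun sequencing without read alignment:

- site positions uniform on a chromosome (default 100 Mb, 5000 sites) with
  a 1 cM/Mb map (configurable or file-based);
- alternative allele frequencies drawn with density ∝ 1/q on
  [0.001, 0.5], the neutral-spectrum abundance of rare variants;
- founder haplotypes i.i.d. Bernoulli(q) per site; offspring haplotypes by
  dropping parental haplotypes through crossovers placed as a Poisson
  process on the genetic-map scale;
- per member and site, depth ~ Poisson(coverage) and alt reads ~
  Binomial(depth, mu_g) with `mu_RR = 0.01`, `mu_RA = 0.5`,
  `mu_AA = 0.99` (per-base error 0.01); likelihoods are the binomial
  kernels, max-normalized.  Unsequenced members carry (1, 1, 1).

Pedigree templates: Sib2/Sib4/Sib6 (sibships, founder parents present but
unsequenced), Nuc4/Nuc6 (nuclear families, all sequenced), Ext10 (three
generations, 10 members, f = 4).  Study conditions for the benchmarks are
20 families per structure (10 per structure for the six-way heterozygote
average), ≥5000 sites, coverages 2–30X, GQ ≥ 3 filtering.

What the generator does **not** emulate: alignment and mapping artifacts,
base-quality miscalibration, allele dropout, indels and structural
variation, duplicate reads, LD between sites.  Error rates measured here
are therefore a clean-channel bound: passing benchmarks shows the
inference machinery extracts the IBD information correctly, not that the
pipeline is robust to real alignment noise (the region-exclusion and
de-novo screens exist for that, but are only lightly exercised by
simulation).  For the same reason the benchmark error rates are expected
to sit at or below values reported for read-level simulations.

The IBD-recovery benchmark uses a denser grid (4000 sites over 25 Mb)
than the genotype benchmarks: crossover-localization error is measured in
scaffold sites, and whole-genome data after pruning is far denser per cM
than a 5000-site desk-scale grid; the denser grid approximates that regime
at 2X coverage.

## Evaluation metrics

FNR = % of true genotypes whose call is filtered out or different;
FDR = % of filter-surviving calls that differ from truth; both optionally
restricted to heterozygotes and stratified by true allele frequency
(pooled across families).  With no filtering, overall FNR = FDR.  FDR is
reported as NaN when nothing survives the filter.  Only sequenced members
are scored: the unsequenced founder parents of sibships are partially
unidentifiable in principle.  The Mendelian-inconsistency rate is the % of
parent-offspring trio genotype triples (min-GQ filtered) impossible under
Mendelian transmission.  IBD concordance is the fraction of sites at which
the pair's IBD from the inferred inheritance vector equals the simulated
truth.

## Numerical choices and edge cases

- Likelihoods are floored at 1e-30 so a single corrupt field cannot
  zero out a site; an all-zero emission vector still raises, naming the
  site.
- VQ and GQ are capped at 255 (phred overflow guard).
- `theta = 0` (coincident map positions) and `theta = 0.5` are handled
  exactly in both sum-product and max-plus transition applications.
- Sites outside the scaffold span use the single available flank; if no
  scaffold survives at all, calling falls back to the uniform
  inheritance-vector distribution with a warning.
- One connected family per chain; multi-family inputs are processed by
  looping, with scaffold selection shared across families.
- Exactly two parents or none: half-specified parentage, loops, and cycles
  are rejected at parse time with the offending id.

## Known limitations

- Pedigrees beyond `2n = 16` meiosis bits or `4^f = 65,536` founder
  configurations are refused rather than approximated.
- No modeling of de-novo mutation calling, X-chromosome inheritance,
  multi-allelic sites, or LD-based phasing of inheritance-ambiguous sites.
- The EM allele-frequency fallback treats panel members as unrelated.
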