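"""Synthetic pedigree-sequencing generator.

Emulates a family shotgun-sequencing experiment without read alignment:
founder haplotypes are drawn site-wise under a configurable allele-frequency
spectrum, offspring haplotypes are produced by dropping parental haplotypes
through crossovers placed as a Poisson process on the genetic-map scale, and
per-member genotype likelihoods are emitted from a Poisson-depth /
binomial-error read model (depth ~ Poisson(coverage), alt reads ~
Binomial(depth, mu_g) with mu_RR = eps, mu_RA = 1/2, mu_AA = 1 - eps,
eps = per-base error 0.01).  Truth haplotypes, meiosis indicators and
pairwise IBD are retained for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .genmap import GeneticMap
from .pedigree import Individual, Pedigree

__all__ = [
    "SimConfig",
    "SimTruth",
    "pedigree_template",
    "PEDIGREE_STRUCTURES",
    "simulate_sites",
    "simulate_family",
    "simulate_cohort",
    "write_truth",
]


# ---------------------------------------------------------------------- #
# pedigree templates


def _sibship(n_sibs: int) -> list[Individual]:
    fa = Individual("FA", sex="male", sequenced=False)
    mo = Individual("MO", sex="female", sequenced=False)
    sibs = [
        Individual(f"S{i+1}", father_id="FA", mother_id="MO") for i in range(n_sibs)
    ]
    return [fa, mo, *sibs]


def _nuclear(n_children: int) -> list[Individual]:
    fa = Individual("FA", sex="male")
    mo = Individual("MO", sex="female")
    kids = [
        Individual(f"C{i+1}", father_id="FA", mother_id="MO")
        for i in range(n_children)
    ]
    return [fa, mo, *kids]


def _extended10() -> list[Individual]:
    """Three-generation pedigree of 10: grandparental couple, their two
    children married to two unrelated spouses, and two grandchildren per
    couple (f=4, n=6)."""
    gp1 = Individual("GF", sex="male")
    gp2 = Individual("GM", sex="female")
    c1 = Individual("P1", father_id="GF", mother_id="GM", sex="male")
    c2 = Individual("P2", father_id="GF", mother_id="GM", sex="female")
    s1 = Individual("SP1", sex="female")
    s2 = Individual("SP2", sex="male")
    g1 = Individual("K1", father_id="P1", mother_id="SP1")
    g2 = Individual("K2", father_id="P1", mother_id="SP1")
    g3 = Individual("K3", father_id="SP2", mother_id="P2")
    g4 = Individual("K4", father_id="SP2", mother_id="P2")
    return [gp1, gp2, s1, s2, c1, c2, g1, g2, g3, g4]


PEDIGREE_STRUCTURES = ("Sib2", "Sib4", "Sib6", "Nuc4", "Nuc6", "Ext10")


def pedigree_template(structure: str, family_id: str = "FAM") -> Pedigree:
    """Standard study pedigrees: sibships (unsequenced parents), nuclear
    families, and a 10-member three-generation pedigree."""
    builders = {
        "Sib2": lambda: _sibship(2),
        "Sib4": lambda: _sibship(4),
        "Sib6": lambda: _sibship(6),
        "Nuc4": lambda: _nuclear(2),
        "Nuc6": lambda: _nuclear(4),
        "Ext10": _extended10,
    }
    if structure not in builders:
        raise ValueError(
            f"unknown pedigree structure {structure!r}; "
            f"choose from {PEDIGREE_STRUCTURES}"
        )
    return Pedigree(builders[structure](), family_id=family_id)


# ---------------------------------------------------------------------- #
# configuration and truth containers


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults follow the simulated-sequencing design this package is built
    around: per-base error 0.01, Poisson read depth at the target coverage,
    and an allele-frequency spectrum proportional to 1/q on [0.001, 0.5]
    (the neutral-spectrum abundance of rare variants).
    """

    structure: str = "Nuc4"
    n_families: int = 20
    n_sites: int = 5000
    chrom_length_bp: int = 100_000_000
    coverage: float = 10.0
    base_error: float = 0.01
    q_min: float = 0.001
    q_max: float = 0.5
    chrom: str = "1"
    map_rate_cm_per_mb: float = 1.0
    custom_pedigree: Pedigree | None = None

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 < self.base_error < 1:
            raise ValueError("base_error must be in (0, 1)")

    def pedigree(self, family_id: str = "FAM") -> Pedigree:
        if self.custom_pedigree is not None:
            return self.custom_pedigree
        return pedigree_template(self.structure, family_id)

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.constant_rate(self.map_rate_cm_per_mb)


@dataclass
class SimTruth:
    """Ground truth for one simulated family."""

    ped: Pedigree
    positions: np.ndarray  # (S,) 1-based bp
    q: np.ndarray  # (S,) true alt allele frequency
    haplotypes: np.ndarray  # (size, 2, S) int8 alleles, slot 0 paternal
    meiosis_bits: np.ndarray  # (S, 2n) int8 indicator per meiosis
    crossovers: list[np.ndarray] = field(default_factory=list)  # per meiosis, bp

    @property
    def genotypes(self) -> np.ndarray:
        """(size, S) unordered true genotypes (alt-allele counts)."""
        return self.haplotypes.sum(axis=1)

    def iv_states(self) -> np.ndarray:
        """(S,) true inheritance-vector state integers."""
        weights = (1 << np.arange(self.meiosis_bits.shape[1], dtype=np.int64))
        return self.meiosis_bits.astype(np.int64) @ weights

    def ibd(self, a: str, b: str) -> np.ndarray:
        from .pedigree import ibd_track

        return ibd_track(self.ped, self.iv_states(), a, b)


# ---------------------------------------------------------------------- #
# generation


def simulate_sites(cfg: SimConfig, rng: np.random.Generator):
    """Shared site grid for a cohort: sorted distinct positions and true q
    drawn from the 1/q spectrum (inverse-CDF: q = qmin * (qmax/qmin)**u)."""
    pos = np.sort(
        rng.choice(cfg.chrom_length_bp, size=cfg.n_sites, replace=False) + 1
    ).astype(np.int64)
    u = rng.random(cfg.n_sites)
    q = cfg.q_min * (cfg.q_max / cfg.q_min) ** u
    return pos, q


def _meiosis_indicators(
    positions: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: per-site grandparental indicator plus crossover bp."""
    cm = np.atleast_1d(gmap.cm_at(positions.astype(np.float64)))
    lo, hi = float(cm[0]), float(cm[-1])
    length_morgans = max(hi - lo, 0.0) / 100.0
    n_x = rng.poisson(length_morgans)
    x_cm = np.sort(rng.uniform(lo, hi, size=n_x))
    start = rng.integers(0, 2)
    bits = (start + np.searchsorted(x_cm, cm, side="right")) % 2
    # report crossover positions in bp via inverse interpolation of the map
    if n_x:
        x_bp = np.interp(
            x_cm,
            np.atleast_1d(gmap.cm_at(positions.astype(np.float64))),
            positions.astype(np.float64),
        )
    else:
        x_bp = np.empty(0)
    return bits.astype(np.int8), x_bp


def _genotype_likelihoods(
    genotypes: np.ndarray,
    sequenced: np.ndarray,
    coverage: float,
    eps: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-scale GL triples (max-normalized) from the depth/error model."""
    m, S = genotypes.shape
    depth = rng.poisson(coverage, size=(m, S))
    depth[~sequenced, :] = 0
    mu = np.array([eps, 0.5, 1.0 - eps])
    alt = rng.binomial(depth, mu[genotypes])
    ref = depth - alt
    # binomial kernel without the combinatorial factor (cancels on normalization)
    logL = np.empty((m, S, 3))
    for g in range(3):
        logL[:, :, g] = alt * np.log(mu[g]) + ref * np.log1p(-mu[g])
    logL -= logL.max(axis=2, keepdims=True)
    return np.exp(logL), depth


def simulate_family(
    cfg: SimConfig,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
    q: np.ndarray | None = None,
    family_id: str = "FAM",
) -> tuple[SimTruth, np.ndarray, np.ndarray]:
    """Simulate one family.

    Returns ``(truth, likelihoods, depth)`` with likelihoods of shape
    ``(size, n_sites, 3)`` on the linear scale, max-normalized per member and
    site; unsequenced members carry the uninformative triple (1, 1, 1).
    """
    ped = cfg.pedigree(family_id)
    gmap = cfg.genetic_map()
    if positions is None or q is None:
        positions, q = simulate_sites(cfg, rng)
    S = len(positions)
    hap = np.zeros((ped.size, 2, S), dtype=np.int8)
    for i in range(ped.f):
        hap[i, 0] = rng.random(S) < q
        hap[i, 1] = rng.random(S) < q
    bits = np.zeros((S, ped.n_meioses), dtype=np.int8)
    crossovers: list[np.ndarray] = []
    for i in range(ped.f, ped.size):
        t = i - ped.f
        for slot, parent in ((0, ped.father_idx[i]), (1, ped.mother_idx[i])):
            b, x_bp = _meiosis_indicators(positions, gmap, rng)
            bits[:, 2 * t + slot] = b
            crossovers.append(x_bp)
            hap[i, slot] = hap[int(parent), b.astype(np.int64), np.arange(S)]
    truth = SimTruth(
        ped=ped,
        positions=positions,
        q=q,
        haplotypes=hap,
        meiosis_bits=bits,
        crossovers=crossovers,
    )
    L, depth = _genotype_likelihoods(
        truth.genotypes, ped.sequenced, cfg.coverage, cfg.base_error, rng
    )
    return truth, L, depth


def simulate_cohort(
    cfg: SimConfig, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple[SimTruth, np.ndarray]]]:
    """Simulate ``cfg.n_families`` families on a shared site grid.

    Returns ``(positions, q, families)`` where each family entry is
    ``(truth, likelihoods)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions, q = simulate_sites(cfg, rng)
    fams = []
    for k in range(cfg.n_families):
        truth, L, _depth = simulate_family(
            cfg, rng, positions=positions, q=q, family_id=f"FAM{k+1}"
        )
        fams.append((truth, L))
    return positions, q, fams


# ---------------------------------------------------------------------- #
# truth output


def write_truth(truth: SimTruth, prefix: str, sample_prefix: str = "") -> None:
    """Write truth as ``<prefix>.truth.vcf`` (phased GT), ``<prefix>.ibd.tsv``
    (pairwise IBD per site) and ``<prefix>.xo.tsv`` (crossover positions).

    ``sample_prefix`` is prepended to member ids in the VCF header so truth
    samples line up with cohort call files that disambiguate families.
    """
    ped = truth.ped
    with open(f"{prefix}.truth.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1,length=536870911>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_prefix + m.id for m in ped.members)
            + "\n"
        )
        for j, pos in enumerate(truth.positions):
            gts = "\t".join(
                f"{truth.haplotypes[i, 0, j]}|{truth.haplotypes[i, 1, j]}"
                for i in range(ped.size)
            )
            fh.write(
                f"1\t{pos}\t.\tA\tG\t.\tPASS\tAF={truth.q[j]:.6g}\tGT\t{gts}\n"
            )
    states = truth.iv_states()
    with open(f"{prefix}.ibd.tsv", "w") as fh:
        fh.write("chrom\tpos\tpair\tibd\n")
        members = [m.id for m in ped.members]
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                track = truth.ibd(a, b)
                for pos, v in zip(truth.positions, track):
                    fh.write(f"1\t{pos}\t{a},{b}\t{v}\n")
    with open(f"{prefix}.xo.tsv", "w") as fh:
        fh.write("meiosis\tposition_bp\n")
        for mi, xs in enumerate(truth.crossovers):
            for x in xs:
                fh.write(f"{mi}\t{x:.0f}\n")
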