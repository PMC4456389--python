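"""VCF input/output for the caller.

Input: a multi-sample VCF carrying per-genotype likelihoods for bi-allelic
SNVs, as PL (phred-scaled, preferred) or GL (log10) FORMAT fields.  Samples
are matched to pedigree members by id; members absent from the VCF (or with
missing data at a site) carry the uninformative likelihood triple (1, 1, 1).
Non-bi-allelic and non-SNV records are skipped and counted.

Output: refined calls with QUAL = VQ, FORMAT GT:GQ ('/' unphased; '|' phased
with the paternal allele written first) and INFO AF/VQ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pysam

from .caller import FamilyCalls
from .ivhmm import LIKELIHOOD_FLOOR
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "SiteTable",
    "read_sites",
    "write_calls",
    "write_input_vcf",
    "read_af_sidecar",
]


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float | None = None
    is_scaffold: bool = False


@dataclass
class SiteTable:
    """Cohort-level site grid plus per-family likelihood tensors."""

    sites: list[VariantSite]
    likelihoods: list[np.ndarray]  # per family: (size, S, 3)
    peds: list[Pedigree]
    n_skipped: int = 0

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def af(self) -> np.ndarray:
        return np.array(
            [s.af if s.af is not None else np.nan for s in self.sites]
        )


def _pl_to_linear(pl) -> np.ndarray | None:
    if pl is None:
        return None
    vals = [v for v in pl]
    if len(vals) != 3 or any(v is None for v in vals):
        return None
    return 10.0 ** (-np.asarray(vals, dtype=np.float64) / 10.0)


def _gl_to_linear(gl) -> np.ndarray | None:
    if gl is None:
        return None
    vals = [v for v in gl]
    if len(vals) != 3 or any(v is None for v in vals):
        return None
    lin = 10.0 ** np.asarray(vals, dtype=np.float64)
    m = lin.max()
    return lin / m if m > 0 else None


def read_sites(path: str, peds: list[Pedigree] | Pedigree) -> SiteTable:
    """Read candidate sites and genotype likelihoods for one or more families.

    Pedigree members marked sequenced but missing from the VCF header are
    demoted to unsequenced with a warning (their likelihoods become flat).
    """
    if isinstance(peds, Pedigree):
        peds = [peds]
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    sample_set = set(samples)
    col: list[dict[int, int]] = []  # per family: member index -> sample column
    for ped in peds:
        mapping = {}
        for i, m in enumerate(ped.members):
            if m.id in sample_set:
                mapping[i] = samples.index(m.id)
            elif m.sequenced:
                warnings.warn(
                    f"pedigree member {m.id} marked sequenced but absent from "
                    "the VCF header; treating as unsequenced"
                )
        col.append(mapping)

    sites: list[VariantSite] = []
    rows: list[list[np.ndarray]] = [[] for _ in peds]
    n_skipped = 0
    for rec in vf:
        if (
            rec.alts is None
            or len(rec.alts) != 1
            or len(rec.ref) != 1
            or len(rec.alts[0]) != 1
            or rec.ref not in "ACGT"
            or rec.alts[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        af = rec.info.get("AF")
        if af is not None:
            af = float(af[0] if isinstance(af, tuple) else af)
        sites.append(
            VariantSite(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0], af=af)
        )
        for fidx, ped in enumerate(peds):
            tri = np.ones((ped.size, 3))
            for i, s in col[fidx].items():
                smp = rec.samples[samples[s]]
                lin = _pl_to_linear(smp.get("PL"))
                if lin is None:
                    lin = _gl_to_linear(smp.get("GL"))
                if lin is not None:
                    tri[i] = np.maximum(lin, LIKELIHOOD_FLOOR)
            rows[fidx].append(tri)
    if n_skipped:
        logger.info("skipped %d non-bi-allelic/non-SNV records", n_skipped)
    likelihoods = [
        np.transpose(np.array(r), (1, 0, 2)) if r else np.empty((p.size, 0, 3))
        for r, p in zip(rows, peds)
    ]
    return SiteTable(sites=sites, likelihoods=likelihoods, peds=peds, n_skipped=n_skipped)


def read_genotype_table(path: str):
    """Read GT (alt-allele count) and GQ tables from a called/truth VCF.

    Returns ``(positions, sample_names, genotypes (samples, S), gq)`` with
    GQ = +inf where absent (truth files carry no GQ).
    """
    vf = pysam.VariantFile(path)
    names = list(vf.header.samples)
    pos, gts, gqs = [], [], []
    for rec in vf:
        pos.append(rec.pos)
        row_g, row_q = [], []
        for s in names:
            smp = rec.samples[s]
            gt = smp.get("GT")
            if gt is None or any(a is None for a in gt):
                row_g.append(-1)
            else:
                row_g.append(int(sum(gt)))
            gq = smp.get("GQ")
            row_q.append(float("inf") if gq is None else float(gq))
        gts.append(row_g)
        gqs.append(row_q)
    return (
        np.asarray(pos, dtype=np.int64),
        names,
        np.asarray(gts, dtype=np.int64).T,
        np.asarray(gqs, dtype=np.float64).T,
    )


def read_af_sidecar(path: str) -> dict[tuple[str, int], float]:
    """Two/three-column allele-frequency sidecar: ``chrom pos af`` (or
    ``pos af`` for single-chromosome input, keyed with chrom '1')."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                out[("1", int(parts[0]))] = float(parts[1])
            else:
                out[(parts[0], int(parts[1]))] = float(parts[2])
    return out


def write_input_vcf(
    path: str,
    positions: np.ndarray,
    q: np.ndarray,
    peds: list[Pedigree],
    likelihoods: list[np.ndarray],
    chrom: str = "1",
) -> None:
    """Write a candidate-site VCF with PL fields, e.g. from simulator output.

    Only sequenced members appear as samples; names are prefixed with the
    family id when member ids collide across families.  Likelihoods are
    emitted as phred-scaled PL (capped at 255).
    """
    ids = [m.id for p in peds for m in p.members if m.sequenced]
    dup = len(ids) != len(set(ids))
    cols: list[tuple[str, int, int]] = []  # (sample name, family idx, member idx)
    for fi, p in enumerate(peds):
        for mi, m in enumerate(p.members):
            if m.sequenced:
                name = f"{p.family_id}_{m.id}" if dup else m.id
                cols.append((name, fi, mi))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length=536870911>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(name for name, _, _ in cols)
            + "\n"
        )
        for j, pos in enumerate(positions):
            parts = [
                chrom,
                str(int(pos)),
                ".",
                "A",
                "G",
                ".",
                "PASS",
                f"AF={q[j]:.6g}",
                "GT:PL",
            ]
            for _, fi, mi in cols:
                tri = np.maximum(likelihoods[fi][mi, j, :], LIKELIHOOD_FLOOR)
                pl = np.minimum(
                    np.round(-10.0 * np.log10(tri / tri.max())), 255
                ).astype(int)
                parts.append("./.:" + ",".join(str(v) for v in pl))
            fh.write("\t".join(parts) + "\n")


def _header(
    samples: list[str], phased: bool, contigs: tuple[str, ...] = ("1",)
) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.add_line(f"##contig=<ID={c},length=536870911>")
    h.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternative allele frequency">'
    )
    h.add_line(
        '##INFO=<ID=VQ,Number=1,Type=Float,Description="Phred-scaled variant quality (duplicate of QUAL)">'
    )
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    h.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">'
    )
    if phased:
        h.add_line(
            "##phasing=paternal allele first: GT is paternal|maternal"
        )
    for s in samples:
        h.add_sample(s)
    return h


def write_calls(
    path: str,
    families: list[FamilyCalls],
    mode: str = "unphased",
    sites: list[VariantSite] | None = None,
) -> None:
    """Write refined calls for one or more families to one VCF.

    ``sites`` supplies chrom/ref/alt per record (defaults to chromosome 1,
    A>G, matching the simulator's convention).  Sample columns take the
    member id, prefixed with the family id when the same member id occurs in
    several families.
    """
    if mode not in ("unphased", "phased"):
        raise ValueError("mode must be 'unphased' or 'phased'")
    phased = mode == "phased"
    if phased and any(f.haplotypes is None for f in families):
        raise ValueError("phased output requested but calls carry no haplotypes")
    ids = [m.id for f in families for m in f.ped.members]
    dup = len(ids) != len(set(ids))
    names: list[str] = []
    for f in families:
        for m in f.ped.members:
            names.append(f"{f.ped.family_id}_{m.id}" if dup else m.id)
    contigs = ("1",)
    if sites is not None:
        contigs = tuple(dict.fromkeys(s.chrom for s in sites)) or ("1",)
    head = _header(names, phased, contigs)
    ref_pos = families[0].positions
    vcf = pysam.VariantFile(path, "w", header=head)
    S = len(ref_pos)
    for j in range(S):
        if sites is not None:
            chrom, ref, alt = sites[j].chrom, sites[j].ref, sites[j].alt
        else:
            chrom, ref, alt = "1", "A", "G"
        rec = vcf.new_record(
            contig=chrom,
            start=int(ref_pos[j]) - 1,
            alleles=(ref, alt),
        )
        rec.qual = float(np.round(max(f.vq[j] for f in families), 2))
        rec.info["AF"] = float(families[0].q[j])
        rec.info["VQ"] = float(rec.qual)
        k = 0
        for f in families:
            for i in range(f.ped.size):
                smp = rec.samples[names[k]]
                if phased:
                    smp["GT"] = (int(f.haplotypes[i, 0, j]), int(f.haplotypes[i, 1, j]))
                    smp.phased = True
                else:
                    g = int(f.genotypes[i, j])
                    smp["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
                smp["GQ"] = int(min(round(f.gq[i, j]), 255))
                k += 1
        vcf.write(rec)
    vcf.close()
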