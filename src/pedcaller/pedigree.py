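"""Pedigree representation and the inheritance-vector state space.

A pedigree with *f* founders and *n* non-founders is canonicalized so that
founders come first and every non-founder appears after both of its parents.
An inheritance vector carries two meiosis indicator bits per non-founder,
``(p_1, m_1, ..., p_n, m_n)``: bit value 0 means the grand-paternal allele of
the transmitting parent was passed on, 1 the grand-maternal allele.  A state
is stored as the integer whose little-endian bits are the meiosis indicators,
so there are ``N = 2**(2n)`` states.

Because the phase of a founder's two alleles is unobservable, states related
by flipping, for some subset of founders, every meiosis bit that chooses
between that founder's two alleles are statistically equivalent; the
resulting founder-symmetry classes (at most ``2**(2n-f)`` of them carry
distinct emissions) are the basis of the caller's main computational saving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "InheritanceVector",
    "FounderClasses",
    "PedigreeError",
    "StateSpaceTooLarge",
    "parse_ped",
    "iter_families",
    "enumerate_states",
    "founder_symmetry_classes",
    "allele_labels",
    "allele_labels_all",
    "ibd_from_iv",
]

#: default cap on the number of meiosis bits (2n) for exact computation
DEFAULT_MAX_BITS = 16


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (unknown/missing parents, cycles...)."""


class StateSpaceTooLarge(PedigreeError):
    """Raised when 2n exceeds the configured meiosis-bit cap."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    A founder has neither parent in the pedigree; a non-founder must have
    both.  Half-specified parentage is rejected at pedigree construction.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # {male, female, unknown}
    sequenced: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class InheritanceVector:
    """An inheritance-vector state: 2n meiosis bits plus its integer label."""

    bits: tuple[int, ...]
    index: int

    def __int__(self) -> int:
        return self.index


class Pedigree:
    """A single connected family, canonicalized founders-first.

    Parameters
    ----------
    individuals:
        Members in any order; they are re-ordered so that the first ``f``
        are founders and every non-founder follows both parents.
    family_id:
        Optional label carried through to output files.
    """

    def __init__(self, individuals: Sequence[Individual], family_id: str = "FAM"):
        self.family_id = family_id
        self.members: list[Individual] = _canonical_order(list(individuals))
        self.index: dict[str, int] = {m.id: i for i, m in enumerate(self.members)}
        if len(self.index) != len(self.members):
            raise PedigreeError("duplicate individual ids in pedigree")
        self.f = sum(1 for m in self.members if m.is_founder)
        self.n = len(self.members) - self.f
        # parent member-indices; -1 for founders
        fa = np.full(len(self.members), -1, dtype=np.int64)
        mo = np.full(len(self.members), -1, dtype=np.int64)
        for i, m in enumerate(self.members):
            if not m.is_founder:
                fa[i] = self.index[m.father_id]
                mo[i] = self.index[m.mother_id]
        self.father_idx = fa
        self.mother_idx = mo
        self.sequenced = np.array([m.sequenced for m in self.members], dtype=bool)

    # ------------------------------------------------------------------ #
    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_meioses(self) -> int:
        return 2 * self.n

    @property
    def n_states(self) -> int:
        return 1 << self.n_meioses

    def nonfounder_index(self, member_idx: int) -> int:
        """Position of a non-founder among the non-founders (0-based)."""
        if member_idx < self.f:
            raise PedigreeError(f"member {self.members[member_idx].id} is a founder")
        return member_idx - self.f

    def meiosis_parent(self, bit: int) -> int:
        """Member index of the parent transmitting through meiosis ``bit``."""
        child = self.f + bit // 2
        return int(self.father_idx[child] if bit % 2 == 0 else self.mother_idx[child])

    def trios(self) -> list[tuple[int, int, int]]:
        """All (father, mother, child) member-index triples."""
        return [
            (int(self.father_idx[i]), int(self.mother_idx[i]), i)
            for i in range(self.f, self.size)
        ]

    def has_parent_offspring_link(self) -> bool:
        """True when at least one parent-offspring pair is sequenced data-wise
        representable, i.e. the pedigree contains a non-founder whose parents
        are members (always true when n >= 1) and at least one parent is
        sequenced."""
        for fa, mo, _child in self.trios():
            if self.sequenced[fa] or self.sequenced[mo]:
                return True
        return False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Pedigree({self.family_id}: f={self.f}, n={self.n})"


def _canonical_order(individuals: list[Individual]) -> list[Individual]:
    """Founders first, then non-founders topologically (parents first)."""
    ids = {m.id for m in individuals}
    for m in individuals:
        has_f, has_m = m.father_id is not None, m.mother_id is not None
        if has_f != has_m:
            raise PedigreeError(f"individual {m.id} has a single parent specified")
        if has_f:
            if m.father_id not in ids:
                raise PedigreeError(f"unknown parent id {m.father_id!r} for {m.id}")
            if m.mother_id not in ids:
                raise PedigreeError(f"unknown parent id {m.mother_id!r} for {m.id}")

    founders = [m for m in individuals if m.is_founder]
    ordered = list(founders)
    placed = {m.id for m in founders}
    pending = [m for m in individuals if not m.is_founder]
    while pending:
        progressed = False
        remaining = []
        for m in pending:
            if m.father_id in placed and m.mother_id in placed:
                ordered.append(m)
                placed.add(m.id)
                progressed = True
            else:
                remaining.append(m)
        if not progressed:
            raise PedigreeError(
                "cyclic parentage involving: " + ", ".join(m.id for m in remaining)
            )
        pending = remaining
    return ordered


# ---------------------------------------------------------------------- #
# PED parsing (6 columns: family, id, father, mother, sex, phenotype)


_SEX = {"1": "male", "2": "female"}


def iter_families(
    stream: TextIO | Iterable[str], sequenced_ids: set[str] | None = None
) -> Iterator[Pedigree]:
    """Yield one :class:`Pedigree` per family id in a 6-column PED stream.

    ``sequenced_ids``, when given, marks individuals absent from it as
    unsequenced (e.g. ids missing from the VCF header).
    """
    fams: dict[str, list[Individual]] = {}
    order: list[str] = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PedigreeError(f"malformed PED line: {raw!r}")
        fam, iid, fid, mid = parts[:4]
        sex = _SEX.get(parts[4], "unknown") if len(parts) > 4 else "unknown"
        seq = True if sequenced_ids is None else (iid in sequenced_ids)
        ind = Individual(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=sex,
            sequenced=seq,
        )
        if fam not in fams:
            fams[fam] = []
            order.append(fam)
        fams[fam].append(ind)
    for fam in order:
        yield Pedigree(fams[fam], family_id=fam)


def parse_ped(
    stream: TextIO | Iterable[str], sequenced_ids: set[str] | None = None
) -> Pedigree:
    """Parse a PED stream that must contain exactly one family."""
    peds = list(iter_families(stream, sequenced_ids))
    if not peds:
        raise PedigreeError("empty PED input")
    if len(peds) > 1:
        raise PedigreeError(
            f"expected one family per run, found {len(peds)}; "
            "use iter_families / the CLI to loop over families"
        )
    return peds[0]


# ---------------------------------------------------------------------- #
# state space


def enumerate_states(
    ped: Pedigree, max_bits: int = DEFAULT_MAX_BITS
) -> list[InheritanceVector]:
    """All ``2**(2n)`` inheritance vectors in canonical (integer) order."""
    nb = ped.n_meioses
    if nb == 0:
        raise PedigreeError("pedigree has no non-founders: no meioses to model")
    if nb > max_bits:
        raise StateSpaceTooLarge(
            f"2n = {nb} meiosis bits exceeds the cap of {max_bits}; "
            "exact inheritance-vector computation is not feasible"
        )
    return [
        InheritanceVector(bits=tuple((k >> b) & 1 for b in range(nb)), index=k)
        for k in range(1 << nb)
    ]


def founder_flip_masks(ped: Pedigree) -> np.ndarray:
    """Per founder, the XOR mask of meiosis bits selecting between that
    founder's two alleles (bits whose transmitting parent is the founder)."""
    masks = np.zeros(ped.f, dtype=np.int64)
    for bit in range(ped.n_meioses):
        parent = ped.meiosis_parent(bit)
        if parent < ped.f:
            masks[parent] |= 1 << bit
    return masks


@dataclass
class FounderClasses:
    """Partition of inheritance-vector states under founder phase flips."""

    class_of: np.ndarray  # (N,) class id per state
    reps: np.ndarray  # (C,) representative (minimum) state per class
    masks: np.ndarray  # (f,) per-founder XOR masks

    @property
    def n_classes(self) -> int:
        return len(self.reps)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.class_of, minlength=self.n_classes)


def founder_symmetry_classes(
    ped: Pedigree, max_bits: int = DEFAULT_MAX_BITS
) -> FounderClasses:
    """Orbits of the state space under the ``2**f`` founder phase flips."""
    nb = ped.n_meioses
    if nb > max_bits:
        raise StateSpaceTooLarge(f"2n = {nb} exceeds cap {max_bits}")
    masks = founder_flip_masks(ped)
    combo = np.zeros(1 << ped.f, dtype=np.int64)
    for s in range(1 << ped.f):
        acc = 0
        for i in range(ped.f):
            if (s >> i) & 1:
                acc ^= int(masks[i])
        combo[s] = acc
    states = np.arange(ped.n_states, dtype=np.int64)
    canon = np.min(states[None, :] ^ combo[:, None], axis=0)
    reps, class_of = np.unique(canon, return_inverse=True)
    return FounderClasses(class_of=class_of.astype(np.int64), reps=reps, masks=masks)


# ---------------------------------------------------------------------- #
# allele flow and IBD


def allele_labels_all(ped: Pedigree) -> np.ndarray:
    """Founder-allele labels carried by every member under every state.

    Returns an int16 array of shape ``(N, size, 2)``: for each state and
    member, the labels of the paternal-slot and maternal-slot alleles.
    Founder ``i`` owns labels ``(2i, 2i+1)``.
    """
    N = ped.n_states
    m = ped.size
    lab = np.empty((N, m, 2), dtype=np.int16)
    states = np.arange(N, dtype=np.int64)
    for i in range(ped.f):
        lab[:, i, 0] = 2 * i
        lab[:, i, 1] = 2 * i + 1
    for i in range(ped.f, m):
        t = i - ped.f
        pbit = (states >> (2 * t)) & 1
        mbit = (states >> (2 * t + 1)) & 1
        fa, mo = int(ped.father_idx[i]), int(ped.mother_idx[i])
        # bit 0 -> parent's paternal-slot (grand-paternal) allele
        lab[:, i, 0] = np.take_along_axis(
            lab[:, fa, :], pbit[:, None].astype(np.int64), axis=1
        )[:, 0]
        lab[:, i, 1] = np.take_along_axis(
            lab[:, mo, :], mbit[:, None].astype(np.int64), axis=1
        )[:, 0]
    return lab


def allele_labels(ped: Pedigree, state: int) -> np.ndarray:
    """Labels for a single state; shape ``(size, 2)``."""
    lab = np.empty((ped.size, 2), dtype=np.int16)
    for i in range(ped.f):
        lab[i] = (2 * i, 2 * i + 1)
    for i in range(ped.f, ped.size):
        t = i - ped.f
        pbit = (state >> (2 * t)) & 1
        mbit = (state >> (2 * t + 1)) & 1
        lab[i, 0] = lab[int(ped.father_idx[i]), pbit]
        lab[i, 1] = lab[int(ped.mother_idx[i]), mbit]
    return lab


def ibd_from_iv(
    ped: Pedigree, iv: InheritanceVector | int, a: str, b: str
) -> int:
    """IBD sharing (0, 1 or 2) between members ``a`` and ``b`` under ``iv``."""
    for x in (a, b):
        if x not in ped.index:
            raise PedigreeError(f"id {x!r} not in pedigree")
    if a == b:
        raise PedigreeError("IBD is defined for two distinct members")
    lab = allele_labels(ped, int(iv))
    ia, ib = ped.index[a], ped.index[b]
    return int(len({lab[ia, 0], lab[ia, 1]} & {lab[ib, 0], lab[ib, 1]}))


def ibd_track(ped: Pedigree, states: np.ndarray, a: str, b: str) -> np.ndarray:
    """Vectorized IBD between two members along a sequence of states."""
    lab = allele_labels_all(ped)
    ia, ib = ped.index[a], ped.index[b]
    la, lb = lab[:, ia, :], lab[:, ib, :]
    share = (
        (la[:, 0:1] == lb).any(axis=1).astype(np.int8)
        + (la[:, 1:2] == lb).any(axis=1).astype(np.int8)
    )
    return share[np.asarray(states, dtype=np.int64)]
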