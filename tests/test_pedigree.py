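import io

import numpy as np
import pytest

from pedcaller import (
    PedigreeError,
    StateSpaceTooLarge,
    enumerate_states,
    founder_symmetry_classes,
    ibd_from_iv,
    iter_families,
    parse_ped,
)
from pedcaller.pedigree import allele_labels, allele_labels_all, founder_flip_masks
from pedcaller.simulate import pedigree_template

NUC4_PED = """\
FAM1 FA 0 0 1 0
FAM1 MO 0 0 2 0
FAM1 C1 FA MO 1 0
FAM1 C2 FA MO 2 0
"""


class TestParsePed:
    def test_nuclear_family_counts(self):
        ped = parse_ped(io.StringIO(NUC4_PED))
        assert (ped.f, ped.n) == (2, 2)
        assert [m.id for m in ped.members[:2]] == ["FA", "MO"]

    def test_founders_first_regardless_of_file_order(self):
        shuffled = "\n".join(reversed(NUC4_PED.strip().split("\n")))
        ped = parse_ped(io.StringIO(shuffled))
        assert all(m.is_founder for m in ped.members[: ped.f])
        assert not any(m.is_founder for m in ped.members[ped.f :])

    def test_extended_ten_member_pedigree(self):
        ped = pedigree_template("Ext10")
        assert (ped.f, ped.n) == (4, 6)
        assert ped.size == 10

    def test_single_parent_rejected_with_id(self):
        bad = "F X 0 0 1 0\nF Y X 0 1 0\n"
        with pytest.raises(PedigreeError, match="Y"):
            parse_ped(io.StringIO(bad))

    def test_unknown_parent_rejected(self):
        bad = "F X 0 0 1 0\nF Y X ZZZ 1 0\n"
        with pytest.raises(PedigreeError, match="ZZZ"):
            parse_ped(io.StringIO(bad))

    def test_multiple_families_need_iteration(self):
        two = NUC4_PED + NUC4_PED.replace("FAM1", "FAM2")
        with pytest.raises(PedigreeError, match="one family"):
            parse_ped(io.StringIO(two))
        fams = list(iter_families(io.StringIO(two)))
        assert [p.family_id for p in fams] == ["FAM1", "FAM2"]

    def test_absent_from_vcf_marked_unsequenced(self):
        ped = parse_ped(io.StringIO(NUC4_PED), sequenced_ids={"C1", "C2"})
        assert list(ped.sequenced) == [False, False, True, True]


class TestStateSpace:
    @pytest.mark.parametrize(
        "structure,expected",
        [("Sib2", 16), ("Nuc4", 16), ("Sib6", 4096)],
    )
    def test_state_count_is_four_to_the_n(self, structure, expected):
        ped = pedigree_template(structure)
        assert len(enumerate_states(ped)) == expected

    def test_trio_has_four_states(self, trio):
        states = enumerate_states(trio)
        assert len(states) == 4
        assert [s.index for s in states] == [0, 1, 2, 3]
        assert states[3].bits == (1, 1)

    def test_cap_raises_explicit_error(self):
        ped = pedigree_template("Sib6")  # 2n = 12
        with pytest.raises(StateSpaceTooLarge):
            enumerate_states(ped, max_bits=10)


def _orbit(state, masks):
    """Brute-force orbit of a state under all founder-flip compositions."""
    out = set()
    f = len(masks)
    for s in range(1 << f):
        x = state
        for i in range(f):
            if (s >> i) & 1:
                x ^= int(masks[i])
        out.add(x)
    return out


class TestFounderSymmetry:
    def test_sib2_four_classes_of_four(self, sib2):
        fc = founder_symmetry_classes(sib2)
        assert fc.n_classes == 4
        assert list(fc.sizes()) == [4, 4, 4, 4]

    def test_trio_single_class(self, trio):
        fc = founder_symmetry_classes(trio)
        assert fc.n_classes == 1

    @pytest.mark.parametrize("structure", ["Sib2", "Nuc4", "Nuc6", "Ext10"])
    def test_classes_match_brute_force_orbits(self, structure):
        ped = pedigree_template(structure)
        fc = founder_symmetry_classes(ped)
        masks = founder_flip_masks(ped)
        rng = np.random.default_rng(5)
        for state in rng.integers(0, ped.n_states, size=20):
            orbit = _orbit(int(state), masks)
            ids = {fc.class_of[x] for x in orbit}
            assert ids == {fc.class_of[int(state)]}  # orbit maps to one class
            assert len(orbit) == fc.sizes()[fc.class_of[int(state)]]

    def test_partition_properties(self, nuc4):
        fc = founder_symmetry_classes(nuc4)
        # covering & disjoint: every state in exactly one class
        assert fc.class_of.shape == (nuc4.n_states,)
        assert fc.sizes().sum() == nuc4.n_states
        # class count bound and reflexivity
        assert fc.n_classes >= nuc4.n_states >> nuc4.f
        assert all(fc.class_of[r] == i for i, r in enumerate(fc.reps))


class TestIbd:
    def test_parent_child_always_one(self, nuc4):
        for k in range(nuc4.n_states):
            assert ibd_from_iv(nuc4, k, "FA", "C1") == 1

    def test_sib_extremes(self, nuc4):
        assert ibd_from_iv(nuc4, 0b0000, "C1", "C2") == 2  # identical meioses
        assert ibd_from_iv(nuc4, 0b1100, "C1", "C2") == 0  # both bits differ

    def test_sib_pair_expectation_is_one(self, sib2):
        a, b = "S1", "S2"
        vals = [ibd_from_iv(sib2, k, a, b) for k in range(sib2.n_states)]
        assert set(vals) <= {0, 1, 2}
        assert np.mean(vals) == pytest.approx(1.0, abs=1e-15)
        # prior (1/4, 1/2, 1/4) over IBD 0/1/2
        counts = np.bincount(vals, minlength=3) / len(vals)
        assert np.allclose(counts, [0.25, 0.5, 0.25])

    def test_ibd_invariant_within_symmetry_class(self, nuc4):
        fc = founder_symmetry_classes(nuc4)
        tracks = np.array(
            [ibd_from_iv(nuc4, k, "C1", "C2") for k in range(nuc4.n_states)]
        )
        for cls in range(fc.n_classes):
            assert len(set(tracks[fc.class_of == cls])) == 1

    def test_unknown_member_rejected(self, nuc4):
        with pytest.raises(PedigreeError):
            ibd_from_iv(nuc4, 0, "FA", "nope")

    def test_vectorized_labels_match_scalar(self, nuc4):
        lab_all = allele_labels_all(nuc4)
        for k in (0, 5, 9, 15):
            assert np.array_equal(lab_all[k], allele_labels(nuc4, k))
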