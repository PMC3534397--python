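import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactfold import (
    ContactBase,
    ContactDefinition,
    CorruptionModel,
    PairwiseAlignment,
    alignment_sensitivity,
    build_contact_map,
    corrupt_alignment,
    fraction_common_contacts,
    make_benchmark,
    make_coil,
    make_fold_family,
    make_helix,
    make_sheet,
)
from contactfold.synthetic import (
    _fold_spec,
    build_fold_structure,
    min_nonadjacent_ca_distance,
)

CB65 = ContactDefinition(ContactBase.CB, 6.5)
CA65 = ContactDefinition(ContactBase.CA, 6.5)


class TestMakeHelix:
    def test_constant_rise_between_neighbours(self):
        h = make_helix(12)
        ca = np.array([r.ca for r in h.residues])
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(steps, steps[0])

    def test_i_i3_i4_are_the_close_pairs(self):
        # closed-form coordinates: i/i+3 and i/i+4 fall inside 6.5 A,
        # i/i+5 and beyond fall outside
        h = make_helix(12)
        ca = np.array([r.ca for r in h.residues])
        d = lambda i, j: np.linalg.norm(ca[i] - ca[j])
        assert d(0, 3) < 6.5 and d(0, 4) < 6.5
        assert d(0, 5) > 6.5
        assert d(0, 3) < d(0, 4)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            make_helix(3)

    def test_cb_is_member_of_heavy_atoms(self):
        h = make_helix(6)
        for r in h.residues:
            assert any(np.allclose(r.cb, a) for a in r.heavy_atoms)


class TestMakeSheet:
    def test_cross_strand_ca_pairs_within_contact_range(self):
        sh = make_sheet(2, 6)
        ca = np.array([r.ca for r in sh.residues])
        # antiparallel pairing: residue k of strand 1 faces residue
        # (2L - 1 - k) of strand 2 at the same x position
        for k in range(6):
            assert np.linalg.norm(ca[k] - ca[11 - k]) <= 6.5

    def test_alternating_cb_pairs_point_apart(self):
        sh = make_sheet(2, 6)
        ca = np.array([r.ca for r in sh.residues])
        cb = np.array([r.cb for r in sh.residues])
        # one-slot-offset cross pairs have opposite pleat: Cbeta further
        # apart than Calpha
        found = 0
        for k in range(5):
            partner = 11 - (k + 1)
            dca = np.linalg.norm(ca[k] - ca[partner])
            dcb = np.linalg.norm(cb[k] - cb[partner])
            if dcb > dca:
                found += 1
        assert found == 5

    def test_ca_base_sees_more_cross_strand_contacts_than_cb(self):
        sh = make_sheet(3, 8)
        strand_of = lambda i: (i - 1) // 8
        cross = lambda m: {
            (i, j) for i, j in m.contacts if strand_of(i) != strand_of(j)
        }
        n_ca = len(cross(build_contact_map(sh, CA65)))
        n_cb = len(cross(build_contact_map(sh, CB65)))
        assert n_ca > n_cb

    @pytest.mark.parametrize("n_strands,strand_len", [(1, 6), (2, 2)])
    def test_invalid_sizes(self, n_strands, strand_len):
        with pytest.raises(ValueError):
            make_sheet(n_strands, strand_len)


class TestFoldSpecs:
    @pytest.mark.parametrize("fold_idx", range(10))
    def test_no_steric_clash(self, fold_idx):
        s, _ = build_fold_structure(_fold_spec(fold_idx))
        assert min_nonadjacent_ca_distance(s) >= 3.5

    def test_kinds_cover_all_residues(self):
        spec = _fold_spec(0)
        s, kinds = build_fold_structure(spec)
        assert len(kinds) == s.length
        assert set(kinds) <= {"helix", "strand", "loop"}


class TestMakeFoldFamily:
    def test_zero_noise_members_identical(self):
        members, gold = make_fold_family(_fold_spec(0), 3, noise_sigma=0.0, seed=1)
        ca0 = np.array([r.ca for r in members[0].residues])
        ca1 = np.array([r.ca for r in members[1].residues])
        np.testing.assert_allclose(ca0, ca1)
        a = gold[(members[0].id, members[1].id)]
        assert a.pairs == tuple((i, i) for i in range(1, members[0].length + 1))

    def test_zero_noise_self_fcc_is_contacted_fraction(self):
        members, gold = make_fold_family(_fold_spec(0), 2, noise_sigma=0.0, seed=1)
        m0 = build_contact_map(members[0], CB65)
        m1 = build_contact_map(members[1], CB65)
        a = gold[(members[0].id, members[1].id)]
        res = fraction_common_contacts(m0, m1, a)
        contacted = {i for pair in m0.contacts for i in pair}
        assert res.fcc == pytest.approx(len(contacted) / members[0].length)

    def test_within_family_fcc_beats_between_family(self):
        spec_a, spec_b = _fold_spec(0), _fold_spec(1)
        fam_a, gold_a = make_fold_family(spec_a, 8, noise_sigma=0.5, seed=2)
        fam_b, _ = make_fold_family(spec_b, 8, noise_sigma=0.5, seed=3)
        maps_a = [build_contact_map(s, CB65) for s in fam_a]
        maps_b = [build_contact_map(s, CB65) for s in fam_b]
        within = [
            fraction_common_contacts(
                maps_a[i], maps_a[j], gold_a[(fam_a[i].id, fam_a[j].id)]
            ).fcc
            for i in range(8)
            for j in range(i + 1, 8)
        ]
        # between-family comparison through a naive full identity alignment
        between = []
        for ma in maps_a:
            for mb in maps_b:
                n = min(ma.length, mb.length)
                a = PairwiseAlignment(
                    ma.structure_id, mb.structure_id,
                    tuple((i, i) for i in range(1, n + 1)),
                )
                between.append(fraction_common_contacts(ma, mb, a).fcc)
        assert np.mean(within) > np.mean(between)

    def test_seed_determinism(self):
        m1, g1 = make_fold_family(_fold_spec(2), 3, seed=9)
        m2, g2 = make_fold_family(_fold_spec(2), 3, seed=9)
        m3, _ = make_fold_family(_fold_spec(2), 3, seed=10)
        np.testing.assert_array_equal(
            [r.ca for r in m1[0].residues], [r.ca for r in m2[0].residues]
        )
        assert g1 == g2
        assert not np.allclose(
            [r.ca for r in m1[0].residues], [r.ca for r in m3[0].residues]
        )

    def test_indels_restricted_to_loops_and_gold_consistent(self):
        members, gold = make_fold_family(
            _fold_spec(0), 4, noise_sigma=0.2, indel_prob=0.5, seed=5
        )
        base, kinds = build_fold_structure(_fold_spec(0))
        n_loops = kinds.count("loop")
        for m in members:
            assert m.length >= base.length - n_loops
        for a in gold.values():
            assert len(a.pairs) >= base.length - 2 * n_loops


class TestCorruptAlignment:
    def gold(self, n=40):
        return PairwiseAlignment("q", "t", tuple((i, i) for i in range(1, n + 1)))

    def test_identity_when_disabled(self):
        model = CorruptionModel(shift_prob=0.0, unaligned_prob=0.0, seed=1)
        assert corrupt_alignment(self.gold(), model).pairs == self.gold().pairs

    def test_full_unit_shift_sensitivity(self):
        gold = self.gold(30)
        model = CorruptionModel(
            shift_prob=1.0, max_shift=1, block_length=1000.0,
            unaligned_prob=0.0, seed=2,
        )
        corrupted = corrupt_alignment(gold, model)
        # whole-alignment +-1 block shift
        offsets = {t - q for q, t in corrupted.pairs}
        assert offsets in ({1}, {-1})
        assert alignment_sensitivity(corrupted, gold, 0) == 0.0
        s2 = alignment_sensitivity(corrupted, gold, 2)
        assert s2 == pytest.approx(len(corrupted.pairs) / len(gold.pairs))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_output_always_monotone(self, seed):
        model = CorruptionModel(
            shift_prob=0.7, max_shift=5, block_length=4.0,
            unaligned_prob=0.2, seed=seed,
        )
        c = corrupt_alignment(self.gold(), model)
        qs = [q for q, _ in c.pairs]
        ts = [t for _, t in c.pairs]
        assert qs == sorted(set(qs))
        assert ts == sorted(set(ts))

    def test_sensitivity_decreases_with_shift_prob(self):
        gold = self.gold(60)
        sens = []
        for p in (0.0, 0.5, 1.0):
            vals = [
                alignment_sensitivity(
                    corrupt_alignment(
                        gold,
                        CorruptionModel(shift_prob=p, max_shift=3,
                                        unaligned_prob=0.0, seed=s),
                    ),
                    gold,
                    0,
                )
                for s in range(40)
            ]
            sens.append(np.mean(vals))
        assert sens[0] > sens[1] > sens[2]


class TestMakeBenchmark:
    def test_shapes_and_labels(self):
        b = make_benchmark(5, 4, seed=0)
        assert len(b.structures) == 20
        assert len(b.index.entries) == 20
        folds = b.index.groups("fold")
        assert len(folds) == 5
        assert all(len(m) == 4 for m in folds.values())
        classes = {e.class_id for e in b.index.entries}
        assert classes == {"a", "b", "a/b", "a+b"}

    def test_alignments_cover_all_pairs(self):
        b = make_benchmark(3, 3, seed=0)
        n = len(b.structures)
        assert len(b.alignments) == n * (n - 1) // 2

    def test_determinism(self):
        b1 = make_benchmark(3, 2, seed=5)
        b2 = make_benchmark(3, 2, seed=5)
        for sid in b1.structures:
            np.testing.assert_array_equal(
                [r.ca for r in b1.structures[sid].residues],
                [r.ca for r in b2.structures[sid].residues],
            )
        assert b1.alignments == b2.alignments

    def test_corruption_keeps_gold_alongside(self):
        model = CorruptionModel(shift_prob=0.5, seed=1)
        b = make_benchmark(3, 2, seed=5, corruption=model)
        assert set(b.gold_alignments) == set(b.alignments)
        changed = sum(
            b.alignments[k].pairs != b.gold_alignments[k].pairs
            for k in b.alignments
        )
        assert changed > 0

    def test_too_few_folds_errors(self):
        with pytest.raises(ValueError):
            make_benchmark(1, 4)

    def test_class_mix_restricts_archetypes(self):
        b = make_benchmark(4, 2, class_mix=["a", "b"], seed=0)
        classes = [
            b.index.class_of_group(f) for f in sorted(b.index.groups("fold"))
        ]
        assert classes == ["a", "b", "a", "b"]


class TestMakeCoil:
    def test_deterministic_and_step_length(self):
        c1 = make_coil(20, seed=3)
        c2 = make_coil(20, seed=3)
        ca = np.array([r.ca for r in c1.residues])
        np.testing.assert_array_equal(ca, [r.ca for r in c2.residues])
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8)
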