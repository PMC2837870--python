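"""Energy terms: hard core, contacts, H-bonds, short-range bias."""

import numpy as np
import pytest

import loopcg as lc
from loopcg.forcefield import (ConformationEvaluator, EnergyModel,
                               _pseudo_atoms, excluded_volume, hbond_energy,
                               pair_contact_energy, short_range_energy)
from loopcg.lattice import LatticeConformation


@pytest.fixture(scope="module")
def model():
    return EnergyModel()


def conf_from_xyz(xyz, sequence, vset):
    """Wrap raw coordinates as an (off-grid) conformation for term tests.

    The energy terms are pure geometry functions; they do not require the
    chain invariant, so tests can construct arbitrary geometries directly.
    """
    ca = np.round(np.asarray(xyz) / vset.spacing).astype(int)
    conf = LatticeConformation(sequence, ca, vset)
    return conf


class TestExcludedVolume:
    def test_extended_chain_is_clash_free(self, vset, model):
        xyz = np.c_[np.arange(10) * 3.8, np.zeros(10), np.zeros(10)]
        conf = conf_from_xyz(xyz, "A" * 10, vset)
        assert excluded_volume(conf, model) == 0.0

    def test_collapsed_pair_is_infinite(self, vset, model):
        xyz = np.c_[np.arange(6) * 3.8, np.zeros(6), np.zeros(6)]
        xyz[5] = xyz[0] + [1.0, 0, 0]
        conf = conf_from_xyz(xyz, "A" * 6, vset)
        assert excluded_volume(conf, model) == np.inf

    def test_matches_brute_force_scan(self, vset, model, rng):
        """The vectorized check agrees with an O(N^2) pair loop."""
        for _ in range(10):
            xyz = np.cumsum(rng.uniform(-1, 1, (30, 3)) * 2.5, axis=0)
            seq = "".join(rng.choice(list("AVLSEKG"), 30))
            conf = conf_from_xyz(xyz, seq, vset)
            got = excluded_volume(conf, model)
            x = conf.ca_xyz()
            _, cb = _pseudo_atoms(x, ConformationEvaluator(seq, model).sc_dist)
            expect = 0.0
            for i in range(30):
                for j in range(i + 2, 30):
                    if (np.linalg.norm(x[i] - x[j]) < model.hardcore_ca
                            or np.linalg.norm(cb[i] - cb[j]) < model.hardcore_cb):
                        expect = np.inf
            assert got == expect


PAIR_XYZ = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                     [7.6, 5.0, 3.0], [3.8, 5.0, 3.0], [0, 5.0, 3.0]], float)


class TestPairContacts:
    def test_pair_inside_well_scores_minus_eps(self, model):
        # two chains folded back so side chains approach at well distance
        ev = ConformationEvaluator("LAAAAL", model)
        from loopcg.forcefield import _pseudo_atoms as pa
        sc, _ = pa(PAIR_XYZ, ev.sc_dist)
        e = ev.pair_contact(sc)
        assert e < 0.0

    def test_all_pairs_beyond_rmax_score_zero(self, vset, model):
        xyz = np.c_[np.arange(8) * 3.8, np.zeros(8), np.zeros(8)]
        conf = conf_from_xyz(xyz, "L" * 8, vset)
        assert pair_contact_energy(conf, model) == 0.0

    def test_matches_brute_force_enumeration(self, vset, model, rng):
        from loopcg.forcefield import contact_key
        for _ in range(10):
            xyz = np.cumsum(rng.uniform(-1, 1, (20, 3)) * 3.0, axis=0) * 1.4
            seq = "".join(rng.choice(list("LKSAEVG"), 20))
            conf = conf_from_xyz(xyz, seq, vset)
            ev = ConformationEvaluator(seq, model)
            sc, _ = _pseudo_atoms(conf.ca_xyz(), ev.sc_dist)
            expect = 0.0
            for i in range(20):
                for j in range(i + 3, 20):
                    w = model.contacts[contact_key(seq[i], seq[j])]
                    d = np.linalg.norm(sc[i] - sc[j])
                    if d < w.r_rep:
                        expect += model.eps_rep
                    elif w.r_min <= d <= w.r_max:
                        expect -= w.eps
            assert pair_contact_energy(conf, model) == pytest.approx(expect, abs=1e-9)

    def test_deeper_eps_strictly_lowers_energy(self):
        from loopcg.forcefield import _pseudo_atoms as pa
        shallow = EnergyModel()
        deep = EnergyModel()
        for k in deep.contacts:
            deep.contacts[k].eps += 0.5
        ev_s = ConformationEvaluator("LAAAAL", shallow)
        ev_d = ConformationEvaluator("LAAAAL", deep)
        sc, _ = pa(PAIR_XYZ, ev_s.sc_dist)
        assert ev_s.pair_contact(sc) < 0  # the geometry really has contacts
        assert ev_d.pair_contact(sc) < ev_s.pair_contact(sc)


def two_strand_xyz(n_per_strand=5, sep=5.0):
    """A hairpin-like geometry: two straight antiparallel strands at `sep` Å.

    Registered Cα pairs sit exactly `sep` apart with the pair axis
    perpendicular to both strand directions.
    """
    up = np.c_[np.zeros(n_per_strand), np.zeros(n_per_strand), np.arange(n_per_strand) * 3.8]
    down = up[::-1].copy()
    down[:, 1] = sep
    return np.vstack([up, down])


class TestHBonds:
    def test_registered_strands_count_bonds_and_cooperativity(self, model):
        """4 registered pairs (sequence separation >= 3) -> 4 bonds plus 3
        adjacent-pair cooperativity bonuses; the tight turn pair is excluded
        by the separation rule."""
        ev = ConformationEvaluator("A" * 10, model)
        p = model.hbond
        expect = -4 * p.e_hb - 3 * p.e_coop
        assert ev.hbond(two_strand_xyz()) == pytest.approx(expect)

    def test_isolated_extended_chain_has_none(self, vset, model):
        xyz = np.c_[np.arange(10) * 3.8, np.zeros(10), np.zeros(10)]
        conf = conf_from_xyz(xyz, "A" * 10, vset)
        assert hbond_energy(conf, model) == 0.0

    def test_rotation_invariant(self, model, rng):
        from scipy.spatial.transform import Rotation
        xyz0 = two_strand_xyz()
        ev = ConformationEvaluator("A" * 10, model)
        e0 = ev.hbond(xyz0)
        assert e0 < 0
        R = Rotation.random(random_state=3).as_matrix()
        assert ev.hbond(xyz0 @ R.T + rng.uniform(-5, 5, 3)) == pytest.approx(e0, abs=1e-9)


class TestShortRange:
    def test_helix_hits_generic_minimum_band(self, vset, model):
        from loopcg.forcefield import (R13_EDGES, R14_EDGES, _generic_tables,
                                       _uniform_bins)
        ca = lc.make_helix(12)
        ev = ConformationEvaluator("G" * 12, model)  # G: no sequence modulation
        e13, e14 = _generic_tables()
        # the helix descriptors land deep inside the helix wells
        r13 = np.linalg.norm(ca[2:] - ca[:-2], axis=1)
        b13 = _uniform_bins(r13, R13_EDGES)
        assert (e13[b13] <= -0.4).all()
        r14 = np.linalg.norm(ca[3:] - ca[:-3], axis=1)  # right-handed: positive
        b14 = _uniform_bins(r14, R14_EDGES)
        assert (e14[b14] <= -0.4).all()
        assert ev.short_range(ca) < 0

    def test_three_residue_chain_has_single_window(self, vset, model):
        xyz = np.array([[0, 0, 0], [3.8, 0, 0], [5.0, 3.6, 0]], float)
        ev = ConformationEvaluator("GGG", model)
        e = ev.short_range(xyz)
        # exactly one r13 term: recompute it by hand
        from loopcg.forcefield import R13_EDGES, _generic_tables, _uniform_bins
        e13, _ = _generic_tables()
        b = _uniform_bins(np.linalg.norm(xyz[2] - xyz[0], keepdims=True), R13_EDGES)
        assert e == pytest.approx(float(e13[b[0]]))

    def test_left_handed_helix_scores_worse(self, vset, model):
        right = lc.make_helix(12)
        left = right.copy()
        left[:, 0] *= -1  # mirror: inverts chirality
        ev = ConformationEvaluator("G" * 12, model)
        assert ev.short_range(left) > ev.short_range(right)


class TestTotals:
    def test_additivity_of_terms(self, hlh_conf, model, hlh_case):
        from loopcg.restraints import scaffold_restraints
        rs = scaffold_restraints(hlh_case, seed=0)
        total = lc.energy_total(hlh_conf, model, rs)
        parts = (excluded_volume(hlh_conf, model)
                 + short_range_energy(hlh_conf, model)
                 + pair_contact_energy(hlh_conf, model)
                 + hbond_energy(hlh_conf, model)
                 + lc.restraint_energy(hlh_conf, rs))
        assert total == pytest.approx(parts, abs=1e-9)

    def test_kernel_matches_reference_on_random_geometries(self, model, rng, hlh):
        structure, _ = hlh
        seq = structure.sequence
        ev = ConformationEvaluator(seq, model)
        base = structure.ca_coords()
        for _ in range(25):
            xyz = base + rng.normal(scale=0.6, size=base.shape)
            fast, ref = ev.total(xyz), ev.total_reference(xyz)
            if np.isfinite(ref):
                assert fast == pytest.approx(ref, abs=1e-9)
            else:
                assert fast == ref

    def test_overlapping_residues_give_inf_sentinel(self, vset, model):
        ca = np.zeros((4, 3), int)
        ca[1] = [5, 2, 0]
        ca[2] = [0, 0, 0]  # identical to residue 0
        ca[3] = [5, -2, 0]
        conf = LatticeConformation("AAAA", ca, vset)
        assert lc.energy_total(conf, model) == np.inf

    def test_rigid_motion_invariance(self, hlh_conf, model, rng):
        from scipy.spatial.transform import Rotation
        ev = ConformationEvaluator(hlh_conf.sequence, model)
        xyz = hlh_conf.ca_xyz()
        e0 = ev.total(xyz)
        for k in range(3):
            R = Rotation.random(random_state=k).as_matrix()
            e1 = ev.total(xyz @ R.T + rng.uniform(-20, 20, 3))
            assert e1 == pytest.approx(e0, abs=1e-8)

    def test_native_below_extended(self, hlh, model):
        """A compact native fold scores below its fully extended conformer."""
        structure, _ = hlh
        seq = structure.sequence
        ev = ConformationEvaluator(seq, model)
        n = len(seq)
        extended = np.c_[np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]
        assert ev.total(structure.ca_coords()) < ev.total(extended)
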