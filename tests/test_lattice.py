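"""Lattice vector set, chain projection and pseudo-atom rebuild."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import loopcg as lc
from loopcg.lattice import (CANONICAL_BOND, ChainBreakError, GeometryTable,
                            project_segments, rebuild_pseudoatoms,
                            sc_positions_from_xyz)


class TestVectorSet:
    def test_default_window_gives_800(self, vset):
        assert len(vset) == 800

    @pytest.mark.parametrize("window,expected", [((1, 1), 6), ((2, 2), 12)])
    def test_small_windows_by_symmetry(self, window, expected):
        assert len(lc.build_vector_set(window=window)) == expected

    def test_lengths_band_around_canonical_bond(self, vset):
        lengths = np.linalg.norm(vset.vectors, axis=1) * vset.spacing
        assert lengths.min() > 3.2 and lengths.max() < 4.3
        assert abs(np.median(lengths) - CANONICAL_BOND) < 0.3

    def test_closed_under_cube_symmetries(self, vset):
        vs = {tuple(v) for v in vset.vectors}
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = rng.permutation(3)
            signs = rng.choice([-1, 1], 3)
            mapped = {tuple(np.array(v)[perm] * signs) for v in vs}
            assert mapped == vs

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            lc.build_vector_set(window=(0, 0))

    def test_id_index_is_bijective(self, vset):
        ids = {vset.vector_id(v) for v in vset.vectors}
        assert ids == set(range(1, len(vset) + 1))
        v = vset.vector(17)
        assert vset.vector_id(v) == 17


class TestProjection:
    def test_on_lattice_trace_is_fixed_point(self, vset):
        ca = np.array([[0, 0, 0], [5, 2, 0], [10, 4, 0], [13, 8, 3]]) * vset.spacing
        conf, rmsd = lc.project_chain(ca, vset)
        assert rmsd < 1e-9
        conf.validate()

    def test_ideal_helix_projects_well(self, vset):
        ca = lc.make_helix(20)
        conf, rmsd = lc.project_chain(ca, vset)
        conf.validate()
        assert rmsd <= 0.5

    def test_chain_break_names_position(self, vset):
        ca = lc.make_helix(10)
        ca[5:] += 30.0
        with pytest.raises(ChainBreakError, match="4->5"):
            lc.project_chain(ca, vset)

    def test_lift_distance_equals_reported_rmsd(self, vset):
        ca = lc.make_helix(15)
        conf, rmsd = lc.project_chain(ca, vset)
        lifted = lc.lift_to_cartesian(conf)
        again = float(np.sqrt(((lifted - ca) ** 2).sum(axis=1).mean()))
        assert again == pytest.approx(rmsd, abs=1e-12)

    def test_projection_idempotent(self, vset):
        ca = lc.make_helix(12)
        conf1, _ = lc.project_chain(ca, vset)
        conf2, rmsd2 = lc.project_chain(lc.lift_to_cartesian(conf1), vset)
        assert rmsd2 < 1e-9
        np.testing.assert_array_equal(np.diff(conf1.ca, axis=0),
                                      np.diff(conf2.ca, axis=0))

    def test_per_residue_error_ceiling(self, vset, rng):
        """No residue drifts beyond nearest-vertex rounding + one lattice unit."""
        ca = lc.make_helix(30) + rng.normal(scale=0.05, size=(30, 3))
        conf, _ = lc.project_chain(ca, vset)
        err = np.linalg.norm(lc.lift_to_cartesian(conf) - ca, axis=1)
        ceiling = (np.sqrt(3) * 0.5 + 1.0) * vset.spacing
        assert (err <= ceiling + 1e-9).all()

    def test_mean_rmsd_meets_lattice_accuracy(self, vset):
        """Protein-like traces project at ~0.35 Å or better on average."""
        rng = np.random.default_rng(7)
        rmsds = []
        for k in range(12):
            n = int(rng.integers(20, 50))
            ca = _protein_like_trace(n, rng)
            _, r = lc.project_chain(ca, vset)
            rmsds.append(r)
        assert np.mean(rmsds) <= 0.35

    def test_segments_share_one_frame(self, vset):
        ca = lc.make_helix(20)
        pos, offset, rmsd = project_segments([ca[:9], ca[12:]], vset)
        assert rmsd < 0.5
        lifted = (pos[0] - offset) * vset.spacing
        assert np.allclose(lifted, ca[:9], atol=3 * vset.spacing)


def _protein_like_trace(n, rng):
    pts = [np.zeros(3)]
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    for _ in range(n - 1):
        d = d + 0.8 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * rng.uniform(3.7, 3.9))
    return np.array(pts)


class TestPseudoAtoms:
    def test_mid_is_exact_midpoint(self, hlh_conf):
        cb, sc, mid = rebuild_pseudoatoms(hlh_conf)
        xyz = hlh_conf.ca_xyz()
        np.testing.assert_allclose(mid, 0.5 * (xyz[:-1] + xyz[1:]), atol=1e-12)

    def test_glycine_sidechain_is_calpha(self, vset):
        ca = lc.make_helix(8)
        conf, _ = lc.project_chain(ca, vset, sequence="AGAGAGAG")
        cb, sc, _ = rebuild_pseudoatoms(conf)
        xyz = conf.ca_xyz()
        for i, aa in enumerate(conf.sequence):
            if aa == "G":
                np.testing.assert_allclose(sc[i], xyz[i], atol=1e-12)
            else:
                assert np.linalg.norm(sc[i] - xyz[i]) > 1.0

    def test_same_id_pair_same_offset(self, vset):
        """Table lookups are deterministic: repeated contexts give identical offsets."""
        table = GeometryTable(vset)
        v1, v2 = vset.vectors[10], vset.vectors[500]
        id1, id2 = vset.vector_id(v1), vset.vector_id(v2)
        off1 = table.cb_offset(id1, id2)
        off2 = table.cb_offset(id1, id2)
        np.testing.assert_array_equal(off1, off2)
        assert np.linalg.norm(off1) == pytest.approx(1.53, abs=1e-9)

    def test_table_text_round_trip(self, vset, tmp_path):
        table = GeometryTable(vset)
        table.cb_offset(3, 77)
        table.cb_offset(150, 400)
        path = tmp_path / "geom.txt"
        table.to_text(path)
        back = GeometryTable.from_text(path, vset)
        np.testing.assert_allclose(back.cb_offset(3, 77), table.cb_offset(3, 77), atol=1e-6)

    def test_vectorized_sc_matches_table_path(self, hlh_conf):
        cb, sc, _ = rebuild_pseudoatoms(hlh_conf)
        sc_fast = sc_positions_from_xyz(hlh_conf.ca_xyz(), hlh_conf.sequence)
        np.testing.assert_allclose(sc_fast, sc, atol=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_lift_is_scaling_plus_offset(seed):
    """Lifting is exactly (ca - offset) * spacing for any conformation."""
    rng = np.random.default_rng(seed)
    vset = lc.build_vector_set()
    n = int(rng.integers(3, 12))
    ca = np.cumsum(np.vstack([[0, 0, 0],
                              vset.vectors[rng.integers(0, 800, n - 1)]]), axis=0)
    conf = lc.LatticeConformation("A" * n, ca, vset, offset=rng.random(3))
    np.testing.assert_allclose(lc.lift_to_cartesian(conf),
                               (ca - conf.offset) * vset.spacing, atol=1e-12)
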