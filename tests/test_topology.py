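import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saxsflex as sx
from saxsflex.errors import GeometryError, TopologyError
from saxsflex.topology import (BeadModel, fuse_collinear,
                               read_beads_pdb, write_beads_pdb)


# ---------------------------------------------------------------------------
# build_topology
# ---------------------------------------------------------------------------

def _arm(n, seed=0):
    return sx.make_toy_rigid_arm(n, 1.4 * (n - 1), 8.0, seed=seed)


class TestBuildTopology:
    def test_desmoplakin_style_hinge_has_37_residues(self):
        topo = sx.build_topology([
            dict(kind="rigid", start=560, end=626, label="arm1", template=_arm(67)),
            dict(kind="flexible", start=627, end=663, label="hinge"),
            dict(kind="rigid", start=664, end=700, label="arm2", template=_arm(37)),
        ])
        hinge = topo.flexible_segments[0]
        assert hinge.n_residues == 37
        assert topo.hinge_length == 37

    def test_single_rigid_segment_is_valid_with_zero_hinge(self):
        topo = sx.build_topology([
            dict(kind="rigid", start=1, end=100, template=_arm(100))])
        assert topo.hinge_length == 0
        assert topo.n_residues == 100

    def test_periplakin_style_hinge_has_8_residues(self):
        # oracle: brute-force enumeration of the inclusive range
        assert len(list(range(496, 503 + 1))) == 8
        topo = sx.build_topology([
            dict(kind="rigid", start=400, end=495, label="arm1", template=_arm(96)),
            dict(kind="flexible", start=496, end=503, label="hinge"),
            dict(kind="rigid", start=504, end=600, label="arm2", template=_arm(97)),
        ])
        assert topo.hinge_length == 8

    def test_overlapping_ranges_rejected_naming_segments(self):
        with pytest.raises(TopologyError, match="overlap.*arm1.*hinge"):
            sx.build_topology([
                dict(kind="rigid", start=1, end=50, label="arm1", template=_arm(50)),
                dict(kind="flexible", start=45, end=60, label="hinge"),
            ])

    def test_gapped_ranges_rejected(self):
        with pytest.raises(TopologyError, match="gap"):
            sx.build_topology([
                dict(kind="rigid", start=1, end=50, label="a", template=_arm(50)),
                dict(kind="flexible", start=60, end=70, label="b"),
            ])

    def test_adjacent_flexible_segments_are_merged(self):
        topo = sx.build_topology([
            dict(kind="rigid", start=1, end=10, template=_arm(10)),
            dict(kind="flexible", start=11, end=15),
            dict(kind="flexible", start=16, end=20),
        ])
        assert len(topo.segments) == 2
        assert topo.segments[1].n_residues == 10

    def test_all_flexible_rejected(self):
        with pytest.raises(TopologyError, match="rigid"):
            sx.build_topology([dict(kind="flexible", start=1, end=10)])

    def test_template_length_mismatch_rejected(self):
        with pytest.raises(TopologyError, match="template"):
            sx.build_topology([
                dict(kind="rigid", start=1, end=10, label="bad", template=_arm(9))])

    def test_residue_count_identity(self, two_arm_topology):
        topo = two_arm_topology
        assert topo.n_residues == topo.last_residue - topo.first_residue + 1


# ---------------------------------------------------------------------------
# make_toy_rigid_arm
# ---------------------------------------------------------------------------

class TestToyArm:
    def test_minimal_two_bead_chain_on_axis(self):
        arm = sx.make_toy_rigid_arm(2, 3.8, radius=0.0)
        assert arm.n_beads == 2
        np.testing.assert_allclose(np.linalg.norm(arm.coords[1] - arm.coords[0]),
                                   3.8)
        # both beads on the x axis
        np.testing.assert_allclose(arm.coords[:, 1:], 0.0, atol=1e-12)

    def test_spectrin_like_arm_matches_cylinder_rg(self):
        # analytic oracle: uniform cylinder Rg^2 = L^2/12 + R^2/2
        arm = sx.make_toy_rigid_arm(106, 50.0, 8.0, seed=3)
        cyl = math.sqrt(50.0**2 / 12.0 + 8.0**2 / 2.0)
        assert abs(arm.rg() - cyl) / cyl < 0.10

    def test_same_seed_identical(self):
        a = sx.make_toy_rigid_arm(20, 25.0, 6.0, seed=9)
        b = sx.make_toy_rigid_arm(20, 25.0, 6.0, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_different_seed_differs(self):
        a = sx.make_toy_rigid_arm(20, 25.0, 6.0, seed=1)
        b = sx.make_toy_rigid_arm(20, 25.0, 6.0, seed=2)
        assert not np.allclose(a.coords, b.coords)

    def test_impossible_length_raises(self):
        with pytest.raises(GeometryError):
            sx.make_toy_rigid_arm(10, 3.8 * 9 + 1.0, 5.0)

    def test_bond_lengths_in_chain_range(self):
        arm = sx.make_toy_rigid_arm(50, 1.4 * 49, 8.0, seed=5)
        arm.validate_chain()  # must not raise

    @pytest.mark.parametrize("n", [10, 40])
    def test_rg_and_dmax_monotone_in_length(self, n):
        lengths = [0.5 * (n - 1), 1.5 * (n - 1), 3.0 * (n - 1)]
        rgs = [sx.make_toy_rigid_arm(n, L, 8.0, seed=0).rg() for L in lengths]
        dmaxes = [sx.make_toy_rigid_arm(n, L, 8.0, seed=0).dmax() for L in lengths]
        assert rgs == sorted(rgs)
        assert dmaxes == sorted(dmaxes)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

PDB_3RES = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

PDB_MISSING_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


class TestPdbIO:
    def test_three_residue_readback(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3RES)
        beads = sx.load_pdb_as_beads(p)
        assert beads.n_beads == 3
        np.testing.assert_allclose(beads.coords[:, 0], [0.0, 3.8, 7.6])
        np.testing.assert_array_equal(beads.residue_ids, [1, 2, 3])

    def test_first_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        beads = sx.load_pdb_as_beads(p)
        assert beads.n_beads == 2
        np.testing.assert_allclose(beads.coords[0], [1.0, 0.0, 0.0])

    def test_missing_ca_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "gap.pdb"
        p.write_text(PDB_MISSING_CA)
        import logging

        with caplog.at_level(logging.WARNING, logger="saxsflex.topology"):
            beads = sx.load_pdb_as_beads(p)
        assert beads.n_beads == 2
        assert any("no CA" in r.message for r in caplog.records)

    def test_empty_selection_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            sx.load_pdb_as_beads(p)

    def test_bead_pdb_roundtrip(self, tmp_path):
        arm = sx.make_toy_rigid_arm(15, 20.0, 5.0, seed=4)
        p = tmp_path / "arm.pdb"
        write_beads_pdb(arm, p)
        back = read_beads_pdb(p)[0]
        np.testing.assert_allclose(back.coords, arm.coords, atol=1e-3)

    def test_multi_model_roundtrip(self, tmp_path):
        arms = [sx.make_toy_rigid_arm(8, 10.0, 4.0, seed=s) for s in range(3)]
        p = tmp_path / "multi.pdb"
        write_beads_pdb(arms, p)
        back = read_beads_pdb(p)
        assert len(back) == 3
        for a, b in zip(arms, back):
            np.testing.assert_allclose(b.coords, a.coords, atol=1e-3)


# ---------------------------------------------------------------------------
# Topology serialization round-trip
# ---------------------------------------------------------------------------

def test_topology_yaml_roundtrip(tmp_path, two_arm_topology):
    path = tmp_path / "topo.yaml"
    sx.save_topology(two_arm_topology, path, template_dir=tmp_path / "templates")
    back = sx.load_topology(path)
    assert len(back.segments) == len(two_arm_topology.segments)
    for a, b in zip(back.segments, two_arm_topology.segments):
        assert (a.kind, a.start, a.end, a.label) == (b.kind, b.start, b.end, b.label)
        if b.template is not None:
            np.testing.assert_allclose(a.template.coords, b.template.coords,
                                       atol=1e-3)


# ---------------------------------------------------------------------------
# BeadModel and fuse_collinear
# ---------------------------------------------------------------------------

class TestBeadModel:
    def test_single_bead_minimum(self):
        with pytest.raises(ValueError):
            BeadModel(np.empty((0, 3)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            BeadModel(np.array([[0.0, 0.0, np.inf]]))

    def test_two_bead_rg_dmax(self):
        m = BeadModel(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        assert m.rg() == pytest.approx(5.0)
        assert m.dmax() == pytest.approx(10.0)


def test_fuse_collinear_extends_along_x():
    # straight rods so the axial extent is exact
    a = sx.make_toy_rigid_arm(10, 3.8 * 9, 0.0)
    b = sx.make_toy_rigid_arm(8, 3.8 * 7, 0.0)
    fused = fuse_collinear([a, b])
    assert fused.n_beads == 18
    extent = fused.coords[:, 0].max() - fused.coords[:, 0].min()
    assert extent == pytest.approx(3.8 * 9 + 3.8 * 7 + 3.8, abs=1e-6)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=3, max_value=40),
       st.floats(min_value=0.5, max_value=3.5))
def test_toy_arm_property_axial_extent(n, rise):
    arm = sx.make_toy_rigid_arm(n, rise * (n - 1), 8.0, seed=0)
    extent = arm.coords[:, 0].max() - arm.coords[:, 0].min()
    assert extent == pytest.approx(rise * (n - 1), rel=1e-9)
    arm.validate_chain()
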