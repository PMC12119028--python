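"""Structure metrics on generated toy coordinates."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gemmi

from ryrgate.structure_metrics import (
    CENTRAL_ALIGN_INTERVALS,
    EXTENDED_REACH,
    HBOND_LENGTH,
    ResidueLookupError,
    StructureFrame,
    align_on_domain,
    apply_rigid,
    ca_distance,
    estimate_symmetry_axis,
    extended_sidechain_reach,
    flexion_angle,
    make_ca_chain,
    make_tetramer,
    max_interaction_distance,
    rmsd100,
    _SIDECHAIN_ZMAT,
)


@pytest.fixture()
def helix():
    return StructureFrame.from_atoms(make_ca_chain(120, "A"), source_id="helix")


class TestCaDistance:
    def test_identical_selection_is_zero(self, helix):
        assert ca_distance(helix, ("A", 10), ("A", 10)) == 0.0

    def test_three_four_five_triangle(self):
        frame = StructureFrame.from_atoms([
            ("A", 1, "GLY", "CA", 0.0, 0.0, 0.0),
            ("A", 2, "GLY", "CA", 3.0, 4.0, 0.0),
        ])
        assert ca_distance(frame, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_against_direct_coordinate_arithmetic(self, helix):
        # brute-force oracle straight from the generated records
        records = {r[1]: np.array(r[4:]) for r in make_ca_chain(120, "A")}
        for a, b in [(1, 120), (5, 37), (60, 61)]:
            expected = math.sqrt(sum((records[a][i] - records[b][i]) ** 2 for i in range(3)))
            assert ca_distance(helix, ("A", a), ("A", b)) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_triangle_inequality(self, helix):
        rng = np.random.default_rng(2)
        for _ in range(25):
            i, j, k = rng.integers(1, 121, size=3)
            dij = ca_distance(helix, ("A", int(i)), ("A", int(j)))
            dji = ca_distance(helix, ("A", int(j)), ("A", int(i)))
            dik = ca_distance(helix, ("A", int(i)), ("A", int(k)))
            dkj = ca_distance(helix, ("A", int(k)), ("A", int(j)))
            assert dij == dji
            assert dij <= dik + dkj + 1e-12

    def test_missing_calpha_is_reported_by_name(self, helix):
        with pytest.raises(ResidueLookupError, match="A:999"):
            ca_distance(helix, ("A", 1), ("A", 999))


class TestMaxInteractionDistance:
    def test_degenerate_reach_gives_hbond_length(self):
        zero = {"D": 0.0, "E": 0.0, "K": 0.0, "R": 0.0}
        assert max_interaction_distance("D", "K", reach=zero) == pytest.approx(2.7)

    def test_argument_order_irrelevant(self):
        assert max_interaction_distance("E", "R") == max_interaction_distance("R", "E")
        assert max_interaction_distance("D", "K") == max_interaction_distance("K", "D")

    @pytest.mark.parametrize("pair", [("A", "K"), ("D", "E"), ("K", "R"), ("D", "X")])
    def test_unsupported_residues_rejected(self, pair):
        with pytest.raises(ValueError):
            max_interaction_distance(*pair)

    def test_reach_against_independent_geometry_oracle(self):
        # re-measure the extended side chains by an independent route:
        # complex-number cumulative rotations instead of the 2D zig-zag
        for code, name in [("D", "ASP"), ("E", "GLU"), ("K", "LYS"), ("R", "ARG")]:
            zmat = _SIDECHAIN_ZMAT[name]
            pos = 0 + 0j
            heading = 0.0
            for i, (length, angle) in enumerate(zmat):
                if angle is not None:
                    turn = math.radians(180.0 - angle)
                    heading += turn if i % 2 else -turn
                pos += length * complex(math.cos(heading), math.sin(heading))
            assert EXTENDED_REACH[code] == pytest.approx(abs(pos), rel=1e-12)
        # and the physically expected ordering of reaches
        assert EXTENDED_REACH["D"] < EXTENDED_REACH["E"] < EXTENDED_REACH["K"] < EXTENDED_REACH["R"]
        assert max_interaction_distance("E", "R") == pytest.approx(
            EXTENDED_REACH["E"] + EXTENDED_REACH["R"] + HBOND_LENGTH
        )


class TestAlignment:
    def test_self_alignment_is_identity(self, helix):
        tr, pairs = align_on_domain(helix, helix, [(1, 120)])
        assert len(pairs) == 120
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0.0, atol=1e-12)

    def test_rigid_motion_recovery(self, helix):
        rng = np.random.default_rng(4)
        for _ in range(5):
            rot = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0, 20, size=3)
            moved = apply_rigid(helix, rot, t)
            tr, _ = align_on_domain(moved, helix, [(1, 120)])
            assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
            # recovered transform inverts the applied motion
            assert np.allclose(tr.rotation @ rot, np.eye(3), atol=1e-8)
            res = rmsd100(moved, helix, [(21, 120)], [(1, 20)])
            assert res.rmsd < 1e-8

    def test_never_returns_a_reflection(self):
        # a near-planar point set invites an improper solution; Kabsch must not take it
        records = [("A", i + 1, "GLY", "CA", float(x), float(y), 0.01 * (i % 2))
                   for i, (x, y) in enumerate((xx, yy) for xx in range(4) for yy in range(4))]
        flat = StructureFrame.from_atoms(records)
        mirrored = apply_rigid(flat, np.diag([1.0, 1.0, -1.0]))
        tr, _ = align_on_domain(mirrored, flat, [(1, 16)])
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_common_residues(self, helix):
        other = StructureFrame.from_atoms(make_ca_chain(5, "A", start=500))
        with pytest.raises(ValueError, match="at least 3"):
            align_on_domain(other, helix, [(1, 120)])


def _shifted_domain_frames(n_domain, shift):
    """Reference chain plus a copy whose measured domain is rigidly shifted."""
    anchor = make_ca_chain(60, "A", start=1)
    domain = make_ca_chain(n_domain, "A", start=101, rise=1.5)
    ref = StructureFrame.from_atoms(anchor + [(c, r, n, a, x + 25.0, y, z)
                                              for c, r, n, a, x, y, z in domain])
    moved = StructureFrame.from_atoms(
        anchor + [(c, r, n, a, x + 25.0 + shift, y, z) for c, r, n, a, x, y, z in domain]
    )
    return moved, ref


class TestRmsd100:
    def test_normalization_identity_at_n100(self):
        moved, ref = _shifted_domain_frames(100, shift=3.0)
        res = rmsd100(moved, ref, [(101, 200)], [(1, 60)])
        assert res.n_residues == 100
        assert res.rmsd == pytest.approx(3.0, rel=1e-12)
        assert res.rmsd100 == pytest.approx(res.rmsd, rel=1e-12)
        assert res.significant  # 3.0 A > 2 A threshold

    def test_closed_form_at_n400(self):
        moved, ref = _shifted_domain_frames(400, shift=2.0)
        res = rmsd100(moved, ref, [(101, 500)], [(1, 60)])
        assert res.rmsd == pytest.approx(2.0, rel=1e-12)
        assert res.rmsd100 == pytest.approx(2.0 / (1.0 + math.log(2.0)), rel=1e-12)
        assert not res.significant  # 1.18 A < 2 A

    def test_self_comparison_not_significant(self):
        moved, ref = _shifted_domain_frames(100, shift=0.0)
        res = rmsd100(ref, ref, [(101, 200)], [(1, 60)])
        assert res.rmsd100 == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_invariant_under_shared_rigid_motion(self):
        moved, ref = _shifted_domain_frames(100, shift=2.5)
        base = rmsd100(moved, ref, [(101, 200)], [(1, 60)])
        rot = Rotation.from_euler("zyx", [11, -37, 101], degrees=True).as_matrix()
        t = np.array([12.0, -4.0, 7.5])
        res = rmsd100(apply_rigid(moved, rot, t), apply_rigid(ref, rot, t),
                      [(101, 200)], [(1, 60)])
        assert res.rmsd100 == pytest.approx(base.rmsd100, rel=1e-9)

    def test_short_domain_fails_or_warns(self):
        moved, ref = _shifted_domain_frames(13, shift=1.0)
        # 13 residues: the normalization factor crosses zero -> hard error
        with pytest.raises(ValueError, match="too short"):
            rmsd100(moved, ref, [(101, 113)], [(1, 60)])
        moved, ref = _shifted_domain_frames(18, shift=1.0)
        with pytest.warns(UserWarning, match="unreliable"):
            rmsd100(moved, ref, [(101, 118)], [(1, 60)])

    def test_domain_too_small(self):
        moved, ref = _shifted_domain_frames(100, shift=1.0)
        with pytest.raises(ValueError, match="at least 2"):
            rmsd100(moved, ref, [(101, 101)], [(1, 60)])


class TestFlexionAngle:
    def test_line_in_plane_is_zero(self):
        assert flexion_angle(make_tetramer(tilt_deg=0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_line_parallel_to_axis_is_ninety(self):
        frame = make_tetramer(tilt_deg=90.0)
        assert flexion_angle(frame) == pytest.approx(90.0, abs=1e-6)
        down = make_tetramer(tilt_deg=-90.0)
        assert flexion_angle(down) == pytest.approx(-90.0, abs=1e-6)

    @pytest.mark.parametrize("tilt", [7.0, -2.8, -13.5])
    def test_constructed_tilt_recovered(self, tilt):
        assert flexion_angle(make_tetramer(tilt_deg=tilt)) == pytest.approx(tilt, abs=1e-6)

    def test_invariant_under_rotation_about_axis(self):
        frame = make_tetramer(tilt_deg=-5.0)
        rot = Rotation.from_euler("z", 33.0, degrees=True).as_matrix()
        rotated = apply_rigid(frame, rot)
        assert flexion_angle(rotated, axis=(0, 0, 1)) == pytest.approx(-5.0, abs=1e-9)

    def test_explicit_axis_override(self):
        frame = make_tetramer(tilt_deg=12.0)
        assert flexion_angle(frame, axis=(0.0, 0.0, 2.0)) == pytest.approx(12.0, abs=1e-6)

    def test_axis_estimation_requires_enough_chains(self):
        single = StructureFrame.from_atoms(
            make_ca_chain(30, "A") + [("A", 348, "GLY", "CA", 10, 0, 0),
                                      ("A", 1052, "GLY", "CA", 20, 0, 5)]
        )
        with pytest.raises(ValueError, match="axis"):
            flexion_angle(single)


class TestStructureIo:
    def test_pdb_and_mmcif_round_trip(self, tmp_path):
        frame = make_tetramer(tilt_deg=7.0)
        pdb = tmp_path / "tetramer.pdb"
        cif = tmp_path / "tetramer.cif"
        frame.write_pdb(pdb)
        frame.write_mmcif(cif)
        for path in (pdb, cif):
            back = StructureFrame.from_file(path)
            assert set(back.chain_names) == {"A", "B", "C", "D"}
            # PDB stores 3 decimals; 1e-3 A coordinate granularity
            assert flexion_angle(back) == pytest.approx(7.0, abs=1e-2)

    def test_insertion_codes_rejected(self):
        st = gemmi.Structure()
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(1, "A")  # insertion code A
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.pos = gemmi.Position(0, 0, 0)
        res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        with pytest.raises(ValueError, match="insertion code"):
            StructureFrame(st)

    def test_highest_occupancy_altloc_kept(self):
        st = gemmi.Structure()
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(1, " ")
        for altloc, occ, x in [("A", 0.3, 1.0), ("B", 0.7, 2.0)]:
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.altloc = altloc
            atom.occ = occ
            atom.pos = gemmi.Position(x, 0, 0)
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        frame = StructureFrame(st)
        assert frame.ca("A", 1)[0] == pytest.approx(2.0)

    def test_domain_tables_are_consistent(self):
        from ryrgate.structure_metrics import DOMAIN_RANGES

        for iso, table in DOMAIN_RANGES.items():
            spans = sorted(iv for ivs in table.values() for iv in ivs)
            for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
                assert hi1 < lo2, f"overlapping domains in {iso}"
        # alignment intervals sit inside the rRyR1 Central domain
        cd_lo, cd_hi = DOMAIN_RANGES["rRyR1"]["CD"][0]
        for lo, hi in CENTRAL_ALIGN_INTERVALS:
            assert cd_lo <= lo <= hi <= cd_hi
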