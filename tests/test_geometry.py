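import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frthread.geometry import (
    BREAK,
    BackboneStructure,
    ChainBreakInFragment,
    ConformationBin,
    FragmentConformation,
    FragmentUndefined,
    GeometryError,
    N_JOINT_BINS,
    bend_angle,
    bin_conformation,
    bisector,
    conformation3,
    conformation9,
    dihedral,
    plane_vector,
    position_bins,
)
from frthread.synthetic import make_backbone

from ._oracles import dihedral_oracle


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_agrees_with_independent_formulation(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            pts = rng.normal(size=(4, 3)) * 3.0
            assert dihedral(*pts) == pytest.approx(dihedral_oracle(*pts), abs=1e-9)

    def test_mirror_flips_sign(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 2.0
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            d = dihedral(*pts)
            dm = dihedral(*mirrored)
            if abs(d) == pytest.approx(180.0, abs=1e-9):
                assert abs(dm) == pytest.approx(180.0, abs=1e-9)
            else:
                assert dm == pytest.approx(-d, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBendBisectorPlane:
    @pytest.mark.parametrize(
        "u,v,expected",
        [((1, 0, 0), (1, 0, 0), 0.0), ((1, 0, 0), (-1, 0, 0), 180.0), ((1, 0, 0), (0, 1, 0), 90.0)],
    )
    def test_bend_angle(self, u, v, expected):
        assert bend_angle(u, v) == pytest.approx(expected)

    def test_bend_zero_vector_raises(self):
        with pytest.raises(GeometryError):
            bend_angle((0, 0, 0), (1, 0, 0))

    def test_bisector_of_axes(self):
        np.testing.assert_allclose(
            bisector((1, 0, 0), (0, 1, 0)), [1 / np.sqrt(2), 1 / np.sqrt(2), 0], atol=1e-12
        )
        np.testing.assert_allclose(bisector((0, 0, 1), (0, 0, 1)), [0, 0, 1], atol=1e-12)

    def test_bisector_antiparallel_raises(self):
        with pytest.raises(GeometryError):
            bisector((0, 0, 1), (0, 0, -1))

    def test_plane_vector_hand_case(self):
        v = plane_vector((1, 0, 0), (0, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(v, [-1 / np.sqrt(2), 1 / np.sqrt(2), 0], atol=1e-12)

    def test_plane_vector_in_plane_and_orthogonal(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3)) * 2.0
            try:
                v = plane_vector(a, b, c)
            except GeometryError:
                continue
            normal = np.cross(a - b, c - b)
            normal /= np.linalg.norm(normal)
            assert abs(v @ normal) < 1e-12
            assert abs(v @ bisector(a - b, c - b)) < 1e-12
            assert v @ (c - b) >= 0

    def test_plane_vector_collinear_raises(self):
        with pytest.raises(GeometryError):
            plane_vector((0, 0, 0), (1, 0, 0), (2, 0, 0))


class TestConformation3:
    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 130.0), (60.0, 40.0), (179.0, -179.0)])
    def test_roundtrip_recovers_torsions(self, phi, psi):
        bb = make_backbone([(phi, psi)] * 7)
        conf = conformation3(bb, 3)
        assert conf.theta1 == pytest.approx(phi, abs=1e-6)
        assert conf.theta2 == pytest.approx(psi, abs=1e-6)

    def test_terminal_residue_undefined(self, helix_backbone):
        with pytest.raises(FragmentUndefined):
            conformation3(helix_backbone, 0)
        with pytest.raises(FragmentUndefined):
            conformation3(helix_backbone, len(helix_backbone) - 1)

    def test_chain_break_signal(self, helix_backbone):
        bb = BackboneStructure(
            helix_backbone.sequence,
            helix_backbone.n,
            helix_backbone.ca,
            helix_backbone.c,
            break_before=np.zeros(len(helix_backbone), dtype=bool),
        )
        bb.break_before[6] = True
        with pytest.raises(ChainBreakInFragment):
            conformation3(bb, 5)
        with pytest.raises(ChainBreakInFragment):
            conformation3(bb, 6)
        conformation3(bb, 7)  # window 6..8 has no internal break


class TestConformation9:
    def test_helix_interior_bins_constant(self, helix_backbone):
        bins = {bin_conformation(conformation9(helix_backbone, i)) for i in range(4, 16)}
        assert len(bins) == 1

    def test_helix_and_strand_bins_differ(self, helix_backbone, strand_backbone):
        b_h = bin_conformation(conformation9(helix_backbone, 8))
        b_e = bin_conformation(conformation9(strand_backbone, 8))
        assert b_h != b_e

    def test_collinear_trace_raises(self):
        L = 11
        ca = np.stack([np.arange(L) * 3.8, np.zeros(L), np.zeros(L)], axis=1)
        bb = BackboneStructure("A" * L, np.full((L, 3), np.nan), ca, np.full((L, 3), np.nan))
        bb.break_before[:] = False
        bb.break_before[0] = True
        with pytest.raises(GeometryError):
            conformation9(bb, 5)

    def test_rigid_motion_invariance(self, helix_backbone):
        rng = np.random.default_rng(5)
        ref = conformation9(helix_backbone, 8)
        for _ in range(10):
            # random rotation via QR; keep it proper
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            t = rng.normal(size=3) * 20.0
            moved = BackboneStructure(
                helix_backbone.sequence,
                helix_backbone.n @ q.T + t,
                helix_backbone.ca @ q.T + t,
                helix_backbone.c @ q.T + t,
            )
            got = conformation9(moved, 8)
            np.testing.assert_allclose(got, ref, atol=1e-9)


class TestBinning:
    def test_origin_maps_to_center_bins(self):
        assert bin_conformation(FragmentConformation(0, 0, 0, 0)) == ConformationBin(3, 3, 0, 0)

    def test_boundary_convention(self):
        eps = 1e-9
        assert bin_conformation(FragmentConformation(180, -180 + eps, 180, 90)) == ConformationBin(
            5, 0, 5, 3
        )

    def test_joint_bin_count(self):
        assert N_JOINT_BINS == (360 // 60) * (360 // 60) * (180 // 30) * (180 // 30) == 1296

    @given(
        t1=st.floats(-179.999, 180.0),
        t2=st.floats(-179.999, 180.0),
        t3=st.floats(0.0, 180.0),
        t4=st.floats(0.0, 180.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_total_on_valid_domain(self, t1, t2, t3, t4):
        b = bin_conformation(FragmentConformation(t1, t2, t3, t4))
        assert all(0 <= x <= 5 for x in b)

    @pytest.mark.parametrize("bad", [(-180.0, 0, 0, 0), (181.0, 0, 0, 0), (0, 0, -1.0, 0), (0, 0, 0, 180.5)])
    def test_out_of_domain_raises(self, bad):
        with pytest.raises(ValueError):
            bin_conformation(FragmentConformation(*bad))

    def test_bin_edges_covered(self):
        # every bin index is reachable on a dense grid
        seen = set()
        for t in np.linspace(-179.999, 180.0, 721):
            seen.add(bin_conformation(FragmentConformation(t, 0, 0, 0)).b1
)
        assert seen == set(range(6))


def test_position_bins_markers(helix_backbone):
    bins = position_bins(helix_backbone, "frag3")
    assert bins[0] is None and bins[-1] is None
    assert all(isinstance(b, ConformationBin) for b in bins[1:-1])
    bb = BackboneStructure(
        helix_backbone.sequence,
        helix_backbone.n,
        helix_backbone.ca,
        helix_backbone.c,
        break_before=np.zeros(len(helix_backbone), dtype=bool),
    )
    bb.break_before[10] = True
    bins = position_bins(bb, "frag3")
    assert bins[9] is BREAK and bins[10] is BREAK
    assert isinstance(bins[8], ConformationBin) and isinstance(bins[11], ConformationBin)
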