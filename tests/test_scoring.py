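import numpy as np
import pytest

from frthread.geometry import BREAK, ConformationBin
from frthread.io_formats import QueryProfile, TemplateRecord
from frthread.lspp import EnergyTable, count_fragments
from frthread.residues import AA20
from frthread.scoring import (
    ScoringWeights,
    build_score_matrix,
    default_hydro_matrix,
    e_2nd,
    e_frag3,
    e_frag9,
    e_hydro,
    e_seq,
    read_hydro_matrix,
)
from frthread.synthetic import make_backbone, make_profile


@pytest.fixture()
def toy_pair():
    seq_q = "ACDEFGHIKL"
    seq_t = "ACDEFGHIKW"
    _, freq, _ = make_profile(seq_q, sharpness=0.5)
    query = QueryProfile(seq_q, freq, "HHHHHCCEEE")
    bb = make_backbone([(-57.0, -47.0)] * len(seq_t), sequence=seq_t)
    _, _, lo = make_profile(seq_t, sharpness=0.5)
    template = TemplateRecord("toy", seq_t, lo, "HHHHHCCEEE", bb)
    return query, template


class TestTerms:
    def test_e_seq_uniform_times_zero_column(self, toy_pair):
        query, template = toy_pair
        q = QueryProfile(query.sequence, np.full((len(query), 20), 1 / 20.0), query.pred_ss)
        t = TemplateRecord("z", template.sequence, np.zeros((len(template), 20)),
                           template.obs_ss, template.backbone)
        assert e_seq(q, 0, t, 0) == 0.0

    def test_e_seq_one_hot_picks_column_value(self, toy_pair):
        _, template = toy_pair
        freq = np.zeros((3, 20))
        freq[:, 5] = 1.0
        q = QueryProfile("QQQ", freq, "CCC")
        assert e_seq(q, 1, template, 2) == template.pssm[2, 5]

    def test_e_seq_matches_sum_oracle(self, toy_pair):
        query, template = toy_pair
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = int(rng.integers(0, len(query)))
            j = int(rng.integers(0, len(template)))
            oracle = sum(query.freq[i, k] * template.pssm[j, k] for k in range(20))
            assert e_seq(query, i, template, j) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("a,b,expected", [("H", "H", 1.0), ("H", "E", -1.0), ("C", "C", 1.0)])
    def test_e_2nd(self, a, b, expected):
        assert e_2nd(a, b) == expected

    def test_e_2nd_invalid_state(self):
        with pytest.raises(ValueError):
            e_2nd("H", "X")

    def test_e_hydro_default_classes(self):
        m = default_hydro_matrix()
        assert e_hydro("F", "I", m) == 1.0  # both hydrophobic
        assert e_hydro("F", "K", m) == -1.0  # hydrophobic vs polar
        assert e_hydro("A", "K", m) == 0.0  # neutral vs polar

    def test_e_hydro_unknown_residue(self):
        assert e_hydro("X", "A", default_hydro_matrix()) == 0.0

    def test_user_matrix_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        m = np.round(rng.normal(size=(20, 20)), 3)
        # write with a shuffled residue order to exercise the permutation
        order = list(AA20)
        rng.shuffle(order)
        perm = [AA20.index(aa) for aa in order]
        path = tmp_path / "hydro.txt"
        with open(path, "w") as fh:
            fh.write(" ".join(order) + "\n")
            for row in m[np.ix_(perm, perm)]:
                fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")
        np.testing.assert_allclose(read_hydro_matrix(path), m, atol=1e-12)


@pytest.fixture()
def helix_tables(toy_pair):
    _, template = toy_pair
    counts3 = count_fragments([template.backbone], "frag3")
    from frthread.lspp import build_energy_table

    helix = make_backbone([(-57.0, -47.0)] * 30)
    strand = make_backbone([(-120.0, 130.0)] * 30)
    t3 = build_energy_table([template.backbone, helix, strand], "frag3")
    t9 = build_energy_table([template.backbone, helix, strand], "frag9")
    return t3, t9


class TestFragTerms:
    def test_template_break_scores_zero(self, toy_pair, helix_tables):
        query, template = toy_pair
        t3, _ = helix_tables
        broken = TemplateRecord(
            "b", template.sequence, template.pssm, template.obs_ss, template.backbone,
            bins3=[BREAK] * len(template), bins9=[BREAK] * len(template),
        )
        assert e_frag3(query, 5, broken, 5, t3) == 0.0

    def test_query_terminus_scores_zero(self, toy_pair, helix_tables):
        query, template = toy_pair
        t3, t9 = helix_tables
        assert e_frag3(query, 0, template, 5, t3) == 0.0
        assert e_frag9(query, 3, template, 5, t9) == 0.0

    def test_helix_match_is_favorable(self, toy_pair, helix_tables):
        query, template = toy_pair
        t3, t9 = helix_tables
        # helix-trained table, helical template position, helix-seen query triplet
        assert e_frag3(query, 5, template, 5, t3) < 0.0


class TestScoreMatrix:
    def test_zero_weights_constant_shift(self, toy_pair):
        query, template = toy_pair
        w = ScoringWeights(w2=0, w3=0, w4=0, w5=0, e_shift=2.5)
        m = build_score_matrix(
            QueryProfile(query.sequence, np.full((len(query), 20), 1 / 20.0), query.pred_ss),
            TemplateRecord("z", template.sequence, np.zeros((len(template), 20)),
                           template.obs_ss, template.backbone),
            w,
        )
        np.testing.assert_allclose(m.values, 2.5, atol=1e-12)

    def test_single_cell_hand_computed(self, toy_pair, helix_tables):
        query, template = toy_pair
        t3, t9 = helix_tables
        w = ScoringWeights(w2=1.5, w3=0.5, w4=0.25, w5=0.75, e_shift=-0.3)
        m = build_score_matrix(query, template, w, t3, t9)
        i = j = 5
        expected = (
            e_seq(query, i, template, j)
            + 1.5 * e_2nd(query.pred_ss[i], template.obs_ss[j])
            + 0.5 * e_hydro(query.sequence[i], template.sequence[j], default_hydro_matrix())
            + 0.25 * (-e_frag3(query, i, template, j, t3))
            + 0.75 * (-e_frag9(query, i, template, j, t9))
            - 0.3
        )
        assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_frt3_frt5_bit_identical(self, toy_pair, helix_tables):
        query, template = toy_pair
        t3, t9 = helix_tables
        w0 = ScoringWeights(w2=2, w3=1, w4=0, w5=0, e_shift=0.1)
        with_tables = build_score_matrix(query, template, w0, t3, t9)
        without = build_score_matrix(query, template, w0)
        np.testing.assert_array_equal(with_tables.values, without.values)

    def test_linearity_in_weights(self, toy_pair, helix_tables):
        query, template = toy_pair
        t3, t9 = helix_tables
        wa = ScoringWeights(w2=1, w3=0.5, w4=0.25, w5=0.5, e_shift=0.2)
        wb = ScoringWeights(w2=0.5, w3=1.5, w4=0.75, w5=0.25, e_shift=-0.1)
        wsum = ScoringWeights(w2=1.5, w3=2.0, w4=1.0, w5=0.75, e_shift=0.1)
        ma = build_score_matrix(query, template, wa, t3, t9).values
        mb = build_score_matrix(query, template, wb, t3, t9).values
        msum = build_score_matrix(query, template, wsum, t3, t9).values
        # w1 (the profile term) is fixed at 1 in every weight set, so the sum
        # double-counts one copy of the profile term
        seq_term = build_score_matrix(
            query, template, ScoringWeights(w2=0, w3=0, w4=0, w5=0, e_shift=0)
        ).values
        np.testing.assert_allclose(msum, ma + mb - seq_term, atol=1e-10)

    def test_w2_monotonicity(self, toy_pair):
        query, template = toy_pair
        lo = build_score_matrix(query, template, ScoringWeights(w2=1, w3=1)).values
        hi = build_score_matrix(query, template, ScoringWeights(w2=3, w3=1)).values
        match = np.array([[a == b and a in "HE" or (a == b) for b in template.obs_ss]
                          for a in query.pred_ss])
        assert np.all(hi[match] >= lo[match])
        assert np.all(hi[~match] <= lo[~match])

    def test_w1_is_fixed(self):
        with pytest.raises(ValueError):
            ScoringWeights(w1=2.0)
        with pytest.raises(ValueError):
            ScoringWeights(w2=-1.0)
        with pytest.raises(ValueError):
            ScoringWeights(go=1.0)

    def test_mode_property(self):
        assert ScoringWeights(w4=0, w5=0).mode == "fr-t3"
        assert ScoringWeights(w4=1, w5=1).mode == "fr-t5"
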