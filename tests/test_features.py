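import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from sutpred.features import (
    aac,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    encode_188d,
    encode_dataset,
    k_separated_bigrams,
    pssm_composition,
)
from sutpred.properties import DEFAULT_GROUPINGS, PropertyGrouping
from sutpred.pssm import PSSM_COLUMNS, PssmProfile
from sutpred.sequence_io import AMINO_ACIDS, ProteinSequence

HYDRO = DEFAULT_GROUPINGS[0]  # polar RKEDQN / neutral GASTPHY / hydrophobic CVLIMFW

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=150)


def naive_k_bigrams(N: np.ndarray, k: int) -> np.ndarray:
    """Independent triple-loop oracle for the bigram transform."""
    L = N.shape[0]
    T = np.zeros((20, 20))
    for m in range(20):
        for n in range(20):
            for i in range(L - k):
                T[m, n] += N[i, m] * N[i + k, n]
    return T.ravel()


class TestAac:
    def test_homopolymer(self):
        v = aac(ProteinSequence("x", "A" * 50))
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_two_residue_mix(self):
        v = aac(ProteinSequence("x", "A" * 25 + "C" * 25))
        assert v[AMINO_ACIDS.index("A")] == 0.5
        assert v[AMINO_ACIDS.index("C")] == 0.5

    @given(seq_strategy)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, residues):
        assert abs(aac(ProteinSequence("x", residues)).sum() - 1) < 1e-12


class TestCtd:
    def test_composition_single_group(self):
        npt.assert_array_equal(
            ctd_composition(ProteinSequence("x", "RRRR"), HYDRO), [1, 0, 0])

    def test_composition_hand_count(self):
        # R polar x2, G neutral x2, C hydrophobic x2 over L=6
        npt.assert_allclose(
            ctd_composition(ProteinSequence("x", "RGCRGC"), HYDRO),
            [2 / 6, 2 / 6, 2 / 6])

    def test_transition_single_cross_pair(self):
        npt.assert_allclose(
            ctd_transition(ProteinSequence("x", "RG"), HYDRO), [1.0, 0, 0])

    def test_transition_no_cross_group(self):
        npt.assert_array_equal(
            ctd_transition(ProteinSequence("x", "RRRR"), HYDRO), [0, 0, 0])

    def test_transition_alternating(self):
        # RG, GR, RG: 3 polar/neutral crossings over L-1 = 3
        npt.assert_allclose(
            ctd_transition(ProteinSequence("x", "RGRG"), HYDRO), [1.0, 0, 0])

    def test_transition_needs_two_residues(self):
        with pytest.raises(ValueError, match="L >= 2"):
            ctd_transition(ProteinSequence("x", "R"), HYDRO)

    def test_distribution_hand_walk(self):
        # polar occurrences at 1,2,3,4; quantile occurrences 1,1,2,3,4
        d = ctd_distribution(ProteinSequence("x", "RRRR"), HYDRO)
        npt.assert_allclose(d[:5], [0.25, 0.25, 0.50, 0.75, 1.00])
        npt.assert_array_equal(d[5:], np.zeros(10))

    def test_distribution_absent_group_is_zero(self):
        d = ctd_distribution(ProteinSequence("x", "RG" * 30), HYDRO)
        npt.assert_array_equal(d[10:], np.zeros(5))  # no hydrophobic residue

    @given(seq_strategy, st.sampled_from(DEFAULT_GROUPINGS))
    @settings(max_examples=60, deadline=None)
    def test_invariants(self, residues, grouping):
        seq = ProteinSequence("x", residues)
        assert abs(ctd_composition(seq, grouping).sum() - 1) < 1e-12
        t = ctd_transition(seq, grouping)
        assert np.all((t >= 0) & (t <= 1))
        d = ctd_distribution(seq, grouping).reshape(3, 5)
        assert np.all((d >= 0) & (d <= 1))
        for block in d:
            assert np.all(np.diff(block) >= -1e-15)


class Test188d:
    def test_width_and_prefix(self):
        seq = ProteinSequence("x", "ACDEFGHIKLMNPQRSTVWY" * 3)
        v = encode_188d(seq)
        assert v.shape == (188,)
        npt.assert_array_equal(v[:20], aac(seq))

    def test_composition_triples_sum_to_one(self):
        v = encode_188d(ProteinSequence("x", "MALWTRGCK" * 8))
        for p in range(8):
            start = 20 + p * 21
            assert abs(v[start:start + 3].sum() - 1) < 1e-12

    def test_requires_eight_groupings(self):
        with pytest.raises(ValueError, match="8"):
            encode_188d(ProteinSequence("x", "ACD" * 20), DEFAULT_GROUPINGS[:3])


class TestPssmComposition:
    def test_two_position_hand_computation(self):
        r1 = np.arange(20, dtype=float)
        r2 = np.arange(20, 40, dtype=float)
        prof = PssmProfile("x", "AC", np.vstack([r1, r2]))
        v = pssm_composition(prof).reshape(20, 20)
        npt.assert_allclose(v[PSSM_COLUMNS.index("A")], r1 / 2)
        npt.assert_allclose(v[PSSM_COLUMNS.index("C")], r2 / 2)
        mask = np.ones(20, bool)
        mask[[PSSM_COLUMNS.index("A"), PSSM_COLUMNS.index("C")]] = False
        npt.assert_array_equal(v[mask], np.zeros((18, 20)))

    def test_homopolymer_averages_to_row(self):
        vrow = np.linspace(-5, 5, 20)
        prof = PssmProfile("x", "A" * 7, np.tile(vrow, (7, 1)))
        v = pssm_composition(prof).reshape(20, 20)
        npt.assert_allclose(v[PSSM_COLUMNS.index("A")], vrow)
        assert v.shape == (20, 20)

    def test_width(self):
        prof = PssmProfile("x", "MACD", np.zeros((4, 20)))
        assert pssm_composition(prof).shape == (400,)


class TestKSeparatedBigrams:
    def test_one_hot_substitution(self):
        m0, n0 = 4, 11
        N = np.zeros((2, 20))
        N[0, m0] = 1.0
        N[1, n0] = 1.0
        v = k_separated_bigrams(PssmProfile("x", "MA", N), k=1)
        expected = np.zeros(400)
        expected[m0 * 20 + n0] = 1.0
        npt.assert_array_equal(v, expected)

    def test_k_equal_length_is_zero(self):
        prof = PssmProfile("x", "MACD", np.ones((4, 20)))
        npt.assert_array_equal(k_separated_bigrams(prof, k=4), np.zeros(400))

    def test_invalid_k(self):
        prof = PssmProfile("x", "MACD", np.ones((4, 20)))
        with pytest.raises(ValueError, match="k"):
            k_separated_bigrams(prof, k=0)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_matches_naive_oracle(self, k):
        rng = np.random.default_rng(2024 + k)
        for _ in range(100):
            N = rng.integers(-10, 11, size=(30, 20)).astype(float)
            prof = PssmProfile("x", "A" * 30, N)
            npt.assert_allclose(k_separated_bigrams(prof, k),
                                naive_k_bigrams(N, k), atol=1e-9)


class TestEncodeDataset:
    @pytest.fixture
    def encoded(self, small_dataset):
        return small_dataset

    @pytest.mark.parametrize("feature_set,width", [
        (("d188",), 188),
        (("pssm_comp",), 400),
        (("kbigrams",), 400),
        (("d188", "pssm_comp"), 588),
        (("d188", "kbigrams"), 588),
        (("pssm_comp", "kbigrams"), 800),
        (("d188", "pssm_comp", "kbigrams"), 988),
    ])
    def test_combination_widths(self, encoded, feature_set, width):
        seqs, labels, profiles = encoded
        data = encode_dataset(seqs[:6], labels[:6], feature_set, profiles)
        assert data.n_features == width
        assert len(data.schema) == width

    def test_empty_feature_set_rejected(self, encoded):
        seqs, labels, _ = encoded
        with pytest.raises(ValueError, match="at least one"):
            encode_dataset(seqs[:3], labels[:3], ())

    def test_missing_profiles_listed(self, encoded):
        seqs, labels, profiles = encoded
        partial = {k: v for k, v in list(profiles.items())[:2]}
        with pytest.raises(ValueError, match="missing PSSM"):
            encode_dataset(seqs[:6], labels[:6], ("kbigrams",), partial)

    def test_multiple_k_blocks(self, encoded):
        seqs, labels, profiles = encoded
        data = encode_dataset(seqs[:4], labels[:4], ("kbigrams",), profiles,
                              k_list=(1, 2, 3))
        assert data.n_features == 1200

    def test_encoding_is_deterministic(self, encoded):
        seqs, labels, profiles = encoded
        a = encode_dataset(seqs[:5], labels[:5], ("d188", "kbigrams"), profiles)
        b = encode_dataset(seqs[:5], labels[:5], ("d188", "kbigrams"), profiles)
        npt.assert_array_equal(a.X, b.X)


def test_custom_grouping_partition_enforced():
    with pytest.raises(ValueError, match="partition"):
        PropertyGrouping("bad", ("RKEDQN", "GASTPHY", "CVLIMF"))  # W missing
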