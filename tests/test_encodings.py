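import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnamodnet import encodings as enc

SEQ41 = ("ACGU" * 10 + "A")
rna = st.text(alphabet="ACGU", min_size=41, max_size=41)


def brute_dims(seq_len: int) -> dict[str, int]:
    """Closed-form dimensionalities derived by enumerating each scheme's
    feature set directly."""
    return {
        "nac": 4,
        "dnc": 16,
        "tnc": 64,
        "kmer": 4**3,
        "cksnap": 16 * 6,
        "enac": 4 * (seq_len - 5 + 1),
        "anf": 4 * seq_len,
        "binary": 4 * seq_len,
        "ncp": 3 * seq_len,
        "eiip": seq_len,
        "psednc": 16 + 2,
        "rckmer": 32,  # odd k: exactly half of 4^3, no RC-palindromes
    }


class TestWorkedExamples:
    def test_anf_printed_example(self):
        # prefix GAUA: A density 0.5, vector [0.5, 0, 0.25, 0.25]
        v = enc.anf_position("GAUAGGUG", 4)
        assert v[0] == pytest.approx(0.5)
        np.testing.assert_allclose(v, [0.5, 0.0, 0.25, 0.25])

    def test_anf_full_prefix(self):
        np.testing.assert_allclose(enc.anf_position("GAUAGGUG", 8),
                                   [2 / 8, 0, 4 / 8, 2 / 8])

    def test_one_hot_rows(self):
        m = enc.one_hot("ACGU").values
        np.testing.assert_array_equal(m, np.eye(4))
        assert enc.one_hot("A").values.tolist() == [[1, 0, 0, 0]]
        assert enc.one_hot("U").values.tolist() == [[0, 0, 0, 1]]

    def test_one_hot_n_is_zero_row(self):
        m = enc.one_hot("ANG").values
        assert m[1].sum() == 0 and m[0].sum() == 1

    def test_ncp_rows(self):
        m = enc.ncp("ACGU").values
        np.testing.assert_array_equal(
            m, [[1, 1, 1], [0, 1, 0], [1, 0, 0], [0, 0, 1]])

    def test_dnc_hand_count(self):
        v = enc.dnc("ACGUACGU")
        d = dict(zip(v.feature_names, v.values))
        assert d["AC"] == pytest.approx(2 / 7)
        assert d["CG"] == pytest.approx(2 / 7)
        assert d["GU"] == pytest.approx(2 / 7)
        assert d["UA"] == pytest.approx(1 / 7)

    def test_tnc_point_mass(self):
        v = enc.tnc("AAAA")
        d = dict(zip(v.feature_names, v.values))
        assert d["AAA"] == 1.0 and sum(v.values) == pytest.approx(1.0)

    def test_cksnap_k0_enumeration(self):
        v = enc.cksnap("ACGU", k_max=0)
        d = dict(zip(v.feature_names, v.values))
        for pair in ("AC", "CG", "GU"):
            assert d[f"{pair}.gap0"] == pytest.approx(1 / 3)
        assert d["AA.gap0"] == 0

    def test_cksnap_point_mass(self):
        v = enc.cksnap("AAAA", k_max=0)
        assert dict(zip(v.feature_names, v.values))["AA.gap0"] == 1.0

    def test_enac_window_count(self):
        v = enc.enac("AAAAA", win=5)
        np.testing.assert_allclose(v.values, [1, 0, 0, 0])
        v = enc.enac("ACGUA", win=5)
        np.testing.assert_allclose(v.values, [0.4, 0.2, 0.2, 0.2])

    def test_kmer1_equals_nac(self):
        np.testing.assert_allclose(enc.kmer(SEQ41, k=1).values,
                                   enc.nac(SEQ41).values)

    def test_rckmer_k1_collapse(self):
        v = enc.rckmer("AU", k=1)
        assert v.feature_names == ["A", "C"]
        np.testing.assert_allclose(v.values, [1.0, 0.0])

    def test_eiip_values(self):
        np.testing.assert_allclose(enc.eiip("AC").values, [0.1260, 0.1340])
        np.testing.assert_allclose(
            enc.eiip("ACG", value_table={"A": 1, "C": 1, "G": 1}).values,
            [1, 1, 1])
        with pytest.raises(ValueError):
            enc.eiip("")


class TestDimensionalities:
    @pytest.mark.parametrize("scheme", sorted(brute_dims(41)))
    def test_scheme_dimension(self, scheme):
        rng = np.random.default_rng(0)
        for _ in range(3):
            seq = "".join(rng.choice(list("ACGU"), size=41))
            v = enc.encode(seq, scheme)
            if isinstance(v, enc.EncodedMatrix):
                v = v.flatten()
            assert len(v) == brute_dims(41)[scheme]
            assert len(v.feature_names) == len(v)

    def test_onehot_matrix_shape(self):
        m = enc.encode(SEQ41, "onehot_matrix")
        assert m.values.shape == (41, 4)
        assert (m.values.sum(axis=1) == 1).all()


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rna)
    def test_compositional_sums(self, seq):
        for scheme in ("nac", "dnc", "tnc", "kmer", "psednc"):
            assert enc.encode(seq, scheme).values.sum() == pytest.approx(
                1.0, abs=1e-9)
        v = enc.cksnap(seq).values.reshape(6, 16)
        np.testing.assert_allclose(v.sum(axis=1), 1.0, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rna)
    def test_anf_last_position_equals_nac(self, seq):
        np.testing.assert_allclose(enc.anf_position(seq, len(seq)),
                                   enc.nac(seq).values, atol=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(rna)
    def test_pure_function(self, seq):
        a = enc.encode(seq, "cksnap").values
        b = enc.encode(seq, "cksnap").values
        np.testing.assert_array_equal(a, b)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(enc.AmbiguousBaseError):
            enc.nac("ACGN")

    def test_unknown_scheme_lists_registered(self):
        with pytest.raises(KeyError, match="anf"):
            enc.encode("ACGU", "nope")


class TestPseDNC:
    def test_weight_zero_limit(self):
        v = enc.psednc(SEQ41, lam=2, w=0.0)
        np.testing.assert_allclose(v.values[:16], enc.dnc(SEQ41).values,
                                   atol=1e-12)
        np.testing.assert_allclose(v.values[16:], 0.0)

    def test_identical_properties_zero_theta(self):
        table = {d: np.zeros(6) for d in enc._kmer_names(2)}
        v = enc.psednc(SEQ41, lam=2, w=0.5, property_table=table)
        np.testing.assert_allclose(v.values[16:], 0.0)

    def test_lambda1_toy_table_hand_value(self):
        # two properties; theta_1 = mean over adjacent dinucleotide pairs
        # of the mean squared property difference
        table = {d: np.array([0.0, 0.0]) for d in enc._kmer_names(2)}
        table["AC"] = np.array([1.0, 3.0])
        table["CG"] = np.array([2.0, 1.0])
        table["GU"] = np.array([0.0, 0.0])
        # seq ACGU: dinucs AC, CG, GU
        # Theta(AC,CG) = ((1-2)^2 + (3-1)^2)/2 = 2.5
        # Theta(CG,GU) = (4 + 1)/2 = 2.5 ; theta1 = 2.5
        v = enc.psednc("ACGU", lam=1, w=0.5, property_table=table)
        f_sum = 1.0  # normalized dinucleotide freqs sum to 1
        expected_last = 0.5 * 2.5 / (f_sum + 0.5 * 2.5)
        assert v.values[-1] == pytest.approx(expected_last)

    def test_scpsednc_single_property_collapses_to_psednc(self):
        table1 = {d: v[:1] for d, v in enc.load_property_table().items()}
        a = enc.psednc(SEQ41, lam=2, w=0.1, property_table=table1)
        b = enc.scpsednc(SEQ41, lam=2, w=0.1, property_table=table1)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_scpsednc_length(self):
        v = enc.scpsednc(SEQ41, lam=1, w=0.1)
        assert len(v) == 16 + 1 * 6
        table2 = {d: v[:2] for d, v in enc.load_property_table().items()}
        assert len(enc.scpsednc(SEQ41, lam=1, property_table=table2)) == 18

    def test_missing_dinucleotide_raises(self):
        table = {"AA": np.zeros(6)}
        with pytest.raises(KeyError):
            enc.psednc(SEQ41, property_table=table)
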