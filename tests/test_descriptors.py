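"""Descriptor encoders against brute-force oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snarekit import (
    DescriptorConfig,
    FeatureMatrix,
    aac,
    asdc,
    cksaap,
    concat_features,
    dde,
    encode_dataset,
    gdc,
    qsorder,
)
from snarekit.sequence_io import ALPHABET, ProteinRecord, SequenceDataset
from snarekit._aadata import (
    compute_grantham_matrix,
    compute_physchem_matrix,
    load_distance_matrix,
)

AA = ALPHABET
sequences = st.text(alphabet=AA, min_size=3, max_size=50)


def brute_force_gap_pairs(seq: str, g: int) -> np.ndarray:
    """Independent oracle: enumerate ordered pairs (i, i+g) directly."""
    counts = np.zeros((20, 20))
    for i in range(len(seq) - g):
        counts[AA.index(seq[i]), AA.index(seq[i + g])] += 1
    return counts.ravel()


def brute_force_asdc(seq: str) -> np.ndarray:
    """Independent oracle: double loop over all position pairs i < j."""
    counts = np.zeros((20, 20))
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            counts[AA.index(seq[i]), AA.index(seq[j])] += 1
    return counts.ravel() / counts.sum()


def component(vector: np.ndarray, pair: str) -> float:
    return float(vector[20 * AA.index(pair[0]) + AA.index(pair[1])])


class TestAAC:
    def test_homopolymer(self):
        v = aac("AAAA")
        assert v[AA.index("A")] == 1.0
        assert v.sum() == 1.0

    def test_uniform_case(self):
        v = aac("ACDE")
        for c in "ACDE":
            assert v[AA.index(c)] == 0.25

    def test_direct_counting(self):
        v = aac("MKVM")
        assert v[AA.index("M")] == 0.5
        assert v[AA.index("K")] == 0.25
        assert v[AA.index("V")] == 0.25

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aac("")

    def test_permutation_invariance(self):
        assert np.array_equal(aac("AAC"), aac("ACA"))


class TestGDC:
    def test_gap1_pair_enumeration(self):
        v = gdc("ACDC", g=1)
        assert component(v, "AC") == pytest.approx(1 / 3)
        assert component(v, "CD") == pytest.approx(1 / 3)
        assert component(v, "DC") == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)

    def test_gap2_pair_enumeration(self):
        v = gdc("ACDC", g=2)
        assert component(v, "AD") == pytest.approx(0.5)
        assert component(v, "CC") == pytest.approx(0.5)

    @pytest.mark.parametrize("g", [1, 2, 3])
    def test_homopolymer_single_pair(self, g):
        v = gdc("A" * 8, g=g)
        assert component(v, "AA") == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gdc("ACD", g=3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(sequences, st.integers(min_value=1, max_value=4))
    def test_matches_brute_force(self, seq, g):
        if len(seq) <= g:
            return
        counts = brute_force_gap_pairs(seq, g)
        assert np.allclose(gdc(seq, g), counts / counts.sum())


class TestASDC:
    def test_single_skip_pair(self):
        v = asdc("AA")
        assert component(v, "AA") == 1.0

    def test_all_ordered_pairs_of_acd(self):
        v = asdc("ACD")
        for pair in ("AC", "CD", "AD"):
            assert component(v, pair) == pytest.approx(1 / 3)

    def test_dimension_400(self):
        assert asdc("MKVLAY").shape == (400,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            asdc("M")

    def test_order_sensitivity_witness(self):
        # AAC is order-blind on this pair; ASDC is not
        assert np.array_equal(aac("AAC"), aac("ACA"))
        assert not np.array_equal(asdc("AAC"), asdc("ACA"))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(sequences)
    def test_matches_brute_force_oracle(self, seq):
        assert np.allclose(asdc(seq), brute_force_asdc(seq), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(sequences)
    def test_equals_normalised_sum_of_gap_counts(self, seq):
        # ASDC == the elementwise sum of raw g-gap counts over all gaps,
        # jointly normalised
        total = sum(
            brute_force_gap_pairs(seq, g) for g in range(1, len(seq))
        )
        assert np.allclose(asdc(seq), total / total.sum())


class TestCKSAAP:
    def test_k0_block_enumeration(self):
        v = cksaap("AAC", kmax=0)
        assert component(v[:400], "AA") == 0.5
        assert component(v[:400], "AC") == 0.5

    def test_dimension_1600_at_kmax3(self):
        assert cksaap("MKVLAYQR", kmax=3).shape == (1600,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cksaap("MKV", kmax=3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(alphabet=AA, min_size=6, max_size=50))
    def test_k_block_equals_gdc_at_g_k_plus_1(self, seq):
        v = cksaap(seq, kmax=3)
        for k in range(4):
            block = v[400 * k: 400 * (k + 1)]
            assert np.allclose(block, gdc(seq, g=k + 1))
            assert block.sum() == pytest.approx(1.0)


class TestDDE:
    def test_theoretical_mean_for_AA(self):
        # alanine has 4 synonymous codons: Tm(AA) = (4/61)^2
        seq = "AAC"
        dc = 0.5
        tm = (4 / 61) ** 2
        tv = tm * (1 - tm) / 2
        v = dde(seq)
        assert component(v, "AA") == pytest.approx((dc - tm) / np.sqrt(tv))

    def test_adjacent_pair_frequencies(self):
        # Dc enters DDE standardised; recover it by inverting the formula
        v = dde("AAC")
        tm = np.outer(
            [4, 2, 2, 2, 2, 4, 2, 3, 2, 6, 1, 2, 4, 2, 6, 6, 4, 4, 1, 2],
            [4, 2, 2, 2, 2, 4, 2, 3, 2, 6, 1, 2, 4, 2, 6, 6, 4, 4, 1, 2],
        ).ravel() / 61**2
        dc = v * np.sqrt(tm * (1 - tm) / 2) + tm
        assert component(dc, "AA") == pytest.approx(0.5)
        assert component(dc, "AC") == pytest.approx(0.5)
        others = dc.copy()
        others[20 * AA.index("A") + AA.index("A")] = 0
        others[20 * AA.index("A") + AA.index("C")] = 0
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_dimension_400(self):
        assert dde("MKVLAY").shape == (400,)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dde("M")


class TestQSOrder:
    def test_dimension_44_at_nlag2(self):
        assert qsorder("MKVLAY", nlag=2).shape == (44,)

    def test_dimension_general(self):
        assert qsorder("MKVLAYQRST", nlag=4).shape == (48,)

    def test_homopolymer_reduces_to_composition(self):
        # zero self-distance kills every coupling term
        v = qsorder("AAAAA", nlag=2)
        for block in (v[:22], v[22:]):
            assert block[AA.index("A")] == pytest.approx(1.0)
            assert np.allclose(block[20:], 0.0)

    def test_normalisation_groups_sum_to_one(self):
        v = qsorder("MKVLA", nlag=2)
        assert v[:22].sum() == pytest.approx(1.0)
        assert v[22:].sum() == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            qsorder("MK", nlag=2)

    def test_coupling_terms_match_direct_sum(self):
        seq = "MKVLA"
        w = 0.1
        v = qsorder(seq, nlag=2, w=w)
        for offset, matrix in (
            (0, load_distance_matrix("physchem_distance_synthetic")),
            (22, load_distance_matrix("grantham")),
        ):
            idx = [AA.index(c) for c in seq]
            tau = [
                sum(
                    matrix[idx[i], idx[i + d]] ** 2
                    for i in range(len(seq) - d)
                )
                for d in (1, 2)
            ]
            denom = len(seq) + w * sum(tau)
            assert v[offset + 20] == pytest.approx(w * tau[0] / denom)
            assert v[offset + 21] == pytest.approx(w * tau[1] / denom)


class TestDistanceMatrixData:
    def test_shipped_grantham_matches_formula(self):
        shipped = load_distance_matrix("grantham")
        assert np.allclose(shipped, compute_grantham_matrix(), atol=1e-5)

    def test_shipped_physchem_matches_formula(self):
        shipped = load_distance_matrix("physchem_distance_synthetic")
        assert np.allclose(shipped, compute_physchem_matrix(), atol=1e-5)

    def test_grantham_published_spot_values(self):
        m = load_distance_matrix("grantham")
        # published integer distances: R-L 102, L-I 5, S-R 110, C-W 215
        assert m[AA.index("R"), AA.index("L")] == pytest.approx(102, abs=1)
        assert m[AA.index("L"), AA.index("I")] == pytest.approx(5, abs=1)
        assert m[AA.index("S"), AA.index("R")] == pytest.approx(110, abs=1)
        assert m[AA.index("C"), AA.index("W")] == pytest.approx(215, abs=1)

    def test_matrices_symmetric_zero_diagonal(self):
        for name in ("grantham", "physchem_distance_synthetic"):
            m = load_distance_matrix(name)
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0.0)


@pytest.mark.parametrize(
    "config,dim",
    [
        (DescriptorConfig("AAC"), 20),
        (DescriptorConfig("GDC"), 400),
        (DescriptorConfig("ASDC"), 400),
        (DescriptorConfig("CKSAAP", kmax=3), 1600),
        (DescriptorConfig("DDE"), 400),
        (DescriptorConfig("QSOrder", nlag=2), 44),
    ],
)
def test_dimension_contract(config, dim):
    assert config.dimension == dim
    seq = "MKVLAYQRSTWC"
    from snarekit.descriptors import encode_sequence

    assert encode_sequence(seq, config).shape == (dim,)
    assert len(config.column_names()) == dim


@settings(deadline=None, max_examples=50, derandomize=True)
@given(sequences)
def test_composition_descriptors_are_distributions(seq):
    for v in (aac(seq), gdc(seq, 1), asdc(seq)):
        assert v.min() >= 0.0
        assert v.max() <= 1.0
        assert v.sum() == pytest.approx(1.0, abs=1e-9)


class TestEncodeDataset:
    def _dataset(self):
        return SequenceDataset(
            [
                ProteinRecord("a", "MKVLAY", "positive"),
                ProteinRecord("b", "ACDEFG", "negative"),
                ProteinRecord("c", "MMKKVV", "negative"),
            ]
        )

    def test_shape_and_labels(self):
        fm = encode_dataset(self._dataset(), DescriptorConfig("ASDC"))
        assert fm.values.shape == (3, 400)
        assert fm.row_ids == ["a", "b", "c"]
        assert fm.labels.tolist() == [1, 0, 0]

    def test_deterministic(self):
        a = encode_dataset(self._dataset(), DescriptorConfig("DDE"))
        b = encode_dataset(self._dataset(), DescriptorConfig("DDE"))
        assert np.array_equal(a.values, b.values)

    def test_short_record_named_in_error(self):
        ds = SequenceDataset(
            [
                ProteinRecord("ok", "MKVLAY", "positive"),
                ProteinRecord("shorty", "MKV", "negative"),
            ]
        )
        with pytest.raises(ValueError, match="shorty"):
            encode_dataset(ds, DescriptorConfig("CKSAAP", kmax=3))

    def test_csv_round_trip(self, tmp_path):
        fm = encode_dataset(self._dataset(), DescriptorConfig("ASDC"))
        path = tmp_path / "f.csv"
        fm.write_csv(path)
        back = FeatureMatrix.read_csv(path)
        assert np.allclose(back.values, fm.values)
        assert back.row_ids == fm.row_ids
        assert back.labels.tolist() == fm.labels.tolist()
        assert back.descriptor.name == "ASDC"


class TestConcatFeatures:
    def test_dimension_additivity(self):
        ds = SequenceDataset(
            [ProteinRecord(f"r{i}", "MKVLAYQRST", "positive")
             for i in range(3)]
        )
        a = encode_dataset(ds, DescriptorConfig("ASDC"))
        q = encode_dataset(ds, DescriptorConfig("QSOrder"))
        cat = concat_features([a, q])
        assert cat.dimension == 444
        assert cat.column_names[0].startswith("ASDC:")
        assert cat.column_names[-1].startswith("QSOrder:")

    def test_single_matrix_identity(self, toy_features):
        assert concat_features([toy_features]) is toy_features

    def test_row_mismatch_rejected(self):
        ds1 = SequenceDataset([ProteinRecord("a", "MKVLAY")])
        ds2 = SequenceDataset([ProteinRecord("b", "MKVLAY")])
        m1 = encode_dataset(ds1, DescriptorConfig("AAC"))
        m2 = encode_dataset(ds2, DescriptorConfig("AAC"))
        with pytest.raises(ValueError):
            concat_features([m1, m2])
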