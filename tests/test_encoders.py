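"""Unit and property tests for the four feature encoders and fusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumiprot.encoders import (
    DIPEPTIDES,
    DatasetEncoder,
    EncoderConfig,
    EncodingError,
    encode_ctd,
    encode_dataset,
    encode_ggap,
    encode_nv,
    encode_pseaac,
    feature_names,
    fuse_features,
    load_ctd_groups,
    load_pseaac_properties,
)
from lumiprot.seqio import ALPHABET, LabeledDataset, ProteinSequence

sequences_st = st.text(alphabet=ALPHABET, min_size=1, max_size=60).map(
    lambda s: ProteinSequence("h", s)
)


# ---------------------------------------------------------------------------
# natural vector
# ---------------------------------------------------------------------------

class TestNaturalVector:
    def test_worked_example_components(self, example_seq):
        nv = encode_nv(example_seq)
        a, c = ALPHABET.index("A"), ALPHABET.index("C")
        assert nv.counts[a] == 2
        assert nv.total_distance("A") == 7  # offsets 3 and 4
        assert nv.mu[a] == pytest.approx(3.5)
        assert nv.counts[c] == 3
        assert nv.total_distance("C") == 14  # offsets 1, 5, 8
        assert nv.mu[c] == pytest.approx(14 / 3)
        assert nv.d2[a] == pytest.approx(0.5 / 22)

    def test_homopolymer(self):
        nv = encode_nv(ProteinSequence("h", "AAAA"))
        a = ALPHABET.index("A")
        assert nv.counts[a] == 4
        assert nv.mu[a] == pytest.approx(1.5)
        assert nv.d2[a] == pytest.approx(5 / 16)
        rest = np.delete(nv.vector.reshape(20, 3), a, axis=0)
        assert np.all(rest == 0)

    def test_vector_is_60_dimensional(self, example_seq):
        assert encode_nv(example_seq).vector.shape == (60,)

    def test_rejects_non_canonical(self):
        with pytest.raises(EncodingError, match="non-canonical"):
            encode_nv(ProteinSequence("q", "MXC"))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(sequences_st)
    def test_count_and_offset_totals(self, seq):
        """Counts sum to L; count-weighted mean offsets sum to L(L-1)/2."""
        nv = encode_nv(seq)
        L = len(seq)
        assert nv.counts.sum() == L
        assert (nv.counts * nv.mu).sum() == pytest.approx(L * (L - 1) / 2)
        assert np.all(nv.d2 >= 0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(sequences_st, st.randoms(use_true_random=False))
    def test_alphabet_permutation_equivariance(self, seq, rnd):
        """Relabelling residues by an alphabet permutation permutes the
        per-residue component triples accordingly."""
        perm = list(ALPHABET)
        rnd.shuffle(perm)
        mapping = dict(zip(ALPHABET, perm))
        relabelled = ProteinSequence(seq.id, "".join(mapping[c] for c in seq.residues))
        orig = encode_nv(seq).vector.reshape(20, 3)
        new = encode_nv(relabelled).vector.reshape(20, 3)
        for i, aa in enumerate(ALPHABET):
            assert np.allclose(new[ALPHABET.index(mapping[aa])], orig[i])


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

class TestCTD:
    def test_output_is_273_dimensional(self, example_seq):
        assert encode_ctd(example_seq).shape == (273,)

    def test_groups_partition_alphabet(self):
        groups = load_ctd_groups()
        assert len(groups.attributes) == 13
        for attr in groups.attributes:
            merged = "".join(groups.groups[attr])
            assert sorted(merged) == sorted(ALPHABET)

    def test_rgc_under_first_hydrophobicity_scale(self):
        # R in group I, G in group II, C in group III of the first attribute
        v = encode_ctd(ProteinSequence("q", "RGC"))
        comp, trans = v[0:3], v[3:6]
        assert np.allclose(comp, [1 / 3, 1 / 3, 1 / 3])
        # order: T_I.II, T_I.III, T_II.III
        assert np.allclose(trans, [0.5, 0.0, 0.5])

    def test_homopolymer_charge_distribution(self):
        groups = load_ctd_groups()
        v = encode_ctd(ProteinSequence("q", "KKKK"))
        i0 = groups.attributes.index("charge") * 21
        comp, trans, dist = v[i0 : i0 + 3], v[i0 + 3 : i0 + 6], v[i0 + 6 : i0 + 21]
        assert np.allclose(comp, [1, 0, 0])  # K is group I (charge = positive)
        assert np.allclose(trans, 0)
        assert np.allclose(dist[:5], [25, 25, 50, 75, 100])
        assert np.allclose(dist[5:], 0)

    def test_length_one_errors(self):
        with pytest.raises(EncodingError, match="L >= 2"):
            encode_ctd(ProteinSequence("q", "M"))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet=ALPHABET, min_size=2, max_size=60))
    def test_composition_transition_distribution_ranges(self, s):
        v = encode_ctd(ProteinSequence("h", s)).reshape(13, 21)
        for row in v:
            assert row[0:3].sum() == pytest.approx(1.0)
            assert np.all((row[3:6] >= 0) & (row[3:6] <= 1))
            d = row[6:21]
            assert np.all((d == 0) | ((d > 0) & (d <= 100)))

    def test_composition_is_length_invariant_for_homopolymers(self):
        short = encode_ctd(ProteinSequence("a", "KR" * 5))
        long = encode_ctd(ProteinSequence("b", "KR" * 10))
        comp_cols = np.concatenate([np.arange(i * 21, i * 21 + 3) for i in range(13)])
        assert np.allclose(short[comp_cols], long[comp_cols])


# ---------------------------------------------------------------------------
# g-gap dipeptide composition
# ---------------------------------------------------------------------------

def ggap_oracle(residues: str, g: int) -> np.ndarray:
    """Brute-force enumeration of all (i, i+g+1) ordered pairs."""
    counts = {d: 0 for d in DIPEPTIDES}
    n_pairs = len(residues) - g - 1
    for i in range(n_pairs):
        counts[residues[i] + residues[i + g + 1]] += 1
    return np.array([counts[d] / n_pairs for d in DIPEPTIDES])


class TestGGap:
    def test_adjacent_frequency_on_example(self, example_seq):
        v = encode_ggap(example_seq, 0)
        assert v.shape == (400,)
        assert v[DIPEPTIDES.index("AA")] == pytest.approx(1 / 10)

    def test_gap_one_frequency_on_example(self, example_seq):
        v = encode_ggap(example_seq, 1)
        assert v[DIPEPTIDES.index("AC")] == pytest.approx(1 / 9)

    def test_too_short_errors(self):
        with pytest.raises(EncodingError, match="L >= 5"):
            encode_ggap(ProteinSequence("q", "MKVA"), 3)

    def test_matches_brute_force_oracle(self, rng):
        from conftest import random_sequence

        for _ in range(200):
            L = int(rng.integers(12, 51))
            g = int(rng.integers(0, 10))
            seq = random_sequence(rng, L)
            assert np.array_equal(encode_ggap(seq, g), ggap_oracle(seq.residues, g))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet=ALPHABET, min_size=2, max_size=60), st.integers(0, 9))
    def test_frequencies_sum_to_one(self, s, g):
        if len(s) < g + 2:
            return
        assert encode_ggap(ProteinSequence("h", s), g).sum() == pytest.approx(1.0)

    def test_homopolymer_vector_is_length_invariant(self):
        a = encode_ggap(ProteinSequence("a", "A" * 10), 2)
        b = encode_ggap(ProteinSequence("b", "A" * 20), 2)
        assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# PseAAC
# ---------------------------------------------------------------------------

class TestPseAAC:
    @pytest.mark.parametrize("lambda_,dim", [(18, 562), (11, 499), (10, 490), (29, 661)])
    def test_dimension_is_400_plus_9_lambda(self, rng, lambda_, dim):
        from conftest import random_sequence

        seq = random_sequence(rng, 60)
        assert encode_pseaac(seq, lambda_, 0.2).shape == (dim,)

    def test_property_table_standardization(self):
        props = load_pseaac_properties()
        assert len(props.properties) == 9
        assert np.allclose(props.standardized.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(props.standardized.std(axis=1), 1, atol=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.text(alphabet=ALPHABET, min_size=6, max_size=60),
        st.integers(1, 5),
        st.floats(0.1, 1.0),
    )
    def test_components_sum_to_one(self, s, lambda_, omega):
        v = encode_pseaac(ProteinSequence("h", s), lambda_, omega)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_small_omega_approaches_dipeptide_frequencies(self, rng):
        from conftest import random_sequence

        seq = random_sequence(rng, 50)
        tiny = encode_pseaac(seq, 3, 1e-9)
        dc = encode_ggap(seq, 0)
        assert np.allclose(tiny[:400], dc, atol=1e-6)
        assert np.all(np.abs(tiny[400:]) < 1e-6)

    def test_tail_mass_monotone_in_omega(self, rng):
        """When all correlation factors are non-negative, the mass on the
        correlation components is non-decreasing in omega."""
        from conftest import random_sequence

        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(20, 60)))
            masses = []
            for omega in (0.1, 0.5, 1.0):
                v = encode_pseaac(seq, 4, omega)
                if np.any(v[400:] < 0):
                    break
                masses.append(v[400:].sum())
            else:
                assert all(a <= b + 1e-12 for a, b in zip(masses, masses[1:]))

    def test_sequence_not_longer_than_lambda_errors(self):
        with pytest.raises(EncodingError, match="lambda"):
            encode_pseaac(ProteinSequence("q", "MKVAC"), 5, 0.2)


# ---------------------------------------------------------------------------
# fusion / dataset encoding
# ---------------------------------------------------------------------------

class TestFusion:
    def test_general_preset_dimension(self, rng):
        from conftest import random_sequence

        config = EncoderConfig(enabled=("NV", "CTD", "GGAP", "PSEAAC"), g=3, lambda_=18, omega=0.2)
        assert config.n_features == 60 + 273 + 400 + 562 == 1295
        seq = random_sequence(rng, 60)
        row = fuse_features(seq, config)
        assert row.shape == (1295,)
        assert len(feature_names(config)) == 1295

    def test_ctd_ggap_combination_dimension(self):
        config = EncoderConfig(enabled=("CTD", "GGAP"), g=6)
        assert config.n_features == 673

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            EncoderConfig(enabled=())

    def test_block_order_is_canonical(self):
        config = EncoderConfig(enabled=("GGAP", "NV"), g=2)
        assert config.enabled == ("NV", "GGAP")

    def test_fusion_error_names_sequence(self):
        config = EncoderConfig(enabled=("GGAP",), g=5)
        with pytest.raises(EncodingError, match="shorty"):
            fuse_features(ProteinSequence("shorty", "MKV"), config)

    def test_encode_dataset_shape_and_order(self, rng):
        from conftest import random_sequence

        seqs = [random_sequence(rng, 30, f"s{i}") for i in range(3)]
        data = LabeledDataset(seqs, [1, 0, 1])
        config = EncoderConfig(enabled=("NV",))
        X = encode_dataset(data, config)
        assert X.shape == (3, 60)
        assert list(X.index) == ["s0", "s1", "s2"]
        assert not X.isna().any().any()
        # permuting the dataset permutes rows only
        perm = LabeledDataset(seqs[::-1], [1, 0, 1])
        Xp = encode_dataset(perm, config)
        assert np.allclose(Xp.loc["s0"], X.loc["s0"])

    def test_encode_dataset_reports_short_ids(self, rng):
        from conftest import random_sequence

        seqs = [random_sequence(rng, 30, "ok"), ProteinSequence("tiny", "MK")]
        data = LabeledDataset(seqs, [1, 0])
        with pytest.raises(EncodingError, match="tiny"):
            encode_dataset(data, EncoderConfig(enabled=("GGAP",), g=3))

    def test_dataset_encoder_cache_reuses_blocks(self, rng):
        from conftest import random_sequence

        seqs = [random_sequence(rng, 40, f"s{i}") for i in range(4)]
        enc = DatasetEncoder(seqs)
        a = enc.encode(EncoderConfig(enabled=("NV", "GGAP"), g=1))
        b = enc.encode(EncoderConfig(enabled=("NV", "GGAP"), g=2))
        assert np.allclose(a.iloc[:, :60], b.iloc[:, :60])
        assert ("NV",) in enc._cache and ("GGAP", 1) in enc._cache and ("GGAP", 2) in enc._cache
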