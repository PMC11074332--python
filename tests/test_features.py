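import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddigrade.features import (
    EMBEDDING_DIM,
    ReferencePanel,
    SimilarityPairFeaturizer,
    StubEmbeddingPairFeaturizer,
    build_reference_panel,
    embed_smiles_stub,
    make_featurizer,
    merge_combination,
    morgan_fingerprint,
    pair_features,
    similarity_profile,
    tanimoto,
)
from ddigrade.records import InvalidSmilesError


def set_tanimoto(a, b):
    """Independent oracle: Tanimoto via explicit python set arithmetic."""
    sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


bitvec = st.lists(st.integers(0, 1), min_size=16, max_size=16).map(
    lambda bits: np.array(bits, dtype=np.uint8)
)


class TestMorganFingerprint:
    def test_default_length_and_occupancy(self):
        fp = morgan_fingerprint(["CC(=O)Oc1ccccc1C(=O)O"])
        assert fp.shape == (1024,)
        assert set(np.unique(fp)) <= {0, 1}
        assert fp.sum() >= 1

    def test_same_molecule_different_smiles_spellings(self):
        np.testing.assert_array_equal(
            morgan_fingerprint(["CCO"]), morgan_fingerprint(["OCC"])
        )

    def test_single_atom_sets_a_bit(self):
        assert morgan_fingerprint(["C"]).sum() >= 1

    def test_invalid_smiles_named_in_error(self):
        with pytest.raises(InvalidSmilesError, match="C\\(\\(\\("):
            morgan_fingerprint(["CCO", "C((("])

    def test_custom_radius_and_bits(self):
        assert morgan_fingerprint(["CCO"], radius=3, n_bits=512).shape == (512,)


class TestMergeCombination:
    def test_union_example(self):
        a = np.array([1, 0, 0], dtype=np.uint8)
        b = np.array([0, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(merge_combination([a, b]), [1, 1, 0])

    def test_mixed_lengths_error(self):
        with pytest.raises(ValueError, match="mixed"):
            merge_combination([np.zeros(4, np.uint8), np.zeros(5, np.uint8)])

    @settings(deadline=None)
    @given(bitvec, bitvec, bitvec)
    def test_set_algebra_properties(self, a, b, c):
        merged = merge_combination([a, b])
        # commutative, associative, idempotent
        np.testing.assert_array_equal(merged, merge_combination([b, a]))
        np.testing.assert_array_equal(
            merge_combination([merge_combination([a, b]), c]),
            merge_combination([a, merge_combination([b, c])]),
        )
        np.testing.assert_array_equal(merge_combination([a, a]), a)
        # popcount bounds from set arithmetic
        assert max(a.sum(), b.sum()) <= merged.sum() <= a.sum() + b.sum()


class TestTanimoto:
    def test_identity_and_disjoint(self):
        x = np.array([1, 1, 0, 1], dtype=np.uint8)
        assert tanimoto(x, x) == 1.0
        assert tanimoto(x, np.array([0, 0, 1, 0], dtype=np.uint8)) == 0.0

    def test_worked_example(self):
        a = np.zeros(8, np.uint8); a[[1, 2, 3]] = 1
        b = np.zeros(8, np.uint8); b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5

    def test_all_zero_convention(self):
        z = np.zeros(8, np.uint8)
        with pytest.warns(UserWarning):
            assert tanimoto(z, z) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(np.zeros(8, np.uint8), np.zeros(9, np.uint8))

    @settings(deadline=None)
    @given(bitvec, bitvec)
    def test_symmetry_and_bounds(self, a, b):
        if a.sum() + b.sum() == 0:
            return
        t = tanimoto(a, b)
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0
        assert (t == 1.0) == bool(np.array_equal(a, b))

    def test_agrees_with_set_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a = (rng.random(64) < 0.3).astype(np.uint8)
            b = (rng.random(64) < 0.3).astype(np.uint8)
            if a.sum() + b.sum() == 0:
                continue
            assert abs(tanimoto(a, b) - set_tanimoto(a, b)) < 1e-12


class TestReferencePanel:
    def test_build_order_and_self_similarity(self, drug_records):
        panel = build_reference_panel(drug_records)
        assert panel.size == len(drug_records)
        assert list(panel.drug_ids) == sorted(panel.drug_ids)
        fp = morgan_fingerprint(drug_records[0].components)
        profile = similarity_profile(fp, panel)
        assert profile[panel.drug_ids.index("arv1")] == 1.0
        assert np.all((0.0 <= profile) & (profile <= 1.0))

    def test_rebuild_is_deterministic(self, drug_records):
        p1 = build_reference_panel(drug_records)
        p2 = build_reference_panel(drug_records)
        assert p1.drug_ids == p2.drug_ids
        np.testing.assert_array_equal(p1.fingerprints, p2.fingerprints)

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            build_reference_panel([])

    def test_csv_frame_roundtrip(self, drug_records):
        panel = build_reference_panel(drug_records)
        back = ReferencePanel.from_frame(panel.to_frame(), panel.n_bits)
        assert back.drug_ids == panel.drug_ids
        np.testing.assert_array_equal(back.fingerprints, panel.fingerprints)

    def test_profile_permutation_equivariance(self, drug_records):
        panel = build_reference_panel(drug_records)
        perm = np.array([2, 0, 1, 3, 4, 6, 5])
        shuffled = ReferencePanel(
            tuple(panel.drug_ids[i] for i in perm), panel.fingerprints[perm]
        )
        fp = morgan_fingerprint(["CCCC"])
        np.testing.assert_allclose(
            similarity_profile(fp, shuffled), similarity_profile(fp, panel)[perm]
        )

    def test_length_mismatch_error(self, drug_records):
        panel = build_reference_panel(drug_records)
        with pytest.raises(ValueError, match="length"):
            similarity_profile(np.zeros(512, np.uint8), panel)


class TestPairFeatures:
    def test_similarity_backend_concatenation(self, drug_records):
        feat = SimilarityPairFeaturizer(drugs=drug_records).fit()
        R = len(drug_records)
        assert feat.n_features_out_ == 2 * R
        fwd = pair_features("arv1", "com1", feat)
        rev = pair_features("com1", "arv1", feat)
        np.testing.assert_array_equal(fwd[:R], rev[R:])
        np.testing.assert_array_equal(fwd[R:], rev[:R])

    def test_embedding_stub_backend_length(self, drug_records):
        feat = StubEmbeddingPairFeaturizer(drugs=drug_records).fit()
        assert feat.n_features_out_ == 2 * EMBEDDING_DIM == 1536
        assert pair_features("arv1", "com2", feat).shape == (1536,)

    def test_unknown_drug_id(self, drug_records):
        feat = SimilarityPairFeaturizer(drugs=drug_records).fit()
        with pytest.raises(KeyError, match="nope"):
            feat.transform([("arv1", "nope")])

    def test_unknown_backend(self, drug_records):
        with pytest.raises(ValueError, match="backend"):
            make_featurizer("chembert-external", drug_records)


class TestEmbeddingStub:
    def test_deterministic_and_spelling_invariant(self):
        e1 = embed_smiles_stub(["CCO"])
        e2 = embed_smiles_stub(["OCC"])
        assert e1.shape == (768,)
        np.testing.assert_array_equal(e1, e2)

    def test_distinct_molecules_get_distinct_embeddings(self):
        from ddigrade.simulate import enumerate_smiles

        smiles = enumerate_smiles(limit=100)
        embeddings = np.array([embed_smiles_stub([s]) for s in smiles])
        fingerprints = [tuple(morgan_fingerprint([s])) for s in smiles]
        # identical fingerprints necessarily collide; all others must not
        for i in range(len(smiles)):
            for j in range(i + 1, len(smiles)):
                if fingerprints[i] != fingerprints[j]:
                    assert not np.array_equal(embeddings[i], embeddings[j])
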