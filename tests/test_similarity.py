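"""Fingerprints, Tanimoto, and global-alignment similarity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from dynheter.data_io import DrugRecord, ProteinRecord
from dynheter.similarity import (Fingerprint, drug_similarity_matrix,
                                 morgan_fingerprint, nw_score, nw_score_blosum,
                                 protein_similarity_matrix, tanimoto,
                                 load_similarity_matrix, save_similarity_matrix)


def bitset_fp(bits_on, n_bits=16):
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(bits_on)] = 1
    return Fingerprint(bits=arr, radius=2, n_bits=n_bits)


# -- fingerprints -----------------------------------------------------------

def test_fingerprint_deterministic_and_distinct():
    a1 = morgan_fingerprint("CCO")
    a2 = morgan_fingerprint("CCO")
    b = morgan_fingerprint("CC")
    assert np.array_equal(a1.bits, a2.bits)
    assert not np.array_equal(a1.bits, b.bits)
    assert morgan_fingerprint("c1ccccc1").bits.sum() > 0


def test_invalid_smiles_errors():
    with pytest.raises(ValueError):
        morgan_fingerprint("][")


# -- tanimoto ---------------------------------------------------------------

def test_tanimoto_closed_forms():
    a = bitset_fp({1, 2, 3})
    b = bitset_fp({2, 3, 4})
    assert tanimoto(a, b) == pytest.approx(0.5)   # |{2,3}| / |{1,2,3,4}|
    assert tanimoto(a, a) == pytest.approx(1.0)
    assert tanimoto(bitset_fp({0, 1}), bitset_fp({5, 6})) == 0.0


def test_tanimoto_all_zero_pair_warns_zero():
    z = bitset_fp(set())
    with pytest.warns(UserWarning):
        assert tanimoto(z, z) == 0.0


@settings(max_examples=200, deadline=None)
@given(st.lists(st.booleans(), min_size=16, max_size=16),
       st.lists(st.booleans(), min_size=16, max_size=16))
def test_tanimoto_symmetry_range_and_set_oracle(xs, ys):
    a = bitset_fp({i for i, v in enumerate(xs) if v})
    b = bitset_fp({i for i, v in enumerate(ys) if v})
    sa, sb = {i for i, v in enumerate(xs) if v}, {i for i, v in enumerate(ys) if v}
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_ab, t_ba = tanimoto(a, b), tanimoto(b, a)
    expected = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
    assert t_ab == pytest.approx(expected)
    assert t_ab == t_ba
    assert 0.0 <= t_ab <= 1.0


def test_tanimoto_matches_rdkit_on_real_molecules():
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
    for s1, s2 in [("CCO", "CCN"), ("c1ccccc1", "Cc1ccccc1"), ("CC(=O)O", "CCC(=O)O")]:
        ours = tanimoto(morgan_fingerprint(s1), morgan_fingerprint(s2))
        ref = DataStructs.TanimotoSimilarity(
            gen.GetFingerprint(Chem.MolFromSmiles(s1)),
            gen.GetFingerprint(Chem.MolFromSmiles(s2)))
        assert ours == pytest.approx(ref)


def test_drug_similarity_matrix_properties():
    drugs = [DrugRecord("a", "CCO"), DrugRecord("b", "CCO"), DrugRecord("c", "c1ccccc1")]
    S = drug_similarity_matrix(drugs)
    assert S.values.shape == (3, 3)
    assert S.values[0, 1] == pytest.approx(1.0)   # duplicated SMILES
    assert np.allclose(np.diag(S.values), 1.0)
    fp = [morgan_fingerprint(d.smiles) for d in drugs]
    for i in range(3):
        for j in range(3):
            assert S.values[i, j] == pytest.approx(tanimoto(fp[i], fp[j]))
    assert drug_similarity_matrix([drugs[0]]).values.tolist() == [[1.0]]


# -- Needleman-Wunsch -------------------------------------------------------

def nw_enumerate(a, b, match, mismatch, gap):
    """Exhaustive recursion over all global alignments (oracle)."""
    if not a and not b:
        return 0.0
    opts = []
    if a and b:
        s = match if a[0] == b[0] else mismatch
        opts.append(s + nw_enumerate(a[1:], b[1:], match, mismatch, gap))
    if a:
        opts.append(gap + nw_enumerate(a[1:], b, match, mismatch, gap))
    if b:
        opts.append(gap + nw_enumerate(a, b[1:], match, mismatch, gap))
    return max(opts)


def test_nw_closed_forms():
    assert nw_score("GATTACA", "GCATGCU", 1, -1, -1) == 0.0
    assert nw_score("ACGTAC", "ACGTAC", 1, -1, -1) == 6.0
    assert nw_score("", "AAAA", 1, -1, -1) == -4.0


def test_nw_dp_matches_enumeration_oracle():
    rng = np.random.default_rng(0)
    alphabet = list("ABCD")
    for _ in range(60):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        match, mismatch, gap = 2.0, -1.5, -1.0
        assert nw_score(a, b, match, mismatch, gap) == pytest.approx(
            nw_enumerate(a, b, match, mismatch, gap))


def test_nw_blosum_basics():
    assert nw_score_blosum("ACDEFG", "ACDEFG") > 0
    # X substitution for unknown letters
    assert nw_score_blosum("ACDB" .replace("B", "J"), "ACDX") == nw_score_blosum("ACDX", "ACDX")
    with pytest.raises(ValueError):
        nw_score_blosum("", "ACD")


def test_protein_similarity_matrix_matches_pairwise_oracle():
    prots = [ProteinRecord("p1", "ACDEFGHIKL"), ProteinRecord("p2", "ACDEFGHIKL"),
             ProteinRecord("p3", "MNPQRSTVWY")]
    S = protein_similarity_matrix(prots)
    assert S.values[0, 1] == pytest.approx(1.0)   # identical sequences
    self_s = [nw_score_blosum(p.sequence, p.sequence) for p in prots]
    for i in range(3):
        for j in range(3):
            raw = nw_score_blosum(prots[i].sequence, prots[j].sequence)
            expected = min(1.0, max(0.0, raw / np.sqrt(self_s[i] * self_s[j])))
            assert S.values[i, j] == pytest.approx(expected)
    single = protein_similarity_matrix([prots[0]])
    assert single.values.tolist() == [[1.0]]


def test_similarity_matrix_cache_roundtrip(tmp_path):
    prots = [ProteinRecord("p1", "ACDEF"), ProteinRecord("p2", "ACDFF")]
    S = protein_similarity_matrix(prots, scoring="simple", match=1, mismatch=-1, gap=-1)
    save_similarity_matrix(S, tmp_path / "Sp.txt")
    S2 = load_similarity_matrix(tmp_path / "Sp.txt")
    assert np.allclose(S.values, S2.values) and S2.ids == S.ids and S2.kind == "protein"
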