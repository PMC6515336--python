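import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from diliqsar.chem_io import CompoundRecord
from diliqsar.descriptors import (
    DESCRIPTOR_CLASSES,
    DESCRIPTOR_NAMES,
    BitFingerprint,
    compute_descriptor_matrix,
    compute_descriptors,
    compute_fingerprint,
    diversity_summary,
    tanimoto,
)
from diliqsar.standardize import standardize_structure


def rec(smiles, cid="x"):
    return CompoundRecord(cid, smiles)


def bits(on, n=16):
    arr = np.zeros(n, dtype=bool)
    arr[list(on)] = True
    return BitFingerprint("m", arr)


def test_descriptor_set_is_85_split_30_55():
    assert len(DESCRIPTOR_NAMES) == 85
    classes = list(DESCRIPTOR_CLASSES.values())
    assert classes.count("physicochemical") == 30
    assert classes.count("topological") == 55
    row = compute_descriptors(rec("CC(=O)Oc1ccccc1C(=O)O"))
    assert list(row) == DESCRIPTOR_NAMES


def test_benzene_molecular_weight_matches_atomic_mass_sum():
    # oracle: 6 C + 6 H from standard atomic masses
    expected = 6 * 12.011 + 6 * 1.008
    row = compute_descriptors(rec("c1ccccc1"))
    assert row["MolWt"] == pytest.approx(expected, abs=0.01)


@pytest.mark.parametrize(
    "smiles",
    ["c1ccc2ccccc2c1", "c1ccccc1", "C1CCC2(CC1)CCCCC2", "CCO", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"],
)
def test_ring_count_matches_cyclomatic_oracle(smiles):
    # oracle: smallest-set-of-smallest-rings size equals the cyclomatic
    # number bonds - atoms + components for these single-component molecules
    mol = Chem.MolFromSmiles(smiles)
    expected = mol.GetNumBonds() - mol.GetNumAtoms() + 1
    row = compute_descriptors(rec(smiles))
    assert row["RingCount"] == expected


def test_mandatory_descriptors_present():
    for name in ("MolWt", "ClogP", "Polarizability", "MolarRefractivity",
                 "NumHDonors", "NumHAcceptors", "TPSA", "NumRotatableBonds",
                 "RingCount"):
        assert name in DESCRIPTOR_NAMES


def test_descriptors_are_standardization_invariant():
    raw = standardize_structure(rec("CC(C)Cc1ccc(C(C)C(=O)[O-])cc1.[Na+]"))
    twice = standardize_structure(raw)
    assert compute_descriptors(raw) == compute_descriptors(twice)


def test_descriptor_matrix_flags_unparsable_rows():
    records = [rec("CCO", "ok"), rec("not_a_smiles", "bad")]
    matrix, flagged = compute_descriptor_matrix(records, active_only=False)
    assert flagged == ["bad"]
    assert matrix.compound_ids == ["ok"]
    assert np.isfinite(matrix.values.to_numpy()).all()


def test_descriptor_matrix_csv_round_trip(tmp_path):
    from diliqsar.descriptors import DescriptorMatrix

    matrix, _ = compute_descriptor_matrix([rec("CCO", "a"), rec("CCN", "b")])
    path = matrix.to_csv(tmp_path / "m.csv")
    loaded = DescriptorMatrix.from_csv(path)
    assert loaded.feature_names == matrix.feature_names
    np.testing.assert_allclose(loaded.values.to_numpy(), matrix.values.to_numpy())


# --- fingerprints & Tanimoto -------------------------------------------------


def test_tanimoto_identity_disjoint_and_partial_overlap():
    assert tanimoto(bits({1, 2}), bits({1, 2})) == 1.0
    assert tanimoto(bits({1, 2}), bits({3, 4})) == 0.0
    # 1 shared bit of 3 total
    assert tanimoto(bits({1, 2}), bits({2, 3})) == pytest.approx(1 / 3)


def test_tanimoto_both_empty_is_one_by_convention():
    assert tanimoto(bits(set()), bits(set())) == 1.0


def test_tanimoto_length_mismatch_is_fatal():
    with pytest.raises(ValueError, match="length"):
        tanimoto(bits({1}, n=16), bits({1}, n=32))


@settings(deadline=None, derandomize=True)
@given(
    a=st.sets(st.integers(0, 31), max_size=20),
    b=st.sets(st.integers(0, 31), max_size=20),
)
def test_tanimoto_symmetric_and_bounded(a, b):
    fa, fb = bits(a, 32), bits(b, 32)
    s = tanimoto(fa, fb)
    assert 0.0 <= s <= 1.0
    assert s == tanimoto(fb, fa)
    if a:
        assert tanimoto(fa, fa) == 1.0


def test_fingerprint_deterministic_and_discriminating():
    asp1 = compute_fingerprint(rec("CC(=O)Oc1ccccc1C(=O)O"))
    asp2 = compute_fingerprint(rec("CC(=O)Oc1ccccc1C(=O)O"))
    caf = compute_fingerprint(rec("Cn1cnc2c1c(=O)n(C)c(=O)n2C"))
    assert np.array_equal(asp1.bits, asp2.bits)
    assert tanimoto(asp1, caf) < 1.0


def test_methane_has_no_paths_hence_zero_fingerprint():
    fp = compute_fingerprint(rec("C"))
    assert fp.on_bits.size == 0


def test_fingerprint_hex_round_trip():
    fp = compute_fingerprint(rec("CCO"))
    back = BitFingerprint.from_hex("m", fp.to_hex(), n_bits=fp.n_bits)
    assert np.array_equal(back.bits, fp.bits)


# --- diversity ---------------------------------------------------------------


def test_diversity_mean_equals_brute_force_pairwise_mean():
    records = [rec("CCO", "a"), rec("CCCN", "b"), rec("c1ccccc1", "c")]
    fps = {r.compound_id: compute_fingerprint(r) for r in records}
    expected = np.mean(
        [
            tanimoto(fps["a"], fps["b"]),
            tanimoto(fps["a"], fps["c"]),
            tanimoto(fps["b"], fps["c"]),
        ]
    )
    summary = diversity_summary(records)
    assert summary.mean_tanimoto == pytest.approx(expected)
    assert summary.n_pairs == 3
    assert summary.histogram_counts.sum() == 3


def test_diversity_of_identical_molecules_is_one():
    records = [rec("CCO", f"c{i}") for i in range(4)]
    assert diversity_summary(records).mean_tanimoto == 1.0


def test_diversity_needs_two_compounds():
    with pytest.raises(ValueError):
        diversity_summary([rec("CCO", "a")])
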