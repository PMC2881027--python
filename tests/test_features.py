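"""Composition features, physicochemical indices, redundancy filtering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from orgproteome.features import (
    CompositionVectorizer,
    aliphatic_index,
    class_prevalences,
    composition,
    feature_names,
    gravy,
    pairwise_identity,
    redundancy_filter,
)
from orgproteome.records import AMINO_ACIDS, ProteinRecord

from conftest import random_sequence

sequences = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=50)


def naive_composition(seq: str, order: int, exclusion_mode: str = "none") -> dict:
    """Independent double-loop counting oracle."""
    names = feature_names(order, exclusion_mode)
    counts = {n: 0 for n in names}
    for i in range(len(seq) - order + 1):
        word = seq[i : i + order]
        if word in counts:
            counts[word] += 1
    return {n: c / len(seq) for n, c in counts.items()}


@pytest.mark.parametrize("order", [1, 2])
@pytest.mark.parametrize("mode", ["none", "drop_CH"])
def test_composition_matches_bruteforce(order, mode):
    rng = np.random.default_rng(42)
    for _ in range(40):
        seq = random_sequence(rng, int(rng.integers(order, 51)))
        got = composition(seq, order=order, exclusion_mode=mode).values
        assert got == naive_composition(seq, order, mode)


def test_composition_examples():
    v = composition("AAAA", order=1).values
    assert v["A"] == 1.0 and sum(v.values()) == 1.0
    v = composition("ACAC", order=2).values
    assert v["AC"] == 0.5 and v["CA"] == 0.25
    assert sum(v.values()) == pytest.approx(3 / 4)
    # every adjacent pair of ACAC contains C, so the C/H-free space is empty
    v = composition("ACAC", order=2, exclusion_mode="drop_CH").values
    assert len(v) == 324 and all(x == 0.0 for x in v.values())


def test_feature_space_sizes():
    assert len(feature_names(1)) == 20
    assert len(feature_names(2)) == 400
    assert len(feature_names(1, "drop_CH")) == 18
    assert len(feature_names(2, "drop_CH")) == 324


def test_mask_cxxch_zeroes_motif_residues():
    seq = "MCAACHKKKK"  # CxxCH spans positions 2-6
    v = composition(seq, order=1, exclusion_mode="mask_CxxCH").values
    assert v["C"] == 0.0 and v["H"] == 0.0 and v["A"] == 0.0
    assert v["K"] == pytest.approx(0.4) and v["M"] == pytest.approx(0.1)


def test_composition_errors():
    with pytest.raises(ValueError, match="nonempty"):
        composition("", order=1)
    with pytest.raises(ValueError, match="'B'"):
        composition("ABA", order=1)
    with pytest.raises(ValueError, match="too short"):
        composition("A", order=2)


@given(seq=sequences)
def test_normalisation_sums(seq):
    L = len(seq)
    assert sum(composition(seq, 1).values.values()) == pytest.approx(1.0)
    assert sum(composition(seq, 2).values.values()) == pytest.approx((L - 1) / L)


def test_physchem_closed_forms():
    assert gravy("I") == pytest.approx(4.5)
    assert gravy("IR") == pytest.approx(0.0)
    assert aliphatic_index("AAAA") == pytest.approx(100.0)
    assert aliphatic_index("VV") == pytest.approx(290.0)
    assert aliphatic_index("GGGG") == pytest.approx(0.0)


@given(seq=sequences)
def test_physchem_invariances(seq):
    shuffled = "".join(sorted(seq))
    assert gravy(seq) == pytest.approx(gravy(shuffled))
    assert aliphatic_index(seq) == pytest.approx(aliphatic_index(shuffled))
    assert gravy(seq + seq) == pytest.approx(gravy(seq))
    assert aliphatic_index(seq + seq) == pytest.approx(aliphatic_index(seq))


def test_class_prevalences_bounds():
    prev = class_prevalences("ILVKRDE")
    assert prev["ILV"] == pytest.approx(3 / 7)
    assert prev["KR"] == pytest.approx(2 / 7)
    assert all(0 <= v <= 1 for v in prev.values())


def test_pairwise_identity_endpoints():
    assert pairwise_identity("PEPTIDE", "PEPTIDE") == 1.0
    assert pairwise_identity("AAAA", "KKKK") == 0.0


def test_redundancy_filter():
    recs = [
        ProteinRecord("a", "PEPTIDE"),
        ProteinRecord("b", "PEPTIDE"),
        ProteinRecord("c", "KKKKKK"),
    ]
    kept = redundancy_filter(recs)
    assert [r.id for r in kept] == ["a", "c"]  # equal length -> later removed
    kept = redundancy_filter([ProteinRecord("x", "AAAA"), ProteinRecord("y", "WWWW")])
    assert len(kept) == 2
    # shorter member of a redundant pair is removed
    kept = redundancy_filter(
        [ProteinRecord("short", "PEPTIDE"), ProteinRecord("long", "PEPTIDEK")]
    )
    assert [r.id for r in kept] == ["long"]


def test_vectorizer_regions():
    rec = ProteinRecord("p", "MKKLLLLLLSAAGGGG", sp_truth=10)
    vec = CompositionVectorizer(region="sp", order=1).fit([])
    sp_vec = vec.transform([rec])[0]
    names = list(vec.get_feature_names_out())
    assert sp_vec[names.index("L")] == pytest.approx(6 / 10)
    mat = CompositionVectorizer(region="mature", order=1).fit([]).transform([rec])[0]
    assert mat[names.index("G")] == pytest.approx(4 / 6)


def test_vectorizer_requires_cleavage_index():
    rec = ProteinRecord("p", "MKKLLLLLLSAAGGGG")
    with pytest.raises(ValueError, match="cleavage index"):
        CompositionVectorizer(region="sp").fit([]).transform([rec])


def test_vectorizer_sklearn_contract():
    from sklearn.base import clone

    vec = CompositionVectorizer(region="mature", order=1, exclusion_mode="drop_CH")
    params = vec.get_params()
    assert params["region"] == "mature"
    vec2 = clone(vec)
    assert vec2.get_params() == params
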