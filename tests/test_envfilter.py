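"""One-sphere environment keys, reference dictionary, candidate filtering."""

import pytest
from hypothesis import given, settings, strategies as st

from nmrcase import (
    EmptyCorpusError,
    ReferenceDict,
    build_reference,
    constitution_from_smiles,
    env_keys,
    filter_candidates,
    load_reference,
    make_toy_structures,
    save_reference,
    summarize_missing,
)


def _renders(m):
    return [k.render() for k in env_keys(m)]


def test_env_key_examples():
    methane = constitution_from_smiles("C")
    assert _renders(methane) == ["C[+0]H4()"]
    ethanol = constitution_from_smiles("CCO")
    assert _renders(ethanol) == [
        "C[+0]H3(C:1)",
        "C[+0]H2(C:1,O:1)",
        "O[+0]H1(C:1)",
    ]


def test_methyl_keys_distinguish_ethanol_from_ether():
    ethanol_methyl = _renders(constitution_from_smiles("CCO"))[0]
    ether_methyl = _renders(constitution_from_smiles("COC"))[0]
    assert ethanol_methyl == "C[+0]H3(C:1)"
    assert ether_methyl == "C[+0]H3(O:1)"


def test_neighbor_sort_is_element_then_order():
    # acrolein carbonyl carbon: neighbors C single, O double, H1
    acrolein = constitution_from_smiles("C=CC=O")
    assert "C[+0]H1(C:1,O:2)" in _renders(acrolein)


def test_aromatic_token_merges_kekule_forms():
    toluene = _renders(constitution_from_smiles("Cc1ccccc1"))
    assert "C[+0]H1(C:ar,C:ar)" in toluene
    assert "C[+0]H0(C:1,C:ar,C:ar)" in toluene
    assert not any(":2" in key and "ar" in key for key in toluene)


def test_radius_one_locality():
    """Atoms two or more bonds away do not affect a key: the methyl group of
    ethanol and of propan-1-ol render identically."""
    assert _renders(constitution_from_smiles("CCO"))[0] == \
        _renders(constitution_from_smiles("CCCO"))[0]


def test_build_reference_counts():
    methane = constitution_from_smiles("C")
    ref1 = build_reference([methane])
    assert ref1.entries == {"C[+0]H4()": 1}
    ref2 = build_reference([methane, methane])
    assert ref2.entries == {"C[+0]H4()": 2}
    ethanol_ref = build_reference([constitution_from_smiles("CCO")])
    assert ethanol_ref.entries == {
        "C[+0]H3(C:1)": 1,
        "C[+0]H2(C:1,O:1)": 1,
        "O[+0]H1(C:1)": 1,
    }


def test_empty_corpus_is_an_error():
    with pytest.raises(EmptyCorpusError):
        build_reference([])


def test_min_count_strictness():
    mols = [constitution_from_smiles(s) for s in ("CCO", "CC", "CC")]
    strict = build_reference(mols, min_count=2)
    assert set(strict.entries) == {"C[+0]H3(C:1)"}


def test_filter_ethanol_vs_ether(ethanol, dimethyl_ether):
    ref = build_reference([ethanol])
    report = filter_candidates([ethanol, dimethyl_ether], ref)
    assert [m.canonical_smiles() for m in report.kept.constitutions] == ["CCO"]
    assert len(report.removed) == 1
    removed, missing = report.removed[0]
    assert removed.canonical_smiles() == "COC"
    assert missing == ["C[+0]H3(O:1)", "O[+0]H0(C:1,C:1)"]
    assert report.reduction == pytest.approx(0.5)


def test_self_reference_keeps_everything(toy_structures):
    ref = build_reference(toy_structures)
    report = filter_candidates(list(toy_structures), ref)
    assert not report.removed and report.reduction == 0.0


def test_filter_safety(toy_structures, reference_corpus):
    """A structure whose environments are all present in the reference is
    never removed, whatever else the corpus holds."""
    ref = build_reference(reference_corpus)
    for structure in toy_structures:
        augmented = ReferenceDict(
            entries={
                **ref.entries,
                **{k.render(): 1 for k in env_keys(structure)},
            }
        )
        report = filter_candidates(list(toy_structures), augmented)
        kept = {m.canonical_smiles() for m in report.kept.constitutions}
        assert structure.canonical_smiles() in kept


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_filter_monotone_in_corpus(seed):
    """Growing the reference can only grow the kept set."""
    candidates = make_toy_structures(seed=seed, n=6, heavy_atom_range=(2, 5))
    small = build_reference(candidates[:2])
    large = build_reference(candidates[:5])
    assert set(small.entries) <= set(large.entries)
    kept_small = {
        m.canonical_smiles()
        for m in filter_candidates(candidates, small).kept.constitutions
    }
    kept_large = {
        m.canonical_smiles()
        for m in filter_candidates(candidates, large).kept.constitutions
    }
    assert kept_small <= kept_large


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_filter_is_idempotent(seed):
    candidates = make_toy_structures(seed=seed, n=8, heavy_atom_range=(2, 5))
    ref = build_reference(candidates[:3])
    first = filter_candidates(candidates, ref)
    second = filter_candidates(first.kept, ref)
    assert not second.removed
    assert second.kept.keys == first.kept.keys


def test_reduction_bounds(toy_structures, reference_corpus):
    ref = build_reference(reference_corpus)
    report = filter_candidates(list(toy_structures), ref)
    assert 0.0 <= report.reduction <= 1.0
    assert len(report.kept) + len(report.removed) == len(toy_structures)


def test_summarize_missing_ordering(ethanol, dimethyl_ether):
    ref = build_reference([ethanol])
    candidates = [dimethyl_ether] * 3 + [constitution_from_smiles("CN")]
    table = summarize_missing(filter_candidates(candidates, ref))
    assert list(table.columns) == ["env_key", "n_candidates"]
    counts = list(table["n_candidates"])
    assert counts == sorted(counts, reverse=True)
    assert table.iloc[0]["n_candidates"] == 3
    # ties broken lexically
    tied = table[table["n_candidates"] == 3]["env_key"].tolist()
    assert tied == sorted(tied)


def test_summarize_empty_report(toy_structures):
    ref = build_reference(toy_structures)
    table = summarize_missing(filter_candidates(list(toy_structures), ref))
    assert table.empty


def test_reference_tsv_round_trip(tmp_path, reference_corpus):
    ref = build_reference(reference_corpus, source="toy corpus")
    path = tmp_path / "ref.tsv"
    save_reference(ref, str(path))
    text = path.read_text()
    assert text.startswith("#") and "env_key\tcount" in text
    back = load_reference(str(path))
    assert back.entries == ref.entries
    assert back.meta["source"] == "toy corpus"
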