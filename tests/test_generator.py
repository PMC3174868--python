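"""Enumeration: worked examples, oracle equivalence, soundness, monotonicity."""

import pytest

from nmrcase import (
    AtomSpec,
    CorrelationSet,
    ForwardConfig,
    GenerationConfig,
    InfeasibleError,
    OracleLimitError,
    brute_force_enumerate,
    check_satisfies,
    compile_constraints,
    dbe,
    enumerate_constitutions,
    forward_correlations,
    make_toy_structures,
    parse_formula,
    structure_to_atomspecs,
)


def _forward_problem(structure, experiments=("COSY", "HMBC"), dropout=0.0,
                     seed=0, open_types=False):
    correlations = forward_correlations(
        structure, ForwardConfig(experiments=experiments, dropout=dropout, seed=seed)
    )
    atoms = structure_to_atomspecs(structure, open_types=open_types)
    constraints = compile_constraints(correlations, atoms)
    return structure.formula(), atoms, constraints


def test_methane_has_one_constitution():
    result = enumerate_constitutions(
        parse_formula("CH4"), [AtomSpec("C1", "C", 4)], []
    )
    assert [m.canonical_smiles() for m in result.constitutions] == ["C"]
    oracle = brute_force_enumerate(parse_formula("CH4"), [AtomSpec("C1", "C", 4)], [])
    assert oracle.keys == result.keys


ETHANOL_ATOMS = [
    AtomSpec("C1", "C", 3, hybridization="sp3"),
    AtomSpec("C2", "C", 2, hybridization="sp3"),
]


def test_ethanol_micro_example_yields_exactly_one():
    """COSY C1-C2 plus HMBC C1<-H(C2) pins C2H6O down to ethanol."""
    constraints = compile_constraints(
        CorrelationSet(cosy=(("C1", "C2"),), hmbc=(("C1", "C2"),)), ETHANOL_ATOMS
    )
    result = enumerate_constitutions(
        parse_formula("C2H6O"), ETHANOL_ATOMS, constraints
    )
    assert [m.canonical_smiles() for m in result.constitutions] == ["CCO"]


def test_unconstrained_c2h6o_count_frozen_by_oracle():
    """With HSQC-fixed proton counts (CH3, CH2, silent O) the full
    unconstrained set is a single constitution — value frozen from the
    brute-force oracle."""
    result = enumerate_constitutions(parse_formula("C2H6O"), ETHANOL_ATOMS, [])
    oracle = brute_force_enumerate(parse_formula("C2H6O"), ETHANOL_ATOMS, [])
    assert result.keys == oracle.keys
    assert len(result) == 1 and "CCO" in result.keys


def test_propane_round_trip_matches_oracle():
    from nmrcase import constitution_from_smiles

    propane = constitution_from_smiles("CCC", atom_ids=("C1", "C2", "C3"))
    formula, atoms, constraints = _forward_problem(propane)
    result = enumerate_constitutions(formula, atoms, constraints)
    oracle = brute_force_enumerate(formula, atoms, constraints)
    assert propane.canonical_smiles() in result.keys
    assert result.keys == oracle.keys


@pytest.mark.parametrize("index", range(8))
def test_oracle_equivalence_on_random_inputs(toy_structures, index):
    """Constraint-propagating search and naive generate-then-filter must
    agree on the canonical-key set (dropout leaves the problem
    under-determined so the sets are non-trivial)."""
    structure = toy_structures[index]
    formula, atoms, constraints = _forward_problem(
        structure, dropout=0.3, seed=100 + index
    )
    fast = enumerate_constitutions(formula, atoms, constraints)
    slow = brute_force_enumerate(formula, atoms, constraints)
    assert fast.keys == slow.keys


def test_outputs_are_sound(toy_structures):
    """Every emitted constitution satisfies the constraints, the valence
    table, and the degree-of-unsaturation balance with the formula."""
    for i, structure in enumerate(toy_structures[:6]):
        formula, atoms, constraints = _forward_problem(
            structure, dropout=0.4, seed=i
        )
        result = enumerate_constitutions(formula, atoms, constraints)
        assert len(result.keys) == len(result.constitutions)
        for m in result.constitutions:
            m.validate()
            ok, violated = check_satisfies(m, constraints)
            assert ok, violated
            rings = len(m.bonds) - m.n_atoms + 1
            unsaturation = sum(o - 1 for _i, _j, o in m.bonds)
            assert rings + unsaturation == dbe(formula)


def test_adding_a_constraint_never_enlarges_the_set(toy_structures):
    import random

    rng = random.Random(77)
    checked = 0
    for structure in toy_structures:
        formula, atoms, full = _forward_problem(structure)
        if len(full) < 2:
            continue
        k = rng.randrange(1, len(full))
        subset = rng.sample(full, k)
        extra = rng.choice([c for c in full if c not in subset])
        base = enumerate_constitutions(formula, atoms, subset)
        tightened = enumerate_constitutions(formula, atoms, subset + [extra])
        assert tightened.keys <= base.keys
        checked += 1
    assert checked >= 5


def test_fixed_types_are_subset_of_open_types(toy_structures):
    """Predefining hybridizations can only remove candidates, mirroring the
    open vs fixed run pairs."""
    for structure in toy_structures[:8]:
        formula, atoms_fixed, cs_fixed = _forward_problem(structure)
        _, atoms_open, cs_open = _forward_problem(structure, open_types=True)
        fixed = enumerate_constitutions(formula, atoms_fixed, cs_fixed)
        open_ = enumerate_constitutions(
            formula, atoms_open, cs_open, GenerationConfig(open_types=True)
        )
        assert fixed.keys <= open_.keys
        assert structure.canonical_smiles() in fixed.keys


def test_result_set_is_independent_of_atom_order(toy_structures):
    structure = toy_structures[3]
    formula, atoms, constraints = _forward_problem(structure, dropout=0.3, seed=9)
    reference = enumerate_constitutions(formula, atoms, constraints)
    permuted = enumerate_constitutions(formula, atoms[::-1], constraints)
    assert permuted.keys == reference.keys


def test_mandatory_degree_overflow_fails_before_search():
    atoms = [
        AtomSpec("C1", "C", 3),
        AtomSpec("C2", "C", 3),
        AtomSpec("C3", "C", 2),
    ]
    # C1 has one free valence but two one-bond constraints
    constraints = compile_constraints(
        CorrelationSet(cosy=(("C1", "C2"), ("C1", "C3"))), atoms
    )
    with pytest.raises(InfeasibleError, match="C1"):
        enumerate_constitutions(parse_formula("C3H8"), atoms, constraints)


def test_excess_protons_are_infeasible():
    with pytest.raises(InfeasibleError):
        enumerate_constitutions(
            parse_formula("C2H4"),
            [AtomSpec("C1", "C", 3), AtomSpec("C2", "C", 3)],
            [],
        )


def test_truncation_is_flagged_never_silent():
    atoms = [AtomSpec(f"C{i}", "C", 1) for i in range(1, 7)]
    cfg = GenerationConfig(max_results=2)
    result = enumerate_constitutions(parse_formula("C6H6"), atoms, [], cfg)
    assert len(result) == 2 and result.truncated


def test_min_ring_size_excludes_small_rings():
    atoms = [AtomSpec(f"C{i}", "C", 2, hybridization="sp3") for i in (1, 2, 3)]
    default = enumerate_constitutions(parse_formula("C3H6"), atoms, [])
    assert [m.canonical_smiles() for m in default.constitutions] == ["C1CC1"]
    strict = enumerate_constitutions(
        parse_formula("C3H6"), atoms, [], GenerationConfig(min_ring_size=4)
    )
    assert len(strict) == 0


def test_heteroatom_bond_policy():
    atoms = [AtomSpec("C1", "C", 3, hybridization="sp3")]
    allowed = enumerate_constitutions(parse_formula("CH4O2"), atoms, [])
    assert [m.canonical_smiles() for m in allowed.constitutions] == ["COO"]
    forbidden = enumerate_constitutions(
        parse_formula("CH4O2"), atoms, [],
        GenerationConfig(forbid_heteroatom_heteroatom_bonds=True),
    )
    assert len(forbidden) == 0


def test_oracle_refuses_large_problems():
    atoms = [AtomSpec(f"C{i}", "C", 1) for i in range(1, 9)]
    with pytest.raises(OracleLimitError):
        brute_force_enumerate(parse_formula("C8H8"), atoms, [])


def test_completeness_holds_for_every_fixture(toy_structures):
    """The true structure is always among the solutions generated from its
    own dropout-free correlations."""
    for structure in toy_structures:
        formula, atoms, constraints = _forward_problem(
            structure, experiments=("COSY", "HMBC", "N15HMBC", "ADEQUATE11")
        )
        result = enumerate_constitutions(formula, atoms, constraints)
        assert structure.canonical_smiles() in result.keys
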