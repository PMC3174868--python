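"""Exhaustive enumeration of constitutions compatible with NMR constraints.

Given a molecular formula, per-atom NMR records (fixed or open bonding
states) and compiled path constraints, :func:`enumerate_constitutions`
returns every isomorphism class of connected, valence-legal molecular graph
that satisfies them, deduplicated by canonical SMILES.  The search is a
depth-first assignment of bond orders to atom pairs with constraint
propagation:

* one-bond constraints (COSY, 1,1-ADEQUATE) become mandatory edges and are
  checked for valence feasibility before the search starts;
* per-atom free valence bounds every branch, and an atom's bond-order
  multiset is checked against its allowed hybridizations (sp3: all single,
  sp2: exactly one double, sp: one triple or two cumulated doubles) as soon
  as all its pairs are decided;
* ambiguous HMBC constraints, connectivity and minimum ring size are checked
  on each completed graph.

Hydrogens left over after the fixed HSQC counts are distributed exhaustively
over the NMR-silent heteroatoms.  Because every atom's bond-order sum matches
its valence exactly and the graph is connected, the degree-of-unsaturation
balance with the formula holds by construction (and is asserted in tests).

:func:`brute_force_enumerate` is the independent oracle: a naive
generate-then-filter enumeration with no propagation beyond the valence cap,
feasible only for small heavy-atom counts.  Both routes must agree on the
canonical-key set.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .constraints import PathConstraint, check_satisfies
from .datamodel import (
    OPEN,
    HYBRIDIZATIONS,
    VALENCES,
    Atom,
    AtomSpec,
    Constitution,
    MolecularFormula,
    check_unique_ids,
    dbe,
)
from .errors import FormulaError, InfeasibleError, OracleLimitError

_ALL_HYB = frozenset(HYBRIDIZATIONS)


@dataclasses.dataclass
class GenerationConfig:
    """Knobs of the generator.

    ``open_types`` overrides every atom's hybridization to open (the
    "no atom types were defined" run mode); ``allowed_hybridizations``
    restricts what open atoms may enumerate, per element.  ``seed`` exists
    for interface symmetry with the fixture generator — the result *set* is
    deterministic and seed-independent.
    """

    open_types: bool = False
    allowed_hybridizations: Mapping[str, frozenset[str]] | None = None
    min_ring_size: int = 3
    max_results: int = 1_000_000
    forbid_heteroatom_heteroatom_bonds: bool = False
    allow_4bond_hmbc: bool = False
    seed: int = 0
    oracle_limit: int = 7

    def __post_init__(self) -> None:
        if self.min_ring_size < 3:
            raise InfeasibleError("min_ring_size must be at least 3")
        if self.max_results < 1:
            raise InfeasibleError("max_results must be positive")


@dataclasses.dataclass
class CandidateSet:
    """Deduplicated result set of a generator run plus run metadata."""

    constitutions: list[Constitution]
    keys: set[str]
    meta: dict[str, object] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.constitutions)

    @property
    def truncated(self) -> bool:
        return bool(self.meta.get("truncated", False))


# ---------------------------------------------------------------------------
# Shared problem setup
# ---------------------------------------------------------------------------

def _hybridization_of(n_double: int, n_triple: int) -> str | None:
    if n_triple == 0 and n_double == 0:
        return "sp3"
    if n_triple == 0 and n_double == 1:
        return "sp2"
    if (n_triple == 1 and n_double == 0) or (n_triple == 0 and n_double == 2):
        return "sp"
    return None


def _partial_hyb_ok(n_double: int, n_triple: int, allowed: frozenset[str]) -> bool:
    """Can the multiset still grow into a member of ``allowed``?"""
    for hyb in allowed:
        if hyb == "sp3" and n_double == 0 and n_triple == 0:
            return True
        if hyb == "sp2" and n_double <= 1 and n_triple == 0:
            return True
        if hyb == "sp" and (
            (n_triple == 1 and n_double == 0)
            or (n_triple == 0 and n_double <= 2)
        ):
            return True
    return False


@dataclasses.dataclass
class _Problem:
    elements: list[str]            # per heavy-atom index
    ids: list[str]
    fixed_h: list[int | None]      # None for silent atoms (to be distributed)
    allowed_hyb: list[frozenset[str]]
    n_observed: int
    leftover_h: int
    mandatory: set[tuple[int, int]]
    constraints: list[PathConstraint]


def _setup(
    formula: MolecularFormula,
    atoms: Sequence[AtomSpec],
    constraints: Sequence[PathConstraint],
    cfg: GenerationConfig,
) -> _Problem:
    check_unique_ids(atoms)
    dbe(formula)  # rejects inconsistent formulas up front

    heavy = dict(formula.heavy_counts)
    observed = Counter(a.element for a in atoms)
    for el, n in observed.items():
        if heavy.get(el, 0) < n:
            raise InfeasibleError(
                f"{n} observed {el} atoms but formula {formula.hill()} has"
                f" only {heavy.get(el, 0)}"
            )
    silent: list[str] = []
    for el in sorted(heavy):
        if el not in VALENCES:
            raise FormulaError(f"no configured valence for element {el}")
        silent.extend([el] * (heavy[el] - observed.get(el, 0)))

    leftover_h = formula.n_hydrogens - sum(a.n_h for a in atoms)
    if leftover_h < 0:
        raise InfeasibleError(
            "attached-proton counts exceed the hydrogen count of the formula"
        )

    elements = [a.element for a in atoms] + silent
    ids = [a.id for a in atoms] + [
        f"{el}*{k}" for k, el in enumerate(silent, start=1)
    ]
    fixed_h: list[int | None] = [a.n_h for a in atoms] + [None] * len(silent)

    hyb_table = dict(cfg.allowed_hybridizations or {})
    allowed_hyb: list[frozenset[str]] = []
    for a in atoms:
        if cfg.open_types or a.hybridization == OPEN:
            allowed_hyb.append(frozenset(hyb_table.get(a.element, _ALL_HYB)))
        else:
            allowed_hyb.append(frozenset({a.hybridization}))
    allowed_hyb.extend(frozenset(hyb_table.get(el, _ALL_HYB)) for el in silent)

    index = {atom_id: i for i, atom_id in enumerate(ids)}
    mandatory: set[tuple[int, int]] = set()
    for c in constraints:
        for endpoint in (c.a, c.b):
            if endpoint not in index:
                raise InfeasibleError(
                    f"constraint references unknown atom id {endpoint!r}"
                )
        if c.allowed_lengths == frozenset({1}):
            i, j = index[c.a], index[c.b]
            mandatory.add((min(i, j), max(i, j)))

    # every mandatory edge costs one unit of valence at both ends
    degree = Counter(itertools.chain.from_iterable(mandatory))
    for i, need in degree.items():
        free = VALENCES[elements[i]] - (fixed_h[i] or 0)
        if need > free:
            raise InfeasibleError(
                f"atom {ids[i]} needs {need} mandatory bonds but has only"
                f" {free} free valences"
            )

    return _Problem(
        elements=elements,
        ids=ids,
        fixed_h=fixed_h,
        allowed_hyb=allowed_hyb,
        n_observed=len(atoms),
        leftover_h=leftover_h,
        mandatory=mandatory,
        constraints=list(constraints),
    )


def _h_distributions(problem: _Problem) -> Iterable[list[int]]:
    """All ways to place the leftover hydrogens on silent heteroatoms.

    Full per-atom H vectors are yielded.  Atoms keep at least one free
    valence for bonding unless the molecule is a single heavy atom.
    Assignments that differ only by permuting silent atoms of one element
    are collapsed (the graphs would be isomorphic anyway).
    """
    n = len(problem.elements)
    silent_idx = [i for i, h in enumerate(problem.fixed_h) if h is None]
    base = [h or 0 for h in problem.fixed_h]
    if not silent_idx:
        if problem.leftover_h:
            raise InfeasibleError(
                f"{problem.leftover_h} hydrogens left over but no silent"
                " heteroatom can carry them"
            )
        yield base
        return

    caps = []
    for i in silent_idx:
        cap = VALENCES[problem.elements[i]]
        if n > 1:
            cap -= 1  # keep one valence to stay connected
        caps.append(cap)

    seen: set[tuple[tuple[str, tuple[int, ...]], ...]] = set()
    for combo in itertools.product(*(range(c + 1) for c in caps)):
        if sum(combo) != problem.leftover_h:
            continue
        by_el: dict[str, list[int]] = {}
        for i, h in zip(silent_idx, combo):
            by_el.setdefault(problem.elements[i], []).append(h)
        signature = tuple(
            (el, tuple(sorted(hs))) for el, hs in sorted(by_el.items())
        )
        if signature in seen:
            continue
        seen.add(signature)
        vec = list(base)
        for i, h in zip(silent_idx, combo):
            vec[i] = h
        yield vec


def _connected(n: int, edges: Iterable[tuple[int, int]]) -> bool:
    if n <= 1:
        return True
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    count = 0
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
        count += 1
    if count < n - 1:
        return False
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def _girth_ok(n: int, edges: list[tuple[int, int]], min_ring: int) -> bool:
    """Reject graphs containing a cycle shorter than ``min_ring``."""
    if min_ring <= 3:
        return True
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    # BFS from every vertex; a cycle of length g is seen from some root as
    # two paths meeting at depth <= g/2
    for root in range(n):
        depth = {root: 0}
        parent = {root: -1}
        queue = [root]
        while queue:
            node = queue.pop(0)
            for nb in adj[node]:
                if nb == parent[node]:
                    continue
                if nb in depth:
                    cycle = depth[node] + depth[nb] + 1
                    if cycle < min_ring:
                        return False
                else:
                    depth[nb] = depth[node] + 1
                    parent[nb] = node
                    queue.append(nb)
        # parallel edges impossible (simple bond set)
    return True


def _build(problem: _Problem, h_vec: list[int],
           edge_orders: dict[tuple[int, int], int]) -> Constitution:
    atoms = tuple(
        Atom(el, 0, h) for el, h in zip(problem.elements, h_vec)
    )
    bonds = frozenset((i, j, o) for (i, j), o in edge_orders.items() if o)
    return Constitution(atoms=atoms, bonds=bonds, atom_ids=tuple(problem.ids))


class _Truncated(Exception):
    pass


# ---------------------------------------------------------------------------
# Main search
# ---------------------------------------------------------------------------

def enumerate_constitutions(
    formula: MolecularFormula,
    atoms: Sequence[AtomSpec],
    constraints: Sequence[PathConstraint],
    cfg: GenerationConfig | None = None,
) -> CandidateSet:
    """Enumerate every constitution compatible with formula, atom records and
    path constraints; deduplicate canonically.

    The returned set is independent of atom input order.  If ``max_results``
    is reached the search stops and ``meta['truncated']`` is set — never a
    silent loss.
    """
    cfg = cfg or GenerationConfig()
    problem = _setup(formula, atoms, constraints, cfg)
    n = len(problem.elements)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # after this pair index, all pairs touching atom k are decided
    last_pair_of: dict[int, int] = {}
    for p, (i, j) in enumerate(pairs):
        last_pair_of[i] = max(last_pair_of.get(i, -1), p)
        last_pair_of[j] = max(last_pair_of.get(j, -1), p)
    completions: dict[int, list[int]] = {}
    for atom_idx, p in last_pair_of.items():
        completions.setdefault(p, []).append(atom_idx)

    results: dict[str, Constitution] = {}
    meta: dict[str, object] = {"truncated": False, "n_explored": 0}

    def finish(h_vec: list[int], orders: dict[tuple[int, int], int]) -> None:
        edges = [(i, j) for (i, j), o in orders.items() if o]
        if not _connected(n, edges):
            return
        if not _girth_ok(n, edges, cfg.min_ring_size):
            return
        m = _build(problem, h_vec, orders)
        ok, _ = check_satisfies(m, problem.constraints)
        if not ok:
            return
        key = m.canonical_smiles()
        if key not in results:
            if len(results) >= cfg.max_results:
                meta["truncated"] = True
                raise _Truncated
            results[key] = m

    for h_vec in _h_distributions(problem):
        free = [
            VALENCES[el] - h for el, h in zip(problem.elements, h_vec)
        ]
        if any(f < 0 for f in free):
            continue
        if n == 1:
            if free[0] == 0:
                try:
                    finish(h_vec, {})
                except _Truncated:
                    break
            continue

        rem = list(free)
        n_double = [0] * n
        n_triple = [0] * n
        orders: dict[tuple[int, int], int] = {}

        def search(p: int) -> None:
            if p == len(pairs):
                finish(h_vec, dict(orders))
                return
            i, j = pairs[p]
            hetero = (
                cfg.forbid_heteroatom_heteroatom_bonds
                and problem.elements[i] != "C"
                and problem.elements[j] != "C"
            )
            is_mandatory = (i, j) in problem.mandatory
            lo = 1 if is_mandatory else 0
            hi = 0 if hetero else min(3, rem[i], rem[j])
            if hetero and is_mandatory:
                return
            for order in range(lo, hi + 1):
                if order:
                    orders[(i, j)] = order
                    rem[i] -= order
                    rem[j] -= order
                    if order == 2:
                        n_double[i] += 1
                        n_double[j] += 1
                    elif order == 3:
                        n_triple[i] += 1
                        n_triple[j] += 1
                ok = True
                if order and not (
                    _partial_hyb_ok(n_double[i], n_triple[i], problem.allowed_hyb[i])
                    and _partial_hyb_ok(n_double[j], n_triple[j], problem.allowed_hyb[j])
                ):
                    ok = False
                if ok:
                    for atom_idx in completions.get(p, ()):
                        if rem[atom_idx] != 0 or _hybridization_of(
                            n_double[atom_idx], n_triple[atom_idx]
                        ) not in problem.allowed_hyb[atom_idx]:
                            ok = False
                            break
                if ok:
                    meta["n_explored"] += 1  # type: ignore[operator]
                    search(p + 1)
                if order:
                    del orders[(i, j)]
                    rem[i] += order
                    rem[j] += order
                    if order == 2:
                        n_double[i] -= 1
                        n_double[j] -= 1
                    elif order == 3:
                        n_triple[i] -= 1
                        n_triple[j] -= 1

        try:
            search(0)
        except _Truncated:
            break

    ordered = [results[k] for k in sorted(results)]
    meta.update(
        n_results=len(ordered),
        n_constraints=len(problem.constraints),
        open_types=cfg.open_types,
    )
    return CandidateSet(constitutions=ordered, keys=set(results), meta=meta)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_enumerate(
    formula: MolecularFormula,
    atoms: Sequence[AtomSpec],
    constraints: Sequence[PathConstraint],
    cfg: GenerationConfig | None = None,
) -> CandidateSet:
    """Naive generate-then-filter enumeration; the independent oracle.

    Assigns an order 0–3 to every atom pair with only the free-valence cap as
    pruning, then filters complete graphs for exact valence balance,
    connectivity, hybridization legality, ring size, heteroatom policy and
    path constraints.  Refuses inputs above ``cfg.oracle_limit`` heavy atoms.
    """
    cfg = cfg or GenerationConfig()
    problem = _setup(formula, atoms, constraints, cfg)
    n = len(problem.elements)
    if n > cfg.oracle_limit:
        raise OracleLimitError(
            f"{n} heavy atoms exceeds the brute-force limit of {cfg.oracle_limit}"
        )
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    results: dict[str, Constitution] = {}

    # naive H placement: plain product over silent atoms, no symmetry folding
    silent_idx = [i for i, h in enumerate(problem.fixed_h) if h is None]
    ranges = []
    for i in silent_idx:
        cap = VALENCES[problem.elements[i]] - (1 if n > 1 else 0)
        ranges.append(range(cap + 1))
    h_vectors: list[list[int]] = []
    if silent_idx:
        for combo in itertools.product(*ranges):
            if sum(combo) == problem.leftover_h:
                vec = [h or 0 for h in problem.fixed_h]
                for i, h in zip(silent_idx, combo):
                    vec[i] = h
                h_vectors.append(vec)
    else:
        if problem.leftover_h:
            raise InfeasibleError("leftover hydrogens with no silent heteroatom")
        h_vectors.append([h or 0 for h in problem.fixed_h])

    def accept(h_vec: list[int], orders: list[int]) -> None:
        sums = [0] * n
        doubles = [0] * n
        triples = [0] * n
        edges = []
        for (i, j), o in zip(pairs, orders):
            if not o:
                continue
            sums[i] += o
            sums[j] += o
            edges.append((i, j))
            if o == 2:
                doubles[i] += 1
                doubles[j] += 1
            elif o == 3:
                triples[i] += 1
                triples[j] += 1
            if (
                cfg.forbid_heteroatom_heteroatom_bonds
                and problem.elements[i] != "C"
                and problem.elements[j] != "C"
            ):
                return
        for i in range(n):
            if sums[i] + h_vec[i] != VALENCES[problem.elements[i]]:
                return
            if _hybridization_of(doubles[i], triples[i]) not in problem.allowed_hyb[i]:
                return
        if not _connected(n, edges):
            return
        if not _girth_ok(n, edges, cfg.min_ring_size):
            return
        m = _build(
            problem, h_vec,
            {pair: o for pair, o in zip(pairs, orders) if o},
        )
        m.validate()
        ok, _ = check_satisfies(m, problem.constraints)
        if not ok:
            return
        results.setdefault(m.canonical_smiles(), m)

    for h_vec in h_vectors:
        free = [VALENCES[el] - h for el, h in zip(problem.elements, h_vec)]
        if any(f < 0 for f in free):
            continue
        if n == 1:
            accept(h_vec, [])
            continue
        orders = [0] * len(pairs)
        rem = list(free)

        def rec(p: int) -> None:
            if p == len(pairs):
                accept(h_vec, orders)
                return
            i, j = pairs[p]
            for o in range(0, min(3, rem[i], rem[j]) + 1):
                orders[p] = o
                rem[i] -= o
                rem[j] -= o
                rec(p + 1)
                rem[i] += o
                rem[j] += o
            orders[p] = 0

        rec(0)

    ordered = [results[k] for k in sorted(results)]
    return CandidateSet(
        constitutions=ordered,
        keys=set(results),
        meta={"truncated": False, "oracle": True, "n_results": len(ordered)},
    )
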