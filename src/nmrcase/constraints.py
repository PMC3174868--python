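"""Compile 2D-NMR correlation lists into heavy-atom bond-path constraints.

COSY cross peaks between vicinal protons mean the two proton-bearing heavy
atoms are directly bonded; 1,1-ADEQUATE gives one-bond C–C connectivity
outright.  HMBC (to carbon or to nitrogen) is the ambiguous experiment: a
2- or 3-bond H→X correlation places the proton's heavy atom one OR two bonds
from X, and that two-valued uncertainty is carried through the search as a
:class:`PathConstraint` rather than resolved up front.  Multiple correlations
on the same atom pair intersect their allowed path-length sets; an empty
intersection is a contradiction in the input data.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence, TYPE_CHECKING

from .datamodel import AtomSpec, check_unique_ids
from .errors import ContradictionError, CorrelationError

if TYPE_CHECKING:  # pragma: no cover
    from .datamodel import Constitution

Pair = tuple[str, str]


@dataclasses.dataclass(frozen=True)
class PathConstraint:
    """Heavy atoms ``a`` and ``b`` must lie on a simple bond path whose length
    (in bonds, silent heteroatoms counting as path vertices) is one of
    ``allowed_lengths``."""

    a: str
    b: str
    allowed_lengths: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_lengths", frozenset(self.allowed_lengths))
        if self.a == self.b:
            raise CorrelationError(f"constraint pairs atom {self.a!r} with itself")
        if not self.allowed_lengths:
            raise CorrelationError(f"empty allowed lengths for ({self.a}, {self.b})")
        if not self.allowed_lengths <= {1, 2, 3}:
            raise CorrelationError(
                f"allowed lengths {sorted(self.allowed_lengths)} outside 1..3"
            )

    @property
    def pair(self) -> Pair:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclasses.dataclass(frozen=True)
class CorrelationSet:
    """Raw correlation lists, one per experiment.

    Conventions: ``cosy`` pairs two proton-bearing atoms; ``hmbc`` /
    ``n15_hmbc`` pair the correlated carbon/nitrogen with the heavy atom
    bearing the proton; ``adequate11`` pairs a carbon with a bonded
    proton-bearing carbon.
    """

    cosy: tuple[Pair, ...] = ()
    hmbc: tuple[Pair, ...] = ()
    n15_hmbc: tuple[Pair, ...] = ()
    adequate11: tuple[Pair, ...] = ()

    def __post_init__(self) -> None:
        for field in ("cosy", "hmbc", "n15_hmbc", "adequate11"):
            pairs = tuple((str(a), str(b)) for a, b in getattr(self, field))
            object.__setattr__(self, field, pairs)

    def validate(self, atoms: Sequence[AtomSpec]) -> None:
        """Cross-check every correlation endpoint against the atom records."""
        check_unique_ids(atoms)
        by_id = {a.id: a for a in atoms}

        def resolve(atom_id: str, where: str) -> AtomSpec:
            if atom_id not in by_id:
                raise CorrelationError(
                    f"{where} correlation names unknown atom id {atom_id!r}"
                )
            return by_id[atom_id]

        def require_h(spec: AtomSpec, where: str) -> None:
            if spec.n_h < 1:
                raise CorrelationError(
                    f"{where} correlation endpoint {spec.id!r} carries no protons"
                )

        for a, b in self.cosy:
            if a == b:
                raise CorrelationError(
                    f"degenerate COSY pair ({a!r}, {b!r}): geminal protons carry"
                    " no heavy-atom connectivity"
                )
            require_h(resolve(a, "COSY"), "COSY")
            require_h(resolve(b, "COSY"), "COSY")
        for c, h in self.hmbc:
            if c == h:
                raise CorrelationError(f"HMBC pair ({c!r}, {h!r}) is a self-pair")
            spec_c = resolve(c, "HMBC")
            if spec_c.element != "C":
                raise CorrelationError(f"HMBC carbon endpoint {c!r} is not a carbon")
            require_h(resolve(h, "HMBC"), "HMBC")
        for n, h in self.n15_hmbc:
            if n == h:
                raise CorrelationError(f"15N-HMBC pair ({n!r}, {h!r}) is a self-pair")
            spec_n = resolve(n, "15N-HMBC")
            if spec_n.element != "N":
                raise CorrelationError(
                    f"15N-HMBC nitrogen endpoint {n!r} is not a nitrogen"
                )
            require_h(resolve(h, "15N-HMBC"), "15N-HMBC")
        for c, c2 in self.adequate11:
            if c == c2:
                raise CorrelationError(
                    f"1,1-ADEQUATE pair ({c!r}, {c2!r}) is a self-pair"
                )
            if resolve(c, "1,1-ADEQUATE").element != "C":
                raise CorrelationError(f"1,1-ADEQUATE endpoint {c!r} is not a carbon")
            spec2 = resolve(c2, "1,1-ADEQUATE")
            if spec2.element != "C":
                raise CorrelationError(f"1,1-ADEQUATE endpoint {c2!r} is not a carbon")
            require_h(spec2, "1,1-ADEQUATE")


def compile_constraints(
    correlations: CorrelationSet,
    atoms: Sequence[AtomSpec],
    allow_4bond_hmbc: bool = False,
) -> list[PathConstraint]:
    """Translate correlations into deduplicated path constraints.

    COSY and 1,1-ADEQUATE pin the heavy-atom pair to path length {1}; HMBC
    (13C or 15N) allows {1, 2} — or {1, 2, 3} when 4-bond correlations are
    admitted.  Constraints accumulating on one unordered pair are intersected;
    an empty intersection raises :class:`ContradictionError` naming the pair.
    The result is sorted, hence independent of correlation-list order.
    """
    correlations.validate(atoms)
    hmbc_lengths = frozenset({1, 2, 3} if allow_4bond_hmbc else {1, 2})
    allowed: dict[Pair, frozenset[int]] = {}

    def merge(a: str, b: str, lengths: frozenset[int]) -> None:
        pair = (a, b) if a <= b else (b, a)
        current = allowed.get(pair, frozenset({1, 2, 3}))
        merged = current & lengths
        if not merged:
            raise ContradictionError(
                f"contradictory correlations on pair {pair}: "
                f"{sorted(current)} ∩ {sorted(lengths)} is empty"
            )
        allowed[pair] = merged

    one = frozenset({1})
    for a, b in correlations.cosy:
        merge(a, b, one)
    for c, h in correlations.hmbc:
        merge(c, h, hmbc_lengths)
    for n, h in correlations.n15_hmbc:
        merge(n, h, hmbc_lengths)
    for c, c2 in correlations.adequate11:
        merge(c, c2, one)

    return [
        PathConstraint(a=pair[0], b=pair[1], allowed_lengths=lengths)
        for pair, lengths in sorted(allowed.items())
    ]


def _path_exists(
    adj: dict[int, dict[int, int]], a: int, b: int, allowed: frozenset[int]
) -> bool:
    """True iff some simple path from a to b has a length in ``allowed``.

    Any simple path counts, not only the shortest: in a ring a pair can be
    both 1 and 2 bonds apart, and either relation explains a correlation.
    """
    longest = max(allowed)
    stack: list[tuple[int, int, frozenset[int]]] = [(a, 0, frozenset({a}))]
    while stack:
        node, depth, visited = stack.pop()
        for nb in adj[node]:
            if nb == b:
                if depth + 1 in allowed:
                    return True
                continue
            if nb not in visited and depth + 1 < longest:
                stack.append((nb, depth + 1, visited | {nb}))
    return False


def check_satisfies(
    m: "Constitution", constraints: Iterable[PathConstraint]
) -> tuple[bool, PathConstraint | None]:
    """Verify a constitution against compiled constraints.

    Returns ``(True, None)`` when every constraint is explained by some simple
    path of an allowed length, else ``(False, first_violated)``.
    """
    adj = m.adjacency()
    for constraint in constraints:
        ia = m.index_of(constraint.a)
        ib = m.index_of(constraint.b)
        if not _path_exists(adj, ia, ib, constraint.allowed_lengths):
            return False, constraint
    return True, None
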