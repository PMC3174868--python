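"""Forward model and synthetic-data generators.

The forward model inverts the elucidation problem: given a known
constitution, emit the correlation set its spectra would show (COSY between
bonded proton-bearing atoms, HMBC from protons two or three bonds out,
1,1-ADEQUATE between bonded carbons).  Feeding those correlations back
through the constraint compiler and the generator must always recover the
original structure — the round-trip property at the heart of the test suite.

``dropout`` models sparse experimental data: each correlation is omitted
independently with the given probability, reproducibly per seed.  Real
spectra additionally suffer overlap, weak peaks and mis-picked artefacts
that this model does not attempt; what it emulates is the *information
content* of a correlation list, not the spectrum itself.

The structure generators build small random connected, valence-legal
molecules (and reference corpora biased toward common functional groups) so
that every pipeline stage is testable without external downloads.
"""

from __future__ import annotations

import dataclasses
import random
from typing import Sequence

from .constraints import CorrelationSet
from .datamodel import (
    OPEN,
    VALENCES,
    Atom,
    AtomSpec,
    Constitution,
)
from .errors import InfeasibleError

EXPERIMENTS = ("COSY", "HMBC", "N15HMBC", "ADEQUATE11")


@dataclasses.dataclass
class ForwardConfig:
    """Which experiments to simulate and how sparse the data is.

    ``hmbc_lengths`` counts bonds on the H→heavy-atom path (the standard 2-
    and 3-bond correlations); the heavy-atom pair distance is one less.
    """

    experiments: tuple[str, ...] = ("COSY", "HMBC")
    hmbc_lengths: frozenset[int] = frozenset({2, 3})
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.experiments:
            raise InfeasibleError("at least one experiment must be simulated")
        for e in self.experiments:
            if e not in EXPERIMENTS:
                raise InfeasibleError(f"unknown experiment {e!r}")
        if not 0 <= self.dropout < 1:
            raise InfeasibleError("dropout must be in [0, 1)")
        object.__setattr__(self, "hmbc_lengths", frozenset(self.hmbc_lengths))


def _heavy_distances(m: Constitution) -> list[list[int]]:
    """All-pairs shortest bond-path lengths over the heavy-atom graph."""
    n = m.n_atoms
    adj = m.adjacency()
    dist = [[-1] * n for _ in range(n)]
    for start in range(n):
        dist[start][start] = 0
        queue = [start]
        while queue:
            node = queue.pop(0)
            for nb in adj[node]:
                if dist[start][nb] < 0:
                    dist[start][nb] = dist[start][node] + 1
                    queue.append(nb)
    return dist


def _require_ids(m: Constitution) -> Sequence[str]:
    if m.atom_ids is not None:
        return m.atom_ids
    return default_atom_ids(m)


def default_atom_ids(m: Constitution) -> tuple[str, ...]:
    """Stable synthetic labels: per-element running numbers (C1, C2, N1, O1...)."""
    counters: dict[str, int] = {}
    ids = []
    for el, _c, _h in m.atoms:
        counters[el] = counters.get(el, 0) + 1
        ids.append(f"{el}{counters[el]}")
    return tuple(ids)


def forward_correlations(m: Constitution, cfg: ForwardConfig | None = None) -> CorrelationSet:
    """Correlation set the given structure would show.

    Only C and N atoms are NMR-observed; O/S/halogens stay silent but count
    as path vertices for the HMBC distances.  Dropout removes each emitted
    correlation independently, seeded and reproducible.
    """
    cfg = cfg or ForwardConfig()
    ids = _require_ids(m)
    dist = _heavy_distances(m)
    observed = [
        i for i, (el, _c, _h) in enumerate(m.atoms) if el in ("C", "N")
    ]
    protonated = {i for i in observed if m.atoms[i].n_h >= 1}
    heavy_hmbc = {length - 1 for length in cfg.hmbc_lengths}

    cosy: list[tuple[str, str]] = []
    hmbc: list[tuple[str, str]] = []
    n15: list[tuple[str, str]] = []
    adequate: list[tuple[str, str]] = []

    if "COSY" in cfg.experiments:
        for i in observed:
            for j in observed:
                if i < j and dist[i][j] == 1 and i in protonated and j in protonated:
                    cosy.append((ids[i], ids[j]))
    if "HMBC" in cfg.experiments:
        for c in observed:
            if m.atoms[c].element != "C":
                continue
            for h in protonated:
                if h != c and dist[c][h] in heavy_hmbc:
                    hmbc.append((ids[c], ids[h]))
    if "N15HMBC" in cfg.experiments:
        for nn in observed:
            if m.atoms[nn].element != "N":
                continue
            for h in protonated:
                if h != nn and dist[nn][h] in heavy_hmbc:
                    n15.append((ids[nn], ids[h]))
    if "ADEQUATE11" in cfg.experiments:
        for c in observed:
            if m.atoms[c].element != "C":
                continue
            for c2 in protonated:
                if (
                    c2 != c
                    and m.atoms[c2].element == "C"
                    and dist[c][c2] == 1
                ):
                    adequate.append((ids[c], ids[c2]))

    if cfg.dropout > 0:
        rng = random.Random(cfg.seed)
        keep = lambda _pair: rng.random() >= cfg.dropout  # noqa: E731
        cosy = [p for p in cosy if keep(p)]
        hmbc = [p for p in hmbc if keep(p)]
        n15 = [p for p in n15 if keep(p)]
        adequate = [p for p in adequate if keep(p)]

    return CorrelationSet(
        cosy=tuple(cosy), hmbc=tuple(hmbc),
        n15_hmbc=tuple(n15), adequate11=tuple(adequate),
    )


def hybridization_of_atom(m: Constitution, index: int) -> str:
    """sp3/sp2/sp classification from the atom's bond orders."""
    orders = list(m.adjacency()[index].values())
    doubles = orders.count(2)
    triples = orders.count(3)
    if triples == 1 or doubles == 2:
        return "sp"
    if doubles == 1:
        return "sp2"
    return "sp3"


def structure_to_atomspecs(
    m: Constitution, open_types: bool = False
) -> list[AtomSpec]:
    """AtomSpec records for the NMR-observed (C, N) atoms of a structure.

    Fixed runs carry the true hybridization of every atom; open runs declare
    every bonding state unknown.  Chemical shifts are not simulated.
    """
    ids = _require_ids(m)
    specs = []
    for i, (el, _charge, n_h) in enumerate(m.atoms):
        if el not in ("C", "N"):
            continue
        specs.append(
            AtomSpec(
                id=ids[i],
                element=el,
                n_h=n_h,
                hybridization=OPEN if open_types else hybridization_of_atom(m, i),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Random structures and corpora
# ---------------------------------------------------------------------------

_TOY_ELEMENTS = ["C", "C", "C", "C", "O", "N"]

#: Functional groups grafted onto corpus molecules, with default weights.
#: Each entry: (free valence consumed on the host carbon, grafter).
FRAGMENT_WEIGHTS = {
    "hydroxyl": 3.0,   # -OH
    "carbonyl": 2.0,   # =O
    "amine": 2.0,      # -NH2
    "methoxy": 1.0,    # -O-CH3
    "none": 4.0,
}


def _random_structure(
    rng: random.Random,
    n_heavy: int,
    elements_pool: Sequence[str] = _TOY_ELEMENTS,
    unsaturation_bias: float = 0.5,
) -> Constitution | None:
    """One random connected valence-legal structure, or None on a dead end."""
    elements = ["C"] + [rng.choice(elements_pool) for _ in range(n_heavy - 1)]
    rng.shuffle(elements)
    free = [VALENCES[el] for el in elements]
    bonds: dict[tuple[int, int], int] = {}

    # random spanning tree
    for j in range(1, n_heavy):
        hosts = [i for i in range(j) if free[i] >= 1]
        if not hosts:
            return None
        i = rng.choice(hosts)
        bonds[(i, j)] = 1
        free[i] -= 1
        free[j] -= 1

    # sprinkle rings and multiple bonds while valence allows
    for _ in range(rng.randint(0, n_heavy)):
        if rng.random() < unsaturation_bias:
            # upgrade an existing bond
            ups = [
                p for p, o in bonds.items()
                if o < 3 and free[p[0]] >= 1 and free[p[1]] >= 1
            ]
            if ups:
                p = rng.choice(ups)
                bonds[p] += 1
                free[p[0]] -= 1
                free[p[1]] -= 1
        else:
            # close a ring with a new single bond
            news = [
                (i, j)
                for i in range(n_heavy)
                for j in range(i + 1, n_heavy)
                if (i, j) not in bonds and free[i] >= 1 and free[j] >= 1
            ]
            if news:
                p = rng.choice(news)
                bonds[p] = 1
                free[p[0]] -= 1
                free[p[1]] -= 1

    atoms = tuple(
        Atom(el, 0, h) for el, h in zip(elements, free)
    )
    m = Constitution(
        atoms=atoms,
        bonds=frozenset((i, j, o) for (i, j), o in bonds.items()),
    )
    m = Constitution(
        atoms=m.atoms, bonds=m.bonds, atom_ids=default_atom_ids(m)
    )
    try:
        m.validate()
        m.to_rdkit()  # RDKit must accept it too
    except Exception:
        return None
    return m


def make_toy_structures(
    seed: int,
    n: int,
    heavy_atom_range: tuple[int, int] = (2, 6),
    elements_pool: Sequence[str] = _TOY_ELEMENTS,
) -> list[Constitution]:
    """``n`` random valid structures, reproducible per seed.

    The size range must stay within the brute-force oracle limit so every
    fixture remains checkable by both enumeration routes.
    """
    lo, hi = heavy_atom_range
    if lo < 1 or hi < lo:
        raise InfeasibleError(f"infeasible heavy-atom range {heavy_atom_range}")
    rng = random.Random(seed)
    out: list[Constitution] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise InfeasibleError(
                f"could not build {n} structures in range {heavy_atom_range}"
            )
        m = _random_structure(rng, rng.randint(lo, hi), elements_pool)
        if m is not None:
            out.append(m)
    return out


def make_reference_corpus(
    seed: int,
    n: int,
    heavy_atom_range: tuple[int, int] = (3, 8),
    fragment_weights: dict[str, float] | None = None,
) -> list[Constitution]:
    """Random reference corpus biased toward common functional groups.

    Each molecule starts as a random skeleton; a weighted functional group
    (hydroxyl, carbonyl, amine, methoxy) is then grafted onto a carbon with
    spare valence, mimicking the composition of a database of described
    compounds at desk scale.
    """
    if n < 1:
        raise InfeasibleError("corpus size must be at least 1")
    weights = dict(FRAGMENT_WEIGHTS)
    weights.update(fragment_weights or {})
    names = sorted(weights)
    rng = random.Random(seed)
    lo, hi = heavy_atom_range
    out: list[Constitution] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 500 * n:
            raise InfeasibleError("corpus generation stalled")
        m = _random_structure(rng, rng.randint(lo, hi), unsaturation_bias=0.35)
        if m is None:
            continue
        choice = rng.choices(names, weights=[weights[k] for k in names])[0]
        grafted = _graft(m, choice, rng)
        out.append(grafted if grafted is not None else m)
    return out


def _graft(m: Constitution, group: str, rng: random.Random) -> Constitution | None:
    """Attach a functional group to a carbon with free H; None if impossible."""
    if group == "none":
        return m
    hosts = [
        i for i, (el, _c, n_h) in enumerate(m.atoms)
        if el == "C" and n_h >= (2 if group == "carbonyl" else 1)
    ]
    if not hosts:
        return None
    host = rng.choice(hosts)
    atoms = list(m.atoms)
    bonds = set(m.bonds)
    el, charge, n_h = atoms[host]

    def add(symbol: str, n_h_new: int, order: int, to: int) -> int:
        atoms.append(Atom(symbol, 0, n_h_new))
        idx = len(atoms) - 1
        bonds.add((min(to, idx), max(to, idx), order))
        return idx

    if group == "hydroxyl":
        atoms[host] = Atom(el, charge, n_h - 1)
        add("O", 1, 1, host)
    elif group == "carbonyl":
        atoms[host] = Atom(el, charge, n_h - 2)
        add("O", 0, 2, host)
    elif group == "amine":
        atoms[host] = Atom(el, charge, n_h - 1)
        add("N", 2, 1, host)
    elif group == "methoxy":
        atoms[host] = Atom(el, charge, n_h - 1)
        o = add("O", 0, 1, host)
        add("C", 3, 1, o)
    else:  # pragma: no cover - config validated upstream
        return None

    grafted = Constitution(atoms=tuple(atoms), bonds=frozenset(bonds))
    grafted = Constitution(
        atoms=grafted.atoms, bonds=grafted.bonds,
        atom_ids=default_atom_ids(grafted),
    )
    try:
        grafted.validate()
        grafted.to_rdkit()
    except Exception:
        return None
    return grafted
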