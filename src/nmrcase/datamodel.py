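"""Core chemical data model: formulas, NMR atom records, constitutions.

A *constitution* is the unit of output in computer-assisted structure
elucidation: the molecular graph (atom connectivity plus bond orders and
hydrogen counts) without stereochemistry.  The lightweight graph type defined
here is what the generator manipulates directly; RDKit supplies
canonicalisation (canonical SMILES with aromaticity perception, so that
Kekulé-equivalent forms of a ring collapse to one key) and SMILES/SDF V2000
round-tripping.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from typing import Iterable, Mapping, NamedTuple, Sequence

from rdkit import Chem, RDLogger

from .errors import ConstitutionError, FormulaError

RDLogger.DisableLog("rdApp.*")

#: Fixed valence table for neutral atoms.  Charged species shift the target
#: valence by the formal charge for N/O/S/P (e.g. N+ binds four).
VALENCES: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "S": 2,
    "P": 3,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

HYBRIDIZATIONS = ("sp3", "sp2", "sp")
#: Sentinel hybridization meaning "not supplied; enumerate all possibilities".
OPEN = "open"

_PT = Chem.GetPeriodicTable()
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _is_element(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


# ---------------------------------------------------------------------------
# Molecular formula
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MolecularFormula:
    """Element → count map, hydrogen included.

    The formula is the mass-balance constraint of the generator: heavy-atom
    counts fix the vertex set of every candidate graph and the hydrogen count
    fixes the total number of attached protons.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if not _is_element(el):
                raise FormulaError(f"unknown element symbol {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}")
            if n:
                clean[el] = int(n)
        if not any(el != "H" for el in clean):
            raise FormulaError("formula must contain at least one heavy atom")
        object.__setattr__(self, "counts", clean)

    @property
    def n_hydrogens(self) -> int:
        return self.counts.get("H", 0)

    @property
    def heavy_counts(self) -> dict[str, int]:
        return {el: n for el, n in self.counts.items() if el != "H"}

    @property
    def n_heavy(self) -> int:
        return sum(self.heavy_counts.values())

    def hill(self) -> str:
        """Hill-notation string (C first, H second, rest alphabetical)."""
        parts = []
        rest = dict(self.counts)
        for el in ("C", "H"):
            if el in rest:
                n = rest.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(rest):
            n = rest[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation molecular formula such as ``"C17H12O6"``.

    Bare element symbols carry an implicit count of one.  Isotope labels,
    charges and dots are not supported.
    """
    counts: Counter[str] = Counter()
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"cannot parse formula {text!r} at {text[pos:m.start()]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if not _is_element(symbol):
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] += int(digits) if digits else 1
        pos = m.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"cannot parse formula {text!r}")
    return MolecularFormula(dict(counts))


def dbe(formula: MolecularFormula) -> int:
    """Degree of unsaturation (rings + multiple bonds) implied by a formula.

    Computed in the general form ``1 + Σ n_i (v_i − 2) / 2`` over the fixed
    valence table, which reduces to ``C + 1 − H/2 − X/2 + N/2`` for CHNOX
    molecules.  A chemically valid neutral formula yields a non-negative
    integer; anything else is rejected.
    """
    twice = 2
    for el, n in formula.counts.items():
        if el not in VALENCES:
            raise FormulaError(f"no configured valence for element {el}")
        twice += n * (VALENCES[el] - 2)
    if twice % 2:
        raise FormulaError(f"formula {formula.hill()} inconsistent: half-integer DBE")
    value = twice // 2
    if value < 0:
        raise FormulaError(f"formula {formula.hill()} inconsistent: negative DBE")
    return value


# ---------------------------------------------------------------------------
# NMR atom records
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AtomSpec:
    """One NMR-observed heavy atom (a carbon or nitrogen resonance).

    ``n_h`` is the attached-proton count fixed by HSQC/DEPT; ``hybridization``
    is either supplied ("fixed atom types") or :data:`OPEN`, in which case the
    generator enumerates sp3/sp2/sp bonding states for the atom.
    """

    id: str
    element: str
    n_h: int
    shift_ppm: float | None = None
    hybridization: str = OPEN

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise ConstitutionError(
                f"atom {self.id}: NMR-observed atoms must be C or N, got {self.element!r}"
            )
        if not 0 <= self.n_h <= VALENCES[self.element]:
            raise ConstitutionError(
                f"atom {self.id}: n_h={self.n_h} outside 0..{VALENCES[self.element]}"
            )
        if self.hybridization not in HYBRIDIZATIONS + (OPEN,):
            raise ConstitutionError(
                f"atom {self.id}: unknown hybridization {self.hybridization!r}"
            )
        if self.shift_ppm is not None and self.shift_ppm < 0:
            raise ConstitutionError(f"atom {self.id}: negative chemical shift")


def check_unique_ids(atoms: Sequence[AtomSpec]) -> None:
    seen: set[str] = set()
    for a in atoms:
        if a.id in seen:
            raise ConstitutionError(f"duplicate atom id {a.id!r}")
        seen.add(a.id)


# ---------------------------------------------------------------------------
# Constitutions
# ---------------------------------------------------------------------------

class Atom(NamedTuple):
    element: str
    charge: int
    n_h: int


_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclasses.dataclass(frozen=True)
class Constitution:
    """A connected molecular graph with explicit bond orders and H counts.

    Bonds are stored Kekulé-style (integer orders 1–3); aromatic systems are
    kept in one Kekulé form and only merged at canonicalisation time.
    ``atom_ids`` carries the NMR labels of observed atoms (silent heteroatoms
    get synthetic labels) so path constraints can be checked against the graph.
    """

    atoms: tuple[Atom, ...]
    bonds: frozenset[tuple[int, int, int]]
    atom_ids: tuple[str, ...] | None = None
    provenance: Mapping[str, object] = dataclasses.field(
        default_factory=dict, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "atoms", tuple(Atom(*a) for a in self.atoms)
        )
        norm = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ConstitutionError("self-bond")
            a, b = (i, j) if i < j else (j, i)
            norm.add((a, b, int(order)))
        object.__setattr__(self, "bonds", frozenset(norm))
        if self.atom_ids is not None:
            object.__setattr__(self, "atom_ids", tuple(self.atom_ids))

    # -- basic graph accessors ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> dict[int, dict[int, int]]:
        """neighbor index → bond order, per atom index."""
        adj: dict[int, dict[int, int]] = {i: {} for i in range(self.n_atoms)}
        for i, j, order in self.bonds:
            adj[i][j] = order
            adj[j][i] = order
        return adj

    def index_of(self, atom_id: str) -> int:
        if self.atom_ids is None:
            raise ConstitutionError("constitution carries no atom ids")
        try:
            return self.atom_ids.index(atom_id)
        except ValueError:
            raise ConstitutionError(f"unknown atom id {atom_id!r}") from None

    def formula(self) -> MolecularFormula:
        counts: Counter[str] = Counter()
        for el, _charge, n_h in self.atoms:
            counts[el] += 1
            counts["H"] += n_h
        return MolecularFormula(dict(counts))

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConstitutionError` unless every invariant holds:
        unique bonds, orders 1–3, exact valence balance per atom, and a
        connected graph."""
        pairs = [(i, j) for i, j, _o in self.bonds]
        if len(pairs) != len(set(pairs)):
            raise ConstitutionError("duplicate bond between one atom pair")
        sums = [0] * self.n_atoms
        for i, j, order in self.bonds:
            if order not in (1, 2, 3):
                raise ConstitutionError(f"bond order {order} not in 1..3")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ConstitutionError("bond references missing atom")
            sums[i] += order
            sums[j] += order
        for idx, (el, charge, n_h) in enumerate(self.atoms):
            if el not in VALENCES:
                raise ConstitutionError(f"no configured valence for {el}")
            target = VALENCES[el]
            if charge and el in ("N", "O", "S", "P"):
                target += charge
            elif charge:
                target -= abs(charge)
            if sums[idx] + n_h != target:
                label = el if not charge else f"{el}{charge:+d}"
                raise ConstitutionError(
                    f"atom {idx} ({label}): bond orders"
                    f" {sums[idx]} + {n_h} H != valence {target}"
                )
        if not self._connected():
            raise ConstitutionError("graph is disconnected")

    def _connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_atoms

    # -- RDKit bridge ---------------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        """Sanitised RDKit molecule (aromaticity perceived)."""
        rw = Chem.RWMol()
        for el, charge, n_h in self.atoms:
            atom = Chem.Atom(el)
            atom.SetFormalCharge(charge)
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(n_h)
            rw.AddAtom(atom)
        for i, j, order in sorted(self.bonds):
            rw.AddBond(i, j, _BOND_TYPES[order])
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - defensive
            raise ConstitutionError(f"RDKit rejected constitution: {exc}") from exc
        return mol

    @classmethod
    def from_rdkit(
        cls, mol: Chem.Mol, atom_ids: Sequence[str] | None = None
    ) -> "Constitution":
        """Extract a Kekulé constitution from any sanitised RDKit molecule."""
        mol = Chem.Mol(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
        atoms = tuple(
            Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        )
        bonds = frozenset(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
            for b in mol.GetBonds()
        )
        return cls(atoms=atoms, bonds=bonds,
                   atom_ids=tuple(atom_ids) if atom_ids else None)

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


def canonical_form(m: Constitution) -> str:
    """Canonical key: identical for isomorphic constitutions (element, charge,
    H count and bond order preserved; Kekulé-equivalent aromatic forms merge),
    distinct otherwise.  Implemented as RDKit canonical SMILES."""
    return m.canonical_smiles()


def constitution_from_smiles(
    smiles: str, atom_ids: Sequence[str] | None = None
) -> Constitution:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConstitutionError(f"cannot parse SMILES {smiles!r}")
    return Constitution.from_rdkit(mol, atom_ids)


# ---------------------------------------------------------------------------
# File I/O (SMILES one-per-line; SDF V2000)
# ---------------------------------------------------------------------------

def read_smiles_file(path: str) -> tuple[list[Constitution], int]:
    """Read one SMILES per line; blank lines and ``#`` comments ignored.

    Returns the parsed constitutions and the number of unparseable lines
    skipped (logged by the CLI)."""
    out: list[Constitution] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            token = line.split()[0] if line.split() else ""
            if not token or token.startswith("#"):
                continue
            try:
                out.append(constitution_from_smiles(token))
            except ConstitutionError:
                skipped += 1
    return out, skipped


def write_smiles_file(
    path: str, constitutions: Iterable[Constitution], sort: bool = True
) -> list[str]:
    """Write canonical SMILES, one per line, lexically sorted by default so
    output files diff stably.  Returns the lines written."""
    lines = [m.canonical_smiles() for m in constitutions]
    if sort:
        lines = sorted(lines)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
    return lines


def write_sdf(path: str, constitutions: Iterable[Constitution]) -> None:
    writer = Chem.SDWriter(path)
    try:
        writer.SetKekulize(True)
        for m in constitutions:
            writer.write(m.to_rdkit())
    finally:
        writer.close()


def read_sdf(path: str) -> list[Constitution]:
    supplier = Chem.SDMolSupplier(path)
    out = []
    for mol in supplier:
        if mol is not None:
            out.append(Constitution.from_rdkit(mol))
    return out
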