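"""Radius-1 atom-environment filter against a reference corpus.

The plausibility test applied to generated candidates: every atom of a
candidate, together with its directly bonded neighbours (one sphere), is
rendered as a canonical key — center element, formal charge, total hydrogen
count and the sorted multiset of (neighbour element, bond order) pairs.  A
dictionary of such keys built from a corpus of known molecules then acts as
an existence test: a candidate survives iff every one of its environments has
been seen at least once in the corpus.  Environments that never occur in a
large corpus of described compounds correspond to substructures that are
unstable or unknown, so removing candidates that contain them shrinks the
result set without touching chemically reasonable solutions.  Aromatic bonds
get a dedicated order token, so the two Kekulé forms of a ring produce the
same keys.  No ranking of the survivors is performed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

from .datamodel import Constitution
from .errors import EmptyCorpusError
from .generator import CandidateSet

#: Token used for aromatic bonds in keys; sorts between single and double.
AROMATIC_TOKEN = "ar"
_ORDER_SORT = {"1": 1.0, AROMATIC_TOKEN: 1.5, "2": 2.0, "3": 3.0}


@dataclasses.dataclass(frozen=True)
class EnvKey:
    """Canonical one-sphere environment of an atom."""

    center: str
    charge: int
    n_h: int
    neighbors: tuple[tuple[str, str], ...]  # (element, order token), sorted

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.neighbors, key=lambda nb: (nb[0], _ORDER_SORT[nb[1]]))
        )
        object.__setattr__(self, "neighbors", ordered)

    def render(self) -> str:
        nbs = ",".join(f"{el}:{tok}" for el, tok in self.neighbors)
        return f"{self.center}[{self.charge:+d}]H{self.n_h}({nbs})"

    def __str__(self) -> str:
        return self.render()


def _bond_token(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic():
        return AROMATIC_TOKEN
    return str(int(bond.GetBondTypeAsDouble()))


def env_key(m: Constitution, atom_index: int) -> EnvKey:
    """One-sphere environment of atom ``atom_index`` (on the aromatized
    molecule, so Kekulé choice cannot split one environment into two keys)."""
    return env_keys(m)[atom_index]


def env_keys(m: Constitution) -> list[EnvKey]:
    """Environment keys for every atom of ``m``, in atom order."""
    mol = m.to_rdkit()
    keys = []
    for atom in mol.GetAtoms():
        neighbors = tuple(
            (bond.GetOtherAtom(atom).GetSymbol(), _bond_token(bond))
            for bond in atom.GetBonds()
        )
        keys.append(
            EnvKey(
                center=atom.GetSymbol(),
                charge=atom.GetFormalCharge(),
                n_h=atom.GetTotalNumHs(),
                neighbors=neighbors,
            )
        )
    return keys


# ---------------------------------------------------------------------------
# Reference dictionary
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReferenceDict:
    """EnvKey string → occurrence count over a reference corpus."""

    entries: dict[str, int]
    meta: dict[str, object] = dataclasses.field(default_factory=dict)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_count(self) -> int:
        return sum(self.entries.values())


def build_reference(
    corpus: Iterable[Constitution],
    source: str = "user corpus",
    min_count: int = 1,
) -> ReferenceDict:
    """Count every atom environment over the corpus.

    Each atom of each molecule contributes exactly one increment.  An empty
    corpus is an error: a dictionary built from nothing would silently
    eliminate every candidate downstream.  ``min_count`` > 1 drops rare
    environments after counting (stricter than the default presence test).
    """
    counts: Counter[str] = Counter()
    n_molecules = 0
    for m in corpus:
        for key in env_keys(m):
            counts[key.render()] += 1
        n_molecules += 1
    if not counts:
        raise EmptyCorpusError("reference corpus is empty after parsing")
    n_atoms = sum(counts.values())
    if min_count > 1:
        counts = Counter({k: c for k, c in counts.items() if c >= min_count})
        if not counts:
            raise EmptyCorpusError(
                f"no environment reaches min_count={min_count}"
            )
    return ReferenceDict(
        entries=dict(counts),
        meta={
            "source": source,
            "n_molecules": n_molecules,
            "n_atoms": n_atoms,
            "built": _dt.date.today().isoformat(),
        },
    )


def save_reference(ref: ReferenceDict, path: str) -> None:
    """TSV with '#' metadata comments, columns env_key / count."""
    with open(path, "w") as fh:
        for k, v in sorted(ref.meta.items()):
            fh.write(f"# {k}={v}\n")
        fh.write("env_key\tcount\n")
        for key in sorted(ref.entries):
            fh.write(f"{key}\t{ref.entries[key]}\n")


def load_reference(path: str) -> ReferenceDict:
    meta: dict[str, object] = {}
    entries: dict[str, int] = {}
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                header_seen = True  # column header line
                continue
            key, count = line.rsplit("\t", 1)
            entries[key] = int(count)
    if not entries:
        raise EmptyCorpusError(f"reference file {path} holds no entries")
    return ReferenceDict(entries=entries, meta=meta)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    """Outcome of one filtering pass."""

    kept: CandidateSet
    removed: list[tuple[Constitution, list[str]]]
    reduction: float

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)

    def to_json_dict(self) -> dict[str, object]:
        return {
            "n_input": self.n_input,
            "n_kept": len(self.kept),
            "n_removed": len(self.removed),
            "reduction": self.reduction,
            "removed": [
                {"smiles": m.canonical_smiles(), "missing_keys": missing}
                for m, missing in self.removed
            ],
        }


def filter_candidates(
    candidates: CandidateSet | Sequence[Constitution],
    ref: ReferenceDict,
) -> FilterReport:
    """Keep a candidate iff every one of its environments is in ``ref``.

    Removed entries record *all* of their unknown keys, so the report can be
    aggregated into a per-substructure account of what drove the exclusions.
    Input order is preserved in the kept set.
    """
    if isinstance(candidates, CandidateSet):
        members: Sequence[Constitution] = candidates.constitutions
        meta = dict(candidates.meta)
    else:
        members = list(candidates)
        meta = {}
    if not ref.entries:
        raise EmptyCorpusError("reference dictionary is empty")

    kept: list[Constitution] = []
    removed: list[tuple[Constitution, list[str]]] = []
    for m in members:
        missing = sorted(
            {key.render() for key in env_keys(m) if key.render() not in ref}
        )
        if missing:
            removed.append((m, missing))
        else:
            kept.append(m)
    n_input = len(members)
    reduction = len(removed) / n_input if n_input else 0.0
    kept_set = CandidateSet(
        constitutions=kept,
        keys={m.canonical_smiles() for m in kept},
        meta={**meta, "filtered": True, "n_results": len(kept)},
    )
    return FilterReport(kept=kept_set, removed=removed, reduction=reduction)


def summarize_missing(report: FilterReport) -> pd.DataFrame:
    """Table of (missing env key, number of removed candidates containing it),
    sorted by count descending then key — the per-substructure view of what
    the filter excluded."""
    counts: Counter[str] = Counter()
    for _m, missing in report.removed:
        for key in missing:
            counts[key] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["env_key", "n_candidates"])
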