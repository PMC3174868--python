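"""The JSON input dialect: schema-validated documents holding a formula,
per-atom NMR records and correlation lists.

Validation happens in two layers: a pydantic model enforces the document
schema (types, ranges, unknown keys rejected), then cross-reference checks
tie the pieces together (unique atom ids, correlation endpoints resolving to
declared atoms with protons where required, proton counts fitting inside the
formula).  A JSON-schema rendering of the model ships with the package for
external tooling.
"""

from __future__ import annotations

import json
from typing import Literal

import pydantic

from .constraints import CorrelationSet
from .datamodel import AtomSpec, MolecularFormula, parse_formula
from .errors import InputError, NmrCaseError
from .generator import GenerationConfig

_IdPair = tuple[str, str]


class AtomRecord(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    id: str
    element: Literal["C", "N"]
    n_h: int = pydantic.Field(ge=0, le=4)
    shift_ppm: float | None = pydantic.Field(default=None, ge=0)
    hybridization: Literal["sp3", "sp2", "sp", "open"] = "open"


class CorrelationLists(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    cosy: list[_IdPair] = []
    hmbc: list[_IdPair] = []
    n15hmbc: list[_IdPair] = []
    adequate11: list[_IdPair] = []


class Options(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")

    open_types: bool = False
    min_ring_size: int = pydantic.Field(default=3, ge=3)
    max_results: int = pydantic.Field(default=1_000_000, ge=1)
    forbid_heteroatom_heteroatom_bonds: bool = False
    allow_4bond_hmbc: bool = False
    seed: int = 0


class InputDocument(pydantic.BaseModel):
    """Top-level NMR input document."""

    model_config = pydantic.ConfigDict(extra="forbid")

    formula: str
    atoms: list[AtomRecord]
    correlations: CorrelationLists = CorrelationLists()
    options: Options = Options()


def _pointer(loc: tuple[object, ...]) -> str:
    return "/" + "/".join(str(part) for part in loc)


def document_from_dict(data: dict) -> InputDocument:
    try:
        return InputDocument.model_validate(data)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        raise InputError(
            f"invalid input document at {_pointer(tuple(first['loc']))}: "
            f"{first['msg']}"
        ) from exc


def to_domain(
    doc: InputDocument,
) -> tuple[MolecularFormula, list[AtomSpec], CorrelationSet, GenerationConfig]:
    """Convert a validated document into domain objects, applying every
    cross-reference check (unique ids, endpoint resolution, H budget)."""
    formula = parse_formula(doc.formula)
    try:
        atoms = [
            AtomSpec(
                id=a.id,
                element=a.element,
                n_h=a.n_h,
                shift_ppm=a.shift_ppm,
                hybridization=a.hybridization,
            )
            for a in doc.atoms
        ]
        correlations = CorrelationSet(
            cosy=tuple(tuple(p) for p in doc.correlations.cosy),
            hmbc=tuple(tuple(p) for p in doc.correlations.hmbc),
            n15_hmbc=tuple(tuple(p) for p in doc.correlations.n15hmbc),
            adequate11=tuple(tuple(p) for p in doc.correlations.adequate11),
        )
        correlations.validate(atoms)
    except NmrCaseError as exc:
        raise InputError(str(exc)) from exc
    if sum(a.n_h for a in atoms) > formula.n_hydrogens:
        raise InputError(
            "attached-proton counts exceed the hydrogen count of the formula"
        )
    cfg = GenerationConfig(
        open_types=doc.options.open_types,
        min_ring_size=doc.options.min_ring_size,
        max_results=doc.options.max_results,
        forbid_heteroatom_heteroatom_bonds=(
            doc.options.forbid_heteroatom_heteroatom_bonds
        ),
        allow_4bond_hmbc=doc.options.allow_4bond_hmbc,
        seed=doc.options.seed,
    )
    return formula, atoms, correlations, cfg


def read_input(
    path: str,
) -> tuple[MolecularFormula, list[AtomSpec], CorrelationSet, GenerationConfig]:
    """Read and fully validate an input document from disk."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError:
        raise InputError(f"input file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise InputError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise InputError(f"{path}: top level must be a JSON object")
    return to_domain(document_from_dict(data))


def write_input(path: str, doc: InputDocument) -> None:
    with open(path, "w") as fh:
        json.dump(doc.model_dump(mode="json"), fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_document(
    formula: str,
    atoms: list[AtomSpec],
    correlations: CorrelationSet,
    options: Options | None = None,
) -> InputDocument:
    """Assemble a document from domain objects (used by the simulator, so
    fixture files are byte-identical to hand-written user inputs)."""
    return InputDocument(
        formula=formula,
        atoms=[
            AtomRecord(
                id=a.id,
                element=a.element,  # type: ignore[arg-type]
                n_h=a.n_h,
                shift_ppm=a.shift_ppm,
                hybridization=a.hybridization,  # type: ignore[arg-type]
            )
            for a in atoms
        ],
        correlations=CorrelationLists(
            cosy=[list(p) for p in correlations.cosy],
            hmbc=[list(p) for p in correlations.hmbc],
            n15hmbc=[list(p) for p in correlations.n15_hmbc],
            adequate11=[list(p) for p in correlations.adequate11],
        ),
        options=options or Options(),
    )


def input_json_schema() -> dict:
    """JSON-schema rendering of the input dialect."""
    return InputDocument.model_json_schema()
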