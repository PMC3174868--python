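# nmrcase

Constraint-based generation of molecular constitutions from 2D-NMR
correlation data, with a statistical one-sphere environment filter over a
reference corpus.

## The problem

Elucidating the constitution of a new natural product from NMR data means
finding every molecular graph (atom connectivity + bond orders, no
stereochemistry) that is compatible with the molecular formula, the
attached-proton counts from HSQC/DEPT, and the through-bond correlations
from COSY, ¹³C-HMBC, ¹⁵N-HMBC and 1,1-ADEQUATE spectra.  COSY and
1,1-ADEQUATE pin the correlated heavy atoms to a direct bond; HMBC is the
difficult experiment — a 2- or 3-bond H→X cross peak places the proton's
heavy atom either one **or** two bonds from X, and the generator must keep
both readings open.  For unsaturated, proton-poor molecules the set of
compatible constitutions can run into the hundreds of thousands.

`nmrcase` addresses both halves of the problem:

1. **Generation.** An exhaustive, duplicate-free enumeration of all
   connected, valence-legal constitutions satisfying the formula, the fixed
   proton counts, fixed or open hybridizations (sp³ / sp² / sp), and the
   compiled path constraints.  A naive brute-force enumerator serves as an
   independent oracle at small sizes: both routes must produce the same
   canonical-SMILES set.

2. **Filtering.** Every atom of every candidate is reduced to its
   *one-sphere environment*: center element, charge, H count, and the sorted
   multiset of (neighbour element, bond order) pairs, with a dedicated token
   for aromatic bonds.  A dictionary of such environments built from a
   corpus of known molecules acts as an existence test — a candidate
   survives iff all of its environments have been observed at least once.
   Environments absent from a large corpus of described compounds
   correspond to substructures that are unstable or unknown, so the filter
   removes implausible candidates while a candidate whose environments are
   all covered is never removed.  No ranking of the survivors is performed.

## Worked example

Ethanol from scratch: simulate the correlation data a C₂H₆O molecule would
show, enumerate the compatible constitutions, and filter them against a
small corpus.

```bash
$ echo "CCO" > mol.smi
$ nmrcase simulate mol.smi --experiments cosy,hmbc -o in.json --seed 1
simulated: 2 atoms, 3 correlations

$ printf 'CCO\nCCC\nCCN\nCC(C)O\nOCCO\nCOC=O\nCC(N)C\n' > corpus.smi
$ nmrcase buildref corpus.smi -o ref.tsv
reference: 12 environments from 7 molecules (0 lines skipped)

$ nmrcase pipeline in.json --ref ref.tsv -o kept.smi --report report.json
generated: 1
kept: 1  removed: 0  reduction: 0.0%

$ cat kept.smi
CCO
```

The simulated document holds two carbon records (CH₃ sp³, CH₂ sp³), one
COSY pair and two HMBC pairs; the single generated constitution is ethanol —
the COSY peak forces the C–C bond and the silent oxygen takes the remaining
hydrogen.  `generated: 1` is the size of the candidate set before
filtering, `reduction` the fraction the filter removed.

The same filter, shown removing something (Python API):

```python
>>> from nmrcase import build_reference, constitution_from_smiles, filter_candidates
>>> ethanol, ether = constitution_from_smiles("CCO"), constitution_from_smiles("COC")
>>> report = filter_candidates([ethanol, ether], build_reference([ethanol]))
>>> [m.canonical_smiles() for m in report.kept.constitutions]
['CCO']
>>> report.removed[0][1]
['C[+0]H3(O:1)', 'O[+0]H0(C:1,C:1)']
```

Dimethyl ether is removed because a reference corpus consisting only of
ethanol has never seen a methyl bonded to oxygen (`C[+0]H3(O:1)`) nor an
ether oxygen (`O[+0]H0(C:1,C:1)`).

## CLI

| command    | purpose |
|------------|---------|
| `generate` | enumerate candidates from a JSON input document |
| `buildref` | build the environment dictionary from a SMILES corpus |
| `filter`   | apply a dictionary to a candidate SMILES file |
| `simulate` | forward-model an input document from a known structure |
| `pipeline` | generate then filter in one run |

Input documents are JSON (schema shipped at
`src/nmrcase/schemas/input.schema.json`): a Hill formula, per-atom records
(`id`, `element` C/N, `n_h`, optional `shift_ppm`, `hybridization` sp3/sp2/
sp/open) and correlation lists keyed `cosy`, `hmbc`, `n15hmbc`,
`adequate11`.  Candidate sets are canonical SMILES (sorted, one per line) or
SDF V2000; reference dictionaries are TSV with `#` metadata comments;
filter reports are JSON.

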