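# Methods

## Model

A *constitution* is a connected multigraph on the heavy atoms of the
molecular formula: vertices carry an element, a formal charge (0 by
default) and an implicit hydrogen count; edges carry an integer bond order
1–3.  Validity means exact valence balance at every atom (C=4, N=3, O=2,
S=2, P=3, halogens=1; a formal charge shifts the target for N/O/S/P),
connectivity, and — as a consequence of the two — agreement between the
graph's rings-plus-multiple-bonds and the degree of unsaturation of the
formula, `1 + Σ nᵢ(vᵢ − 2)/2`.

NMR data enters as two kinds of facts:

* **Proton counts** (HSQC/DEPT): each observed C/N atom has a fixed `n_h`.
  Hydrogens left over after these assignments are distributed exhaustively
  over the NMR-silent heteroatoms (O, S, halogens, and any undeclared N),
  each silent atom keeping at least one valence for bonding.
* **Path constraints**: a COSY or 1,1-ADEQUATE correlation compiles to
  "heavy atoms a and b are bonded" ({1}); a ¹³C- or ¹⁵N-HMBC correlation to
  "1 or 2 bonds apart" ({1,2}, widened to {1,2,3} by `allow_4bond_hmbc`).
  Constraints accumulating on one pair intersect; an empty intersection is
  reported as contradictory input data.

A constraint is *satisfied* when **any** simple path of an allowed length
connects the pair — not only the shortest path.  In a ring, adjacent atoms
are also two bonds apart around the back, and either relation can explain a
cross peak; requiring the shortest path would over-constrain cyclic
molecules.  This is a dialect decision (the alternative, shortest-path-only
semantics, is strictly stronger) and it is what the round-trip tests pin
down.

Hybridizations constrain the bond-order multiset at an atom: sp³ — all
single; sp² — exactly one double; sp — one triple or two cumulated doubles.
"Open" atom types (per atom, or globally via `open_types`) enumerate all
three states; silent heteroatoms are always unrestricted within their
valence (so a carbonyl oxygen is reachable without declaring it).

## Search

`enumerate_constitutions` assigns bond orders 0–3 to atom pairs in a fixed
lexicographic order, depth-first, with:

* {1}-constraints pre-placed as mandatory edges; the per-atom count of
  mandatory partners is checked against free valence *before* the search,
  so contradictory inputs fail fast;
* free-valence bounds on both endpoints of every choice;
* partial and final hybridization checks per atom as soon as all of its
  pairs are decided (an atom whose pairs are exhausted must have used its
  free valence exactly);
* connectivity, minimum ring size, and the ambiguous {1,2} constraints
  checked on each completed graph.

Duplicates are merged by RDKit canonical SMILES.  Aromatic systems are kept
in one Kekulé form during the search; canonicalisation aromatizes first, so
Kekulé-equivalent solutions collapse to one key (benzene is counted once).
The result *set* is deterministic and independent of atom input order;
files are written lexically sorted.  `max_results` (default 10⁶) truncates
with an explicit flag, never silently.

`brute_force_enumerate` is the deliberately naive oracle: enumerate every
pair-order assignment with only the valence cap as pruning, filter complete
graphs for all conditions afterwards, deduplicate canonically.  It refuses
problems above 7 heavy atoms.  Equality of the two key sets is the central
correctness check of the generator.

## Environment filter

Each atom contributes one key: `element[charge]Hn(neighbors)` with the
neighbour multiset sorted by element then bond order; aromatic bonds use the
token `ar` so the two Kekulé forms of a ring cannot split one chemical
environment into two keys.  The reference dictionary counts keys over a
user-supplied corpus; filtering keeps a candidate iff every key is present
(count ≥ 1).  This is a presence/absence test — a re-cast of "has this
one-sphere fragment ever been parameterised/observed" — not a frequency
model; `--min-count` optionally makes it stricter.  Removed candidates
record *all* their unseen keys, and `summarize_missing` aggregates them so
the user can see which substructural element drove the exclusions.

Properties that follow and are tested: monotonicity in the corpus (more
reference molecules can only keep more candidates), idempotence, safety (a
candidate whose environments are all covered is never removed), and
radius-1 locality (atoms two bonds away cannot change a key).

A known coarseness: real parameter-assignment failures in force-field
pipelines sometimes correspond to fragments larger than one sphere.  The
radius-1 recast keeps the dictionary small and the test conservative; a
multi-sphere extension would filter more aggressively but would need a far
larger corpus to stay safe.

## Synthetic data

The fixture generator emulates the *information content* of correlation
spectra, not spectra themselves.  `forward_correlations` emits, for a known
structure: COSY for bonded proton-bearing observed pairs, HMBC for
heavy-atom distances 1–2 (H-path 2–3 bonds), ¹⁵N-HMBC likewise to nitrogen,
1,1-ADEQUATE for bonded carbons with a protonated partner.  `dropout`
removes each correlation independently (default 0; seeded), modelling
sparse experimental data.  Not modelled: chemical-shift values, peak
overlap, intensity, artefacts, exchangeable-proton correlations — so
passing tests certify the combinatorial machinery under complete or
thinned correlation lists, not robustness to mis-picked real spectra.

Random structures are built as a random spanning tree over a C-biased
element multiset, with seeded ring closures and bond-order upgrades while
valence allows; leftover valence becomes hydrogens.  Reference corpora
additionally graft weighted functional groups (hydroxyl, carbonyl, amine,
methoxy) onto a carbon, approximating the composition of a database of
described compounds at desk scale.

## Problem sizes and tolerances

Tests and the acceptance script run at oracle-checkable sizes, chosen so
the whole suite completes in seconds: toy structures of 2–6 heavy atoms;
20 inputs for oracle equivalence (with 30 % correlation dropout so the sets
are non-trivial); 50 structures for round-trip completeness; 500
(structure, corpus) trials for filter safety; 100 trials for constraint
anti-monotonicity; corpora of 40–200 molecules.  All checks are exact set
relations or zero-violation counts — no numerical tolerances are involved
anywhere in the package.

## Design choices

* Neutral molecules only by default; the valence table is fixed rather than
  inferred.  Protonation-state and charged-nitrogen conventions in
  published generators vary; keeping charge behind the data model (and out
  of the default search space) makes the enumeration well-defined.
* Heteroatom–heteroatom bonds are allowed by default (peroxide and N–O
  natural products exist); it is the filter's job, not the generator's, to
  penalise rarity.  `forbid_heteroatom_heteroatom_bonds` disables them.
* Minimum ring size defaults to 3 — every chemically expressible ring is
  allowed; the statistical filter removes strained rings when the corpus
  has never seen them.
* COSY is interpreted as vicinal only; geminal pairs are rejected as input
  since they carry no heavy-atom connectivity.
* Exchangeable-proton (OH/NH to silent atoms) correlations are out of
  scope; H counts on heteroatoms are only declared when the atom is
  observed.
* JSON was chosen as the input dialect, validated by a pydantic model with
  unknown keys rejected; a JSON-schema rendering ships with the package.

## Limitations

* Exhaustive enumeration is exponential; open-type runs on proton-poor
  molecules beyond ~10–12 heavy atoms need the `max_results` cap.  The
  brute-force oracle is limited to 7 heavy atoms by design.
* No chemical-shift prediction or candidate ranking: the filter only
  removes, it never orders.
* No stereochemistry, tautomer enumeration, isotopes, or radicals.
* Filter safety is relative to the corpus: a corpus that does not cover the
  true structure's environments will remove it.  The guarantee tested is
  conditional coverage, which is why `buildref` refuses empty corpora.
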