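# Methods

This note documents the model behind the package, the concrete choices
made where the format definition was open, the synthetic-data generator's
defaults, and the known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The condensed graph of reaction

A mapped reaction is aggregated into one pseudo-molecule keyed by map
numbers. Every bond carries `(order_r, order_p)` with orders in
{0 absent, 1, 2, 3, 9 aromatic}; every atom carries dual charge, isotope
(as a mass delta against the most common isotope), radical-count and
stereo states. Roles:

* **CENTER** — incident to ≥ 1 bond with `order_r ≠ order_p`. Atoms
  present only in reactants are LEAVING even when they terminate a broken
  bond, so CENTER ⊆ both-sides atoms. Property changes alone (charge,
  stereo, isotope, radical) never create a center; a reaction whose only
  change is such a property flip has an empty center and refuses to
  encode.
* **REMAINING** — both sides, not center. Depth = multi-source BFS
  distance from the center set over the *union* (reactant ∪ product)
  adjacency.
* **LEAVING** — reactants only. Depth = BFS distance over the
  reactant-side adjacency (letter layers, A = 1). Every bond between a
  kept and a leaving atom is broken by definition, which forces its kept
  endpoint into the center; leaving fragments are therefore always rooted
  at depth A.

Bonds *internal* to the leaving group are stored unchanged
(`order_p = order_r`): the fragment departs intact, and default decoding
regenerates it as a product molecule. This is what makes the default
decode of an unbalanced code a balanced reaction, and it is why leaving
atoms carry no independent product-side property state (their reactant
state is mirrored).

Spectator removal drops agents, reactant molecules with no mapped atom in
any product, unmapped product duplicates of such reactants, and mapped
reactant/product pairs that are completely unchanged. The last rule is
needed for well-definedness: an unchanged bystander has no finite
distance to the reaction center.

## Character tables

All alphabets live in `codec_tables` and are printed by
`reactioncode tables`:

* element code: 2-digit uppercase hex of Z (Si = `0E`);
* bond orders: `0123` plus `9` for aromatic;
* bond status: `0` unchanged < `5` order change < `7` broken < `9` made;
  the atom code's first character is the maximum incident status;
* signed offsets for /c, /i, /r: letters around the pivot `H` = −1,
  `I` = +1 (so `J` = +2, `G` = −2, range ±8); the digit `0` is the
  zero/default state. For /r the characters encode the radical *count*
  per side;
* stereo digits: `4` DOWN, `6` UP (wedge directions), `1`/`2` tetrahedral
  CW/CCW, `3`/`5` cis/trans;
* atom indices: the numeric block uses base-16 over `GHIJKLMNOPQRSTUV`
  (`GG` = 0); the leaving block uses plain 2-digit hex. The two alphabets
  are deliberately disjoint so a partner reference names its block by
  itself — with a shared alphabet a reference like `0A` would be
  ambiguous between blocks. Capacity is 256 atoms per block; overflow is
  an error.

Sub-layer entries are 4 characters: a 2-digit decimal *entity* index plus
the reactant-state and product-state characters, in that order. Entities
are counted in one shared in-layer sequence: each atom, then the bonds of
its connection table, in emission order. The emitter writes sub-layers in
the fixed order /c, /s, /i, /r; the parser accepts any order.

## Canonical ordering

"Reverse sorting" is implemented as an exact optimization: within each
layer, atoms are ordered so that the serialized layer string — and, among
layer-level ties, the remainder of the code — is lexicographically
maximal over all layer-respecting orderings. This single criterion
subsumes the descending atom-code sort and the whole tie-break cascade
(previous-layer positions, bond codes, atom properties, deeper-layer
environments): anything that changes any emitted character is compared
through the string itself, and atoms that are truly symmetric may be
ordered arbitrarily without affecting the result.

The search is a depth-first enumeration with prefix pruning. All complete
serializations of one layer have the same length (the atom set and the
emitted bond set are fixed), so a partial emission that falls below the
best-known prefix can be discarded exactly. Within a connection table,
bond entries are sorted descending by their 4-character string. Layer
ties (distinct orderings, identical layer string) are carried into deeper
layers and resolved by comparing full codes, with caps (16 tie orderings
per layer, 256 complete candidates) that matter only for accidental
non-automorphic ties, which we have not observed; layers larger than 12
atoms fall back to a width-12 beam search. Tests verify exact agreement
with a brute-force enumeration of *all* orderings on every generated
instance with ≤ 8 heavy atoms, and invariance under random atom-order
permutation at corpus scale.

Because layers serialize in order and ties never differ within a layer
string, every prefix of a code is stable: dropping all layers deeper than
k and re-encoding reproduces layers 0..k byte-identically. Atom status
characters travel with parsed documents (a partially decoded CGR keeps
the status its atoms had in the full code, even when the bond that caused
it was cut away), which is what makes prefix re-encoding exact.

## Decoding

Parsing is exact: the document's serialization is byte-identical to its
input after whitespace removal, and structural errors (unterminated
layer, dangling partner index, odd sub-layer length, unknown tag, empty
reaction center) carry character positions. Decoding rebuilds the CGR
from a downward-closed layer subset (depth 2 requires 0 and 1; layer 0 is
always required), splits it into sides — reactant side: all atoms, bonds
with `order_r > 0`; product side: kept atoms plus (by default) the
leaving fragments — assigns fresh consecutive map numbers in emission
order, and fills hydrogens by RDKit's standard valence model. For
radical-bearing atoms the hydrogen count is pinned to
`default_valence − Σorders − radicals` so radical counts round-trip.
Kekulization of decoded aromatic systems is attempted for final reactions
(`kekulize_final=True`); failures are recorded per reaction in the
`kekulization_failures` property, never raised, and no attempt is made to
recover the original tautomer. Tetrahedral parities and bond directions
are carried as descriptors; since the format stores no neighbor ordering,
they are representational rather than geometrically resolved, and
constitution-level tests treat them as annotations.

## Transform language

A compiled pattern is the reactant-side projection of the selected layers
(element, formal charge, reactant bond order, aromatic flag) plus the
instruction list of bond and property changes. Matching is plain subgraph
monomorphism (VF2); aromatic pattern bonds match only aromatic target
bonds; no synthetic-accessibility knowledge is applied. Each embedding is
edited on a copy; atoms whose environment changed get their hydrogen
count recomputed by the standard valence model (mapped SMILES input pins
every hydrogen, and an edited atom must be free to re-equilibrate);
embeddings producing valence-invalid molecules are discarded; results are
deduplicated by the canonical SMILES multiset of their products.
Stereo instructions are carried but matching is constitution-only.

## Rebalancing

`encode_and_rebalance` encodes an unbalanced reaction (the *non-final*
code), re-homes its leaving fragments as products with any deduced made
bonds applied, and re-encodes; the returned code is *final* — its own
decode/re-encode cycle reproduces it byte-identically, because no leaving
block remains. The missing-bond deduction is deliberately narrow: a bond
(`0→1`) between a depth-A leaving atom and a center atom of status `7` is
proposed only when both are carbon ("non-heteroatom" is read as carbon,
so only C–C bonds are ever deduced) and neither is detected — by map
number — in the originally given products. A CGR built from a reaction
always has its kept atoms in the products, so on such input the deduction
is conservative; lone single-atom product fragments of broken bonds
([Cl:3]-style) are additionally flagged as already-correct and excluded,
and are never merged into another leaving fragment. The flags annotate
the in-memory document only and are never serialized.

## Validation harness and fingerprints

Round-trip similarity uses RDKit Morgan fingerprints of radius 3
(ECFP6-equivalent), as identifier *sets*, with containment per side:
original ⊆ decoded. Because the format stores neither hydrogen counts
nor a Kekulé choice, each protocol normalizes **both** the original and
the decoded reaction identically before fingerprinting:

1. aromaticity stripped on both ends (aromatic bonds single, flags
   cleared, aromatic atoms' hydrogen counts pinned to 0; decoding leaves
   aromatic systems unkekulized so the same atoms are identified);
   no product correction;
2. molecules kekulized on both ends; no correction — the protocol that
   surfaces kekulization/tautomer flips;
3. protocol 1 plus product correction.

A property of this implementation worth stating: the CGR stores both bond
states per map key, so each side reconstructs *its own* graph exactly and
an element-consistent but wrong atom-atom mapping is transported
faithfully (the suite asserts this). Round-trip dissimilarity therefore
signals mappings corrupt enough to refuse encoding (element-inconsistent
pairs; tallied as errors *and* non-identical), kekulization failures, or
tautomer flips — counted automatically as non-similar pairs whose
bond-order-flattened skeletons still agree.

## Synthetic-data generator

Fixtures are grown CGR-first so ground truth (roles, depths, leaving
atoms, spectators, planted defects) is exact by construction; depths are
cross-checked against a NetworkX shortest-path oracle. Defaults emulate a
small organic transformation: 3 center atoms, 2 remaining shells of 1–2
atoms, elements drawn C-heavy from {C, N, O, S, P, Si}, single bonds with
occasional order changes, leaving fragments rooted at the center by one
broken bond, optional N⁺/O⁻ charges, ±1–2 isotope deltas, single
radicals, wedge directions, one benzene ring, and unmapped solvent-like
spectators. Valence feasibility is enforced on both sides so every
fixture sanitizes; infeasible requests retry deterministically and then
fail loudly. All randomness flows from the seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real corpora: noisy or partial atom-atom mappings,
exotic valences and organometallics, multi-center reactions, stereo
chemistry with resolved geometry, tautomer-rich aromatic systems, and the
heavy-tailed reaction-type distribution of patent data. The acceptance
script's corpus-scale numbers (round-trip similarity, diversity
statistics) characterize the implementation under these controlled
conditions, not any external dataset; problem sizes (1,000 round trips,
200 × 20 permutations, 500 transform closures, 300 reactions per
protocol) were chosen as comfortable corpus-scale demonstrations.

## Numerical/representational choices

* Stoichiometry brackets `[k]` round-trip through the string and the
  pseudo-molecule record; reaction-level duplication semantics beyond
  `k = 1` are carried but inert, since map numbers are unique per side.
* Numeric depths ≥ 10 use multi-digit decimal ids; leaving depths beyond
  Z continue AA, AB, …
* Sub-layer entity indices are 2-digit decimal; more than 100 entities in
  one layer is an encoding error.
* MDL support is V2000 only; V3000 input is rejected with a clear error.
  RXN output drops agents (the format has no agent block).
* The pseudo-molecule SD record stores the dual bond states, roles,
  depths and dual atom states in `RC_ATOMS`/`RC_BONDS` property fields;
  the connection table carries reactant orders (made bonds written
  single) for viewer compatibility. Re-import is lossless.

## Known limitations

* Canonicality relies on the tie caps described above; pathological
  graphs with huge numbers of accidental (non-automorphic) ties could in
  principle evade the exact search. None arise in the tested families.
* Stereo descriptors round-trip as annotations; wedge directions on
  bonds far from double bonds are not geometrically meaningful and are
  dropped by SMILES writers.
* Aromatic encoding deliberately loses the Kekulé choice; decoded
  tautomers can differ from the input (protocol 2 measures this).
* The transform engine enumerates embeddings up to a cap (5,000) and is
  intended for desk-scale substrates, not exhaustive library enumeration.
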