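# reactioncode

A Python implementation of **ReactionCode**: a canonical, multi-layer,
machine-readable string format for chemical reactions, built on the
condensed graph of reaction (CGR). It is aimed at cheminformaticians who
need reactions as *strings that can be compared, sliced, searched and
inverted*: round-trippable encoding for database normalization and
mapping QC, layer prefixes for reaction-type classification and corpus
diversity analysis, and partial codes as a reaction transform language.

## The format in brief

An atom-mapped reaction `R → P` is superimposed into a single
pseudo-molecule: every atom appears once, and every bond carries a pair of
orders `(b_r, b_p)` — its order on the reactant side and on the product
side. Atoms are partitioned into three blocks:

* **reaction center** (depth 0): atoms incident to at least one bond with
  `b_r ≠ b_p` (made `0→k`, broken `k→0`, or order-changed). Changes of
  charge, stereo, isotope or radical state alone do *not* create a center;
* **remaining group**: atoms present on both sides, layered by their BFS
  distance `d = 1, 2, …` from the center over the union graph;
* **leaving group**: atoms present in reactants only, layered by their
  reactant-side BFS distance and labelled `A, B, …` (`A` = depth 1).

Each layer serializes as `<id>:` + atom entries + optional sub-layers
(`/c` charges, `/s` stereo, `/i` isotopes, `/r` radicals) + `|`. An atom
entry is a 3-character atom code — the highest incident bond status
(`0` unchanged < `5` order change < `7` broken < `9` made) plus the
2-digit hex atomic number — followed by a parenthesized connection table
of 4-character bond entries (`b_r` char, `b_p` char, 2-character partner
index). Within each layer atoms are *reverse-ranked*: the emitted string
is the lexicographic maximum over every layer-respecting ordering, which
makes the whole code canonical — independent of input atom order. Because
each layer depends only on shallower layers, prefixes of a code are valid
codes: layer 0 alone *is* the reaction type.

Hydrogens are implicit and never stored; aromatic bonds are encoded with
their aromatic state (`9`) rather than a Kekulé assignment, so two
kekulizations of the same reaction share one code.

## Worked example

Chlorosilane hydrolysis, mapped but with the HCl by-product missing:

```python
>>> import reactioncode as rc
>>> r = rc.read_reaction(
...     "[CH3:2][SiH:1]([CH3:3])[Cl:4].[OH2:5]"
...     ">>[CH3:2][SiH:1]([CH3:3])[OH:5]")
>>> rc.encode_reaction(r)
'0:90E()908(01GG)|1:006(11GG)006(11GG)|A:711(10GG)|'
```

Reading the code: layer `0:` holds the center — `90E` is the silicon
(status `9`: its highest incident bond is a *made* bond; `0E` = element
14) and `908` the incoming oxygen, whose table `01GG` records the made
(`0→1`) bond to atom `GG` (the first emitted atom, the Si). Layer `1:`
holds the two unchanged methyl carbons (`006`), each bonded `11` to `GG`.
Layer `A:` is the leaving chlorine `711` (status `7`, element 0x11 = 17),
its table `10GG` recording the broken bond to the Si. Decoding is
bidirectional and layer-selective:

```python
>>> rc.decode_code(code).to_smiles()            # balanced by default
'[SiH:1]([CH3:3])([CH3:4])[Cl:5].[OH2:2]>>[SiH:1]([OH:2])([CH3:3])[CH3:4].[ClH:5]'
>>> rc.decode_code(code, rc.DecodeOptions(include_leaving=False)).to_smiles()
'[SiH:1]([CH3:3])([CH3:4])[Cl:5].[OH2:2]>>[SiH:1]([OH:2])([CH3:3])[CH3:4]'
>>> rc.decode_code(code, rc.DecodeOptions(layers={"0"})).to_smiles()
'[SiH4:1].[OH2:2]>>[SiH3:1][OH:2]'
```

The same code acts as a transform on new substrates:

```python
>>> outs = rc.apply_code(code, "CC(C)[SiH](C)Cl.O")
>>> outs[0].to_smiles()
'[CH3:1][CH:2]([CH3:3])[SiH:4]([CH3:5])[Cl:6].[OH2:7]>>[CH3:1][CH:2]([CH3:3])[SiH:4]([CH3:5])[OH:7].[ClH:6]'
```

A `reactioncode` console script exposes the same operations
(`encode`, `decode`, `transform`, `analyze`, `validate`, `tables` — the
last prints the full character tables for auditing).

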