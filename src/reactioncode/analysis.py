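"""Corpus analysis and round-trip validation.

Diversity analysis slices every code into incremental layer prefixes (the
numeric block only: a depth-``d`` prefix is the reaction center plus the
remaining shells up to depth ``d``) and counts common occurrences,
producing one frequency table per depth 0..9 -- the depth-0 table counts
reaction *types*, i.e. distinct reaction centers.

Round-trip validation encodes, decodes and compares reactions with circular
substructure fingerprints of radius 3 (ECFP6-equivalent).  A decoded
reaction is *similar* when every fingerprint identifier of the original
reaction is contained in those of the decoded one, side by side.

Three validation protocols are provided.  Each one normalizes *both* the
original and the decoded reaction the same way before fingerprinting,
because the format stores neither hydrogen counts nor a Kekulé assignment:

1. aromaticity stripped on both ends (aromatic bonds single, flags
   cleared, aromatic atoms' implicit hydrogens set to 0; decoding leaves
   aromatic systems unkekulized so the same atoms are identified), no
   product correction;
2. molecules kekulized on both ends, no product correction -- this is the
   protocol that surfaces tautomer/kekulization flips;
3. as (1) plus product correction.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .decoder import DecodeOptions, decode, parse
from .encoder import encode_reaction
from .errors import ReactionCodeError
from .reaction_io import MappedReaction, remove_spectators


# ---------------------------------------------------------------------------
# layer-prefix diversity


@dataclass
class DiversityResult:
    tables: dict[int, pd.DataFrame]
    skipped: int = 0

    def coverage(self, depth: int = 0) -> pd.Series:
        """Cumulative reaction counts down the (sorted) depth table."""
        return self.tables[depth]["occurrences"].cumsum()


def layer_prefix(code_or_doc, depth: int) -> str:
    """Numeric-block prefix of a code: layers 0..``depth`` concatenated.

    Codes with fewer than ``depth + 1`` numeric layers contribute their
    whole numeric block.
    """
    doc = parse(code_or_doc) if isinstance(code_or_doc, str) else code_or_doc
    from .decoder import ReactionCodeDoc  # local to avoid shadowing
    numeric = [l for l in doc.layers if l.block == "main"]
    return ReactionCodeDoc(numeric[:depth + 1]).serialize()


def diversity_tables(codes, max_depth: int = 9,
                     out_dir=None) -> DiversityResult:
    """Per-depth prefix frequency tables of a code corpus.

    Tables are sorted by descending occurrence count (ties by code, for
    determinism).  With ``out_dir`` the tables are also written as
    ``d0.csv`` .. ``d<max_depth>.csv``, two columns with a header row.
    """
    counters: list[dict[str, int]] = [dict() for _ in range(max_depth + 1)]
    skipped = 0
    for code in codes:
        try:
            doc = parse(code)
        except ReactionCodeError:
            skipped += 1
            continue
        numeric = [l for l in doc.layers if l.block == "main"]
        from .decoder import ReactionCodeDoc
        parts = [ReactionCodeDoc([l]).serialize() for l in numeric]
        prefix = ""
        for d in range(max_depth + 1):
            if d < len(parts):
                prefix += parts[d]
            table = counters[d]
            table[prefix] = table.get(prefix, 0) + 1
    tables = {}
    for d, table in enumerate(counters):
        df = pd.DataFrame(
            sorted(table.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["partial_reaction_code", "occurrences"])
        tables[d] = df
        if out_dir is not None:
            out = pathlib.Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            df.to_csv(out / f"d{d}.csv", index=False)
    return DiversityResult(tables, skipped)


# ---------------------------------------------------------------------------
# fingerprint round-trip


_FP_RADIUS = 3
_GEN_CACHE: dict[int, object] = {}


def _morgan_gen(radius: int):
    if radius not in _GEN_CACHE:
        _GEN_CACHE[radius] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius)
    return _GEN_CACHE[radius]


def _mol_fingerprint_ids(mol: Chem.Mol, radius: int) -> set[int]:
    mol = Chem.Mol(mol)
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    fp = _morgan_gen(radius).GetSparseCountFingerprint(mol)
    return set(fp.GetNonzeroElements())


def _side_ids(mols, radius: int) -> set[int]:
    ids: set[int] = set()
    for mol in mols:
        ids |= _mol_fingerprint_ids(mol, radius)
    return ids


def roundtrip_similar(original: MappedReaction, decoded: MappedReaction,
                      radius: int = _FP_RADIUS) -> bool:
    """True iff the original's fingerprints are contained in the decoded's.

    Containment (not equality) per side: a decoded reaction carrying an
    extra rebalanced product is still similar; one missing a ring is not.
    Any fingerprinting failure yields False.
    """
    try:
        return (_side_ids(original.reactants, radius)
                <= _side_ids(decoded.reactants, radius)
                and _side_ids(original.products, radius)
                <= _side_ids(decoded.products, radius))
    except Exception:
        return False


# ---------------------------------------------------------------------------
# validation protocols


def strip_aromaticity(mol: Chem.Mol) -> Chem.Mol:
    """Protocol-1 normalization: de-aromatize without kekulizing.

    Aromatic bonds become single, aromatic flags are cleared and the
    implicit hydrogen count of every aromatic atom is pinned to 0.
    """
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(0)
            atom.SetIsAromatic(False)
    for bond in mol.GetBonds():
        if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
            bond.SetBondType(Chem.BondType.SINGLE)
            bond.SetIsAromatic(False)
    mol.UpdatePropertyCache(strict=False)
    return mol


def _transform_reaction(r: MappedReaction, fn) -> MappedReaction:
    return MappedReaction([fn(m) for m in r.reactants], [],
                          [fn(m) for m in r.products], dict(r.properties))


def _kekulize(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def _skeleton_key(r: MappedReaction) -> tuple:
    """Bond-order-blind signature used to spot tautomer-type mismatches."""
    def key(mols):
        out = []
        for mol in mols:
            m = Chem.RWMol(mol)
            for atom in m.GetAtoms():
                atom.SetAtomMapNum(0)
                atom.SetNoImplicit(True)
                atom.SetNumExplicitHs(0)
                atom.SetIsAromatic(False)
                atom.SetNumRadicalElectrons(0)
            for bond in m.GetBonds():
                bond.SetBondType(Chem.BondType.SINGLE)
                bond.SetIsAromatic(False)
            mm = m.GetMol()
            mm.UpdatePropertyCache(strict=False)
            out.append(Chem.MolToSmiles(mm))
        return tuple(sorted(out))
    return key(r.reactants), key(r.products)


def run_validation(reactions, protocol: int = 1) -> dict[str, int]:
    """Encode/decode every reaction and tally the round-trip outcome.

    Per-reaction failures (e.g. a corrupt atom-atom mapping that refuses to
    encode) never abort the stream: they are tallied in ``errors`` *and*
    count as non-identical -- a reaction that cannot round-trip is not
    recovered.  Always: ``similar + non_identical = total``.
    """
    if protocol not in (1, 2, 3):
        raise ValueError("protocol must be 1, 2 or 3")
    counts = {"total": 0, "similar": 0, "non_identical": 0,
              "kekulization_failures": 0, "tautomer_mismatches": 0,
              "errors": 0}
    def _try(fn, m):
        try:
            return fn(m)
        except Exception:
            return m

    for r in reactions:
        try:
            ref = remove_spectators(r)
            if protocol == 2:
                ref = _transform_reaction(ref, _kekulize)
            code = encode_reaction(ref, strip_spectators=False)
            dec = decode(parse(code), DecodeOptions(
                correct_products=(protocol == 3),
                kekulize_final=(protocol == 2)))
            counts["kekulization_failures"] += int(
                dec.properties.get("kekulization_failures", "0")) > 0
            if protocol in (1, 3):
                norm = strip_aromaticity
            else:
                norm = _kekulize
            ref_n = _transform_reaction(ref, lambda m: _try(norm, m))
            dec_n = _transform_reaction(dec, lambda m: _try(norm, m))
            counts["total"] += 1
            if roundtrip_similar(ref_n, dec_n):
                counts["similar"] += 1
            else:
                counts["non_identical"] += 1
                if _skeleton_key(ref_n) == _skeleton_key(dec_n):
                    counts["tautomer_mismatches"] += 1
        except ReactionCodeError:
            counts["errors"] += 1
            counts["total"] += 1
            counts["non_identical"] += 1
    return counts
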