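"""Mapped-reaction input/output in the common interchange formats.

Reactions travel as :class:`MappedReaction`: plain lists of RDKit molecules
for the reactant, agent and product sides, with atom-atom map numbers kept
verbatim on the atoms.  Supported formats are reaction SMILES / SMIRKS
(concrete molecules, the middle component read as agents), MDL RXN V2000 and
MDL RDF; V3000 connection tables are rejected with a clear error.

Reading an incompletely mapped reaction is legal; completeness of the
mapping is only enforced later, when a reaction is encoded.
"""

from __future__ import annotations

import pathlib
import re
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdChemReactions
from rdkit import RDLogger

from .errors import MappingError, ParseError

RDLogger.DisableLog("rdApp.*")

FORMATS = ("reaction-smiles", "smirks", "rxn", "rdf")


@dataclass
class MappedReaction:
    """A reaction with per-atom map numbers.

    Invariants (checked by :meth:`validate`):

    * a map number > 0 appears at most once among reactant atoms and at most
      once among product atoms;
    * every mapped product atom has an element-identical reactant partner.
    """

    reactants: list[Chem.Mol] = field(default_factory=list)
    agents: list[Chem.Mol] = field(default_factory=list)
    products: list[Chem.Mol] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)

    # -- helpers -----------------------------------------------------------

    def copy(self) -> "MappedReaction":
        return MappedReaction(
            [Chem.Mol(m) for m in self.reactants],
            [Chem.Mol(m) for m in self.agents],
            [Chem.Mol(m) for m in self.products],
            dict(self.properties),
        )

    def side_maps(self, side: str) -> dict[int, Chem.Atom]:
        """Map number -> atom over one side ('reactants' or 'products')."""
        out: dict[int, Chem.Atom] = {}
        for mol in getattr(self, side):
            for atom in mol.GetAtoms():
                n = atom.GetAtomMapNum()
                if n > 0:
                    if n in out:
                        raise MappingError(
                            f"map number {n} duplicated among {side}")
                    out[n] = atom
        return out

    def validate(self) -> None:
        rmaps = self.side_maps("reactants")
        pmaps = self.side_maps("products")
        for n, patom in pmaps.items():
            ratom = rmaps.get(n)
            if ratom is None:
                raise MappingError(
                    f"product atom with map {n} has no reactant partner")
            if ratom.GetAtomicNum() != patom.GetAtomicNum():
                raise MappingError(
                    f"map {n} links {ratom.GetSymbol()} to {patom.GetSymbol()}")

    def to_smiles(self) -> str:
        return write_reaction(self, "reaction-smiles")


# ---------------------------------------------------------------------------
# reading


def _mol_from_smiles(fragment: str, component: str) -> list[Chem.Mol]:
    mols = []
    for piece in fragment.split("."):
        piece = piece.strip()
        if not piece:
            continue
        mol = Chem.MolFromSmiles(piece)
        if mol is None:
            raise ParseError(
                f"unparseable {component} SMILES component {piece!r}")
        mols.append(mol)
    return mols


def _reaction_from_smiles(text: str) -> MappedReaction:
    parts = text.strip().split(">")
    if len(parts) != 3:
        raise ParseError(
            "a reaction SMILES needs exactly two '>' separators",
            pos=text.find(">") if ">" in text else 0)
    r, a, p = parts
    return MappedReaction(
        _mol_from_smiles(r, "reactant"),
        _mol_from_smiles(a, "agent"),
        _mol_from_smiles(p, "product"),
    )


def _sanitized_copies(templates) -> list[Chem.Mol]:
    out = []
    for t in templates:
        mol = Chem.Mol(t)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - surfaced as ParseError
            raise ParseError(f"RXN molecule failed sanitization: {exc}")
        out.append(mol)
    return out


def _reaction_from_rxn(block: str) -> MappedReaction:
    if "V3000" in block:
        raise ParseError("MDL V3000 connection tables are not supported; "
                         "only V2000 RXN/RDF files are read")
    rxn = rdChemReactions.ReactionFromRxnBlock(block)
    if rxn is None:
        raise ParseError("unparseable RXN block", line=1)
    return MappedReaction(
        _sanitized_copies(rxn.GetReactants()),
        _sanitized_copies(rxn.GetAgents()),
        _sanitized_copies(rxn.GetProducts()),
    )


def _iter_rdf_records(text: str):
    """Yield (rxn_block, properties) records of an MDL RDF file."""
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n and not lines[i].startswith("$RFMT"):
        i += 1
    while i < n:
        # skip the $RFMT (+ optional $RIREG/$REREG) line
        i += 1
        start = i
        while i < n and not lines[i].startswith(("$RFMT", "$DTYPE")):
            i += 1
        block = "\n".join(lines[start:i]) + "\n"
        props: dict[str, str] = {}
        while i < n and lines[i].startswith("$DTYPE"):
            key = lines[i][6:].strip()
            i += 1
            val = ""
            if i < n and lines[i].startswith("$DATUM"):
                val = lines[i][6:].strip()
                i += 1
            props[key] = val
        yield block, props
        while i < n and not lines[i].startswith("$RFMT"):
            i += 1


def read_reaction(source, fmt: str = "reaction-smiles") -> MappedReaction:
    """Read one mapped reaction.

    ``source`` is the text itself or a path; ``fmt`` is one of
    ``reaction-smiles``, ``smirks``, ``rxn`` or ``rdf`` (for ``rdf`` the
    first record is returned; use :func:`read_reactions` for the stream).
    """
    text = _as_text(source)
    if fmt in ("reaction-smiles", "smirks"):
        return _reaction_from_smiles(text.strip().splitlines()[0])
    if fmt == "rxn":
        return _reaction_from_rxn(text)
    if fmt == "rdf":
        for rxn in read_reactions(text, "rdf"):
            return rxn
        raise ParseError("RDF file contains no $RFMT record", line=1)
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def read_reactions(source, fmt: str = "reaction-smiles"):
    """Iterate over the reactions of a multi-record source.

    Reaction-SMILES/SMIRKS sources hold one reaction per non-empty line;
    RDF sources one per ``$RFMT`` record ($DTYPE/$DATUM data is attached to
    ``MappedReaction.properties``).
    """
    text = _as_text(source)
    if fmt in ("reaction-smiles", "smirks"):
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                yield _reaction_from_smiles(line)
    elif fmt == "rxn":
        yield _reaction_from_rxn(text)
    elif fmt == "rdf":
        for block, props in _iter_rdf_records(text):
            rxn = _reaction_from_rxn(block)
            rxn.properties.update(props)
            yield rxn
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def _as_text(source) -> str:
    if isinstance(source, pathlib.Path):
        return source.read_text()
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    # treat short single-line strings that name an existing file as paths
    if "\n" not in text and len(text) < 4096:
        p = pathlib.Path(text)
        try:
            if p.is_file():
                return p.read_text()
        except OSError:
            pass
    return text


# ---------------------------------------------------------------------------
# writing


def _side_smiles(mols) -> str:
    return ".".join(Chem.MolToSmiles(m) for m in mols)


def _to_rdkit_reaction(r: MappedReaction) -> rdChemReactions.ChemicalReaction:
    rxn = rdChemReactions.ChemicalReaction()
    for m in r.reactants:
        rxn.AddReactantTemplate(m)
    for m in r.products:
        rxn.AddProductTemplate(m)
    return rxn


def write_reaction(r: MappedReaction, fmt: str = "reaction-smiles") -> str:
    """Serialize a reaction; the output is re-readable by :func:`read_reaction`.

    RXN V2000 has no agent block, so agents are dropped in ``rxn``/``rdf``
    output.
    """
    if fmt in ("reaction-smiles", "smirks"):
        return ">".join([_side_smiles(r.reactants), _side_smiles(r.agents),
                         _side_smiles(r.products)])
    if fmt == "rxn":
        return rdChemReactions.ReactionToRxnBlock(_to_rdkit_reaction(r))
    if fmt == "rdf":
        return write_reactions([r], "rdf")
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def write_reactions(reactions, fmt: str = "reaction-smiles") -> str:
    if fmt in ("reaction-smiles", "smirks"):
        return "\n".join(write_reaction(r, fmt) for r in reactions) + "\n"
    if fmt == "rxn":
        reactions = list(reactions)
        if len(reactions) != 1:
            raise ValueError("RXN holds exactly one reaction; use rdf")
        return write_reaction(reactions[0], "rxn")
    if fmt == "rdf":
        out = ["$RDFILE 1"]
        for r in reactions:
            out.append("$RFMT")
            out.append(write_reaction(r, "rxn").rstrip("\n"))
            for key, val in r.properties.items():
                out.append(f"$DTYPE {key}")
                out.append(f"$DATUM {val}")
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# spectator removal


def _mol_key(mol: Chem.Mol) -> str:
    stripped = Chem.Mol(mol)
    for atom in stripped.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(stripped)


def _state_signature(mol: Chem.Mol):
    """Map-keyed atom states and bonds, for unchanged-pair detection."""
    atoms = {}
    for a in mol.GetAtoms():
        atoms[a.GetAtomMapNum()] = (a.GetAtomicNum(), a.GetFormalCharge(),
                                    a.GetIsotope(), a.GetNumRadicalElectrons())
    bonds = set()
    for b in mol.GetBonds():
        i = b.GetBeginAtom().GetAtomMapNum()
        j = b.GetEndAtom().GetAtomMapNum()
        bonds.add((frozenset((i, j)), b.GetBondTypeAsDouble(),
                   b.GetIsAromatic()))
    return atoms, bonds


def remove_spectators(r: MappedReaction) -> MappedReaction:
    """Drop molecules that do not contribute to the transformation.

    Removed are: all agents; reactant molecules none of whose map numbers
    occur in any product (this covers unmapped solvents and vanishing mapped
    bystanders alike); unmapped product molecules that are exact duplicates
    of a removed/unmapped reactant; and fully mapped reactant/product pairs
    whose mapped states and bonds are completely unchanged.  Idempotent.
    """
    product_maps = set()
    for mol in r.products:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum() > 0:
                product_maps.add(atom.GetAtomMapNum())

    kept_reactants, dropped_keys = [], []
    for mol in r.reactants:
        maps = {a.GetAtomMapNum() for a in mol.GetAtoms()} - {0}
        if maps & product_maps:
            kept_reactants.append(Chem.Mol(mol))
        else:
            dropped_keys.append(_mol_key(mol))

    kept_products = []
    for mol in r.products:
        maps = {a.GetAtomMapNum() for a in mol.GetAtoms()} - {0}
        if not maps and _mol_key(mol) in dropped_keys:
            dropped_keys.remove(_mol_key(mol))
            continue
        kept_products.append(Chem.Mol(mol))

    # unchanged mapped reactant/product pairs
    psigs = {}
    for idx, mol in enumerate(kept_products):
        maps = frozenset(a.GetAtomMapNum() for a in mol.GetAtoms())
        if 0 not in maps:
            psigs.setdefault(maps, []).append(idx)
    drop_r, drop_p = set(), set()
    for ridx, mol in enumerate(kept_reactants):
        maps = frozenset(a.GetAtomMapNum() for a in mol.GetAtoms())
        if 0 in maps:
            continue
        for pidx in psigs.get(maps, []):
            if pidx in drop_p:
                continue
            if _state_signature(mol) == _state_signature(kept_products[pidx]):
                drop_r.add(ridx)
                drop_p.add(pidx)
                break
    kept_reactants = [m for i, m in enumerate(kept_reactants) if i not in drop_r]
    kept_products = [m for i, m in enumerate(kept_products) if i not in drop_p]

    return MappedReaction(kept_reactants, [], kept_products,
                          dict(r.properties))
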