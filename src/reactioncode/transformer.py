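"""ReactionCode as a transform language.

A complete or partial (downward-closed, center-including) set of layers is
compiled into a :class:`ReactionPattern`: the reactant-side projection of
the selected CGR slice is the query graph, and the differences between the
two bond/atom states are the instruction list.  Application is strict
subgraph matching -- element, formal charge, reactant bond order and
aromatic flag -- with no notion of synthetic accessibility; every embedding
yields a candidate product set, embeddings whose edited molecules violate
valence rules are discarded, and the surviving reactions are deduplicated
by canonical product identity.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

from .cgr import CGR, _BOND_TYPES, _PT
from .codec_tables import AROMATIC_ORDER
from .decoder import ReactionCodeDoc, _check_downward_closed, doc_to_cgr, parse
from .errors import ReactionCodeError
from .reaction_io import MappedReaction

_MAX_EMBEDDINGS = 5000


@dataclass
class ReactionPattern:
    cgr: CGR                       # selected-layer slice, reactant projection
    query: nx.Graph = field(repr=False, default=None)
    instructions: list = field(default_factory=list)

    def __post_init__(self):
        if self.query is None:
            self.query = _query_graph(self.cgr)
        if not self.instructions:
            self.instructions = _instructions(self.cgr)


def _query_graph(cgr: CGR) -> nx.Graph:
    g = nx.Graph()
    aromatic = {i for b in cgr.bonds if b.order_r == AROMATIC_ORDER
                for i in (b.i, b.j)}
    for i, a in enumerate(cgr.atoms):
        g.add_node(i, element=a.element, charge=a.charge_r,
                   aromatic=i in aromatic)
    for b in cgr.bonds:
        if b.order_r > 0:
            g.add_edge(b.i, b.j, order=b.order_r)
    return g


def _instructions(cgr: CGR) -> list:
    ops = []
    for b in cgr.bonds:
        if b.order_r != b.order_p:
            ops.append(("bond", b.i, b.j, b.order_r, b.order_p))
    for i, a in enumerate(cgr.atoms):
        if a.charge_r != a.charge_p:
            ops.append(("charge", i, a.charge_p))
        if a.radical_r != a.radical_p:
            ops.append(("radical", i, a.radical_p))
        if a.isotope_r != a.isotope_p:
            ops.append(("isotope", i, a.isotope_p))
    return ops


def compile_pattern(doc: ReactionCodeDoc | str,
                    layers=None) -> ReactionPattern:
    """Compile a parsed code (or code string) into a reaction pattern."""
    if isinstance(doc, str):
        doc = parse(doc)
    cgr, membership = doc_to_cgr(doc)
    if layers is not None:
        wanted = set(layers)
        if not wanted:
            raise ValueError("empty layer selection")
        _check_downward_closed(doc, wanted)
        keep = {gid for lid in wanted for gid in membership[lid]}
        cgr = cgr.subgraph(keep)
    return ReactionPattern(cgr)


# ---------------------------------------------------------------------------
# application


def _load_reactants(reactants) -> list[Chem.Mol]:
    if isinstance(reactants, str):
        p = pathlib.Path(reactants)
        if "\n" not in reactants and p.is_file():
            return [m for m in Chem.SDMolSupplier(str(p)) if m is not None]
        mols = []
        for piece in reactants.split("."):
            mol = Chem.MolFromSmiles(piece)
            if mol is None:
                raise ReactionCodeError(
                    f"unparseable reactant SMILES {piece!r}")
            mols.append(mol)
        return mols
    return [Chem.Mol(m) for m in reactants]


def _target_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetAtomicNum(),
                   charge=atom.GetFormalCharge(),
                   aromatic=atom.GetIsAromatic())
    for bond in mol.GetBonds():
        order = (AROMATIC_ORDER if bond.GetIsAromatic()
                 else int(bond.GetBondTypeAsDouble()))
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=order)
    return g


def _node_match(t, q):
    return (t["element"] == q["element"] and t["charge"] == q["charge"]
            and t["aromatic"] == q["aromatic"])


def _edge_match(t, q):
    return t["order"] == q["order"]


def apply(pattern: ReactionPattern, reactants) -> list[MappedReaction]:
    """All unique reactions obtained by applying ``pattern``.

    ``reactants`` is a SMILES string (molecules separated by '.'), the path
    of an SD file, or a list of molecules.  Returns an empty list when the
    query does not embed.  All atoms of every returned reaction are mapped.
    """
    mols = _load_reactants(reactants)
    if not mols:
        return []
    combined = mols[0]
    for m in mols[1:]:
        combined = Chem.CombineMols(combined, m)
    combined = Chem.RWMol(combined)
    for atom in combined.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    combined = combined.GetMol()

    target = _target_graph(combined)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        target, pattern.query, node_match=_node_match,
        edge_match=_edge_match)

    results: list[MappedReaction] = []
    seen: set = set()
    reactant_frags = list(Chem.GetMolFrags(combined, asMols=True,
                                           sanitizeFrags=False))
    for count, mapping in enumerate(matcher.subgraph_monomorphisms_iter()):
        if count >= _MAX_EMBEDDINGS:
            break
        emb = {q: t for t, q in mapping.items()}  # query atom -> target atom
        product = _apply_instructions(combined, pattern, emb)
        if product is None:
            continue
        frags = list(Chem.GetMolFrags(product, asMols=True,
                                      sanitizeFrags=False))
        key = tuple(sorted(_plain_smiles(f) for f in frags))
        if key in seen:
            continue
        seen.add(key)
        results.append(MappedReaction(
            [Chem.Mol(m) for m in reactant_frags], [], frags))
    return results


def _apply_instructions(combined, pattern: ReactionPattern, emb):
    mol = Chem.RWMol(combined)
    touched: set[int] = set()
    for op in pattern.instructions:
        if op[0] == "bond":
            _, qi, qj, order_r, order_p = op
            ti, tj = emb[qi], emb[qj]
            touched.update((ti, tj))
            if order_p == 0:
                mol.RemoveBond(ti, tj)
            elif order_r == 0:
                mol.AddBond(ti, tj, _BOND_TYPES[order_p])
            else:
                bond = mol.GetBondBetweenAtoms(ti, tj)
                bond.SetBondType(_BOND_TYPES[order_p])
                bond.SetIsAromatic(order_p == AROMATIC_ORDER)
        elif op[0] == "charge":
            mol.GetAtomWithIdx(emb[op[1]]).SetFormalCharge(op[2])
            touched.add(emb[op[1]])
        elif op[0] == "radical":
            mol.GetAtomWithIdx(emb[op[1]]).SetNumRadicalElectrons(op[2])
            touched.add(emb[op[1]])
        elif op[0] == "isotope":
            atom = mol.GetAtomWithIdx(emb[op[1]])
            z = atom.GetAtomicNum()
            atom.SetIsotope(_PT.GetMostCommonIsotope(z) + op[2]
                            if op[2] else 0)
    # atoms whose environment changed get their hydrogen count recomputed
    # by the standard valence model (mapped SMILES input pins every H)
    for t in touched:
        atom = mol.GetAtomWithIdx(t)
        rad = atom.GetNumRadicalElectrons()
        if rad > 0:
            dv = _PT.GetDefaultValence(atom.GetAtomicNum())
            order = sum(1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()
                        for b in atom.GetBonds())
            atom.SetNumExplicitHs(max(int(dv - order - rad), 0))
            atom.SetNoImplicit(True)
        else:
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None  # this embedding yields a valence-invalid product
    return out


def _plain_smiles(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    for atom in m.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(m)


def apply_code(code: str, reactants, layers=None) -> list[MappedReaction]:
    """Convenience: compile ``code`` (optionally a layer subset) and apply."""
    return apply(compile_pattern(code, layers), reactants)
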