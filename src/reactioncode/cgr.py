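"""Condensed graph of reaction: annotation and aggregation.

A mapped reaction is superimposed into a single pseudo-molecule whose atoms
carry a *role* and whose bonds carry both a reactant-side and a product-side
order:

* ``CENTER`` — endpoint of at least one bond whose order differs between the
  two sides (made, broken, or order-changed).  Changes of charge, stereo,
  isotope or radical state alone never make an atom part of the center.
* ``REMAINING`` — present on both sides but not in the center; depth is the
  breadth-first distance from the center set over the union
  (reactant ∪ product) adjacency.
* ``LEAVING`` — present in reactants only; depth is the breadth-first
  distance over the reactant-side adjacency (letter depths, A = 1).

Bonds between a kept atom and a leaving atom are broken (status '7'); bonds
internal to the leaving group are stored unchanged, so that default decoding
regenerates the departed fragment as a product molecule.

Hydrogens are implicit: explicit hydrogen atoms in the input survive as
graph nodes, but no hydrogen counts are stored in the CGR.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit.Chem import BondType

from .codec_tables import AROMATIC_ORDER, Stereo, bond_status
from .errors import (DecodingError, EmptyReactionCenterError, MappingError,
                     ReactionCodeError)
from .reaction_io import MappedReaction


class Role(enum.Enum):
    CENTER = "center"
    REMAINING = "remaining"
    LEAVING = "leaving"


@dataclass
class CGRAtom:
    element: int
    role: Role
    depth: int  # 0 for center; >= 1 otherwise (letter depths count from 1)
    charge_r: int = 0
    charge_p: int = 0
    isotope_r: int = 0  # mass delta vs the most common isotope; 0 = default
    isotope_p: int = 0
    radical_r: int = 0
    radical_p: int = 0
    stereo_r: Stereo = Stereo.NONE
    stereo_p: Stereo = Stereo.NONE
    multiplicity: int = 1  # product stoichiometry ([k] bracket when > 1)
    map_number: int = 0  # provenance; 0 when decoded
    status_char: str | None = None  # carried through partial decoding


@dataclass
class CGRBond:
    i: int
    j: int
    order_r: int  # 0..3, or 9 for aromatic
    order_p: int
    stereo_r: Stereo = Stereo.NONE
    stereo_p: Stereo = Stereo.NONE

    @property
    def status(self) -> str:
        return bond_status(self.order_r, self.order_p)

    def other(self, k: int) -> int:
        return self.j if k == self.i else self.i


@dataclass
class CGR:
    atoms: list[CGRAtom]
    bonds: list[CGRBond]

    def neighbors(self, i: int):
        for b in self.bonds:
            if b.i == i or b.j == i:
                yield b.other(i), b

    def adjacency(self) -> dict[int, list[tuple[int, CGRBond]]]:
        adj: dict[int, list[tuple[int, CGRBond]]] = {
            i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            adj[b.i].append((b.j, b))
            adj[b.j].append((b.i, b))
        return adj

    def subgraph(self, keep: set[int]) -> "CGR":
        """CGR restricted to ``keep``; bonds to excluded atoms are dropped."""
        index = {old: new for new, old in enumerate(sorted(keep))}
        atoms = [replace(self.atoms[old]) for old in sorted(keep)]
        bonds = [replace(b, i=index[b.i], j=index[b.j])
                 for b in self.bonds if b.i in keep and b.j in keep]
        return CGR(atoms, bonds)


# ---------------------------------------------------------------------------
# annotation


def _bond_order(bond: Chem.Bond) -> int:
    if bond.GetIsAromatic() or bond.GetBondType() == BondType.AROMATIC:
        return AROMATIC_ORDER
    order = bond.GetBondTypeAsDouble()
    if order in (1.0, 2.0, 3.0):
        return int(order)
    raise MappingError(f"unsupported bond type {bond.GetBondType()}")


def _atom_stereo(atom: Chem.Atom) -> Stereo:
    tag = atom.GetChiralTag()
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
        return Stereo.CW
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
        return Stereo.CCW
    return Stereo.NONE


def _bond_stereo(bond: Chem.Bond) -> Stereo:
    st = bond.GetStereo()
    if st == Chem.BondStereo.STEREOZ or st == Chem.BondStereo.STEREOCIS:
        return Stereo.CIS
    if st == Chem.BondStereo.STEREOE or st == Chem.BondStereo.STEREOTRANS:
        return Stereo.TRANS
    d = bond.GetBondDir()
    if d == Chem.BondDir.ENDUPRIGHT:
        return Stereo.UP
    if d == Chem.BondDir.ENDDOWNRIGHT:
        return Stereo.DOWN
    return Stereo.NONE


def _collect_side(mols, side: str):
    """(map -> atom info, bond dict keyed by map pair) for one side."""
    atoms: dict[int, Chem.Atom] = {}
    for mol in mols:
        for atom in mol.GetAtoms():
            n = atom.GetAtomMapNum()
            if n == 0:
                if atom.GetAtomicNum() != 1:
                    raise MappingError(
                        f"unmapped heavy atom {atom.GetSymbol()} among {side}; "
                        "encoding requires a complete atom-atom mapping")
                continue
            if n in atoms:
                raise MappingError(f"map number {n} duplicated among {side}")
            atoms[n] = atom
    bonds: dict[frozenset, tuple[int, Stereo]] = {}
    for mol in mols:
        for bond in mol.GetBonds():
            i = bond.GetBeginAtom().GetAtomMapNum()
            j = bond.GetEndAtom().GetAtomMapNum()
            if i == 0 or j == 0:
                continue
            bonds[frozenset((i, j))] = (_bond_order(bond), _bond_stereo(bond))
    return atoms, bonds


def classify_roles(r: MappedReaction):
    """Assign a role to every mapped atom of ``r``.

    Returns ``(roles, ratoms, patoms, rbonds, pbonds)`` where ``roles`` maps
    map numbers to :class:`Role` and the remaining entries are the per-side
    atom/bond collections keyed by map numbers.  Reactant-only atoms are
    LEAVING even when they terminate a broken bond; CENTER is reserved for
    atoms present on both sides.
    """
    ratoms, rbonds = _collect_side(r.reactants, "reactants")
    patoms, pbonds = _collect_side(r.products, "products")
    for n, patom in patoms.items():
        ratom = ratoms.get(n)
        if ratom is None:
            raise MappingError(
                f"product atom with map {n} has no reactant partner")
        if ratom.GetAtomicNum() != patom.GetAtomicNum():
            raise MappingError(
                f"map {n} links {ratom.GetSymbol()} to {patom.GetSymbol()}"
                " - corrupted mapping")

    leaving = set(ratoms) - set(patoms)
    changed: set[int] = set()
    for key in set(rbonds) | set(pbonds):
        i, j = tuple(key)
        if key in rbonds and (i in leaving and j in leaving):
            continue  # leaving-internal bonds depart intact
        order_r = rbonds.get(key, (0, Stereo.NONE))[0]
        order_p = pbonds.get(key, (0, Stereo.NONE))[0]
        if i in leaving or j in leaving:
            order_p = 0  # a bond to a leaving atom is broken by definition
        if order_r != order_p:
            changed.update(key)

    roles: dict[int, Role] = {}
    for n in ratoms:
        if n in leaving:
            roles[n] = Role.LEAVING
        elif n in changed:
            roles[n] = Role.CENTER
        else:
            roles[n] = Role.REMAINING
    return roles, ratoms, patoms, rbonds, pbonds


def _bfs_depths(sources: set[int], adj: dict[int, set[int]]) -> dict[int, int]:
    depth = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in depth:
                depth[v] = depth[u] + 1
                queue.append(v)
    return depth


def build_cgr(r: MappedReaction) -> CGR:
    """Aggregate reactants and products into the condensed graph of reaction.

    Requires a non-empty reaction center; remove spectators first (an
    unchanged bystander molecule has no distance to the center and raises).
    """
    roles, ratoms, patoms, rbonds, pbonds = classify_roles(r)
    if not any(role == Role.CENTER for role in roles.values()):
        raise EmptyReactionCenterError(
            "no bond differs between reactants and products")

    maps = sorted(ratoms)
    index = {n: i for i, n in enumerate(maps)}
    leaving = {n for n, role in roles.items() if role == Role.LEAVING}

    bonds: list[CGRBond] = []
    for key in sorted(set(rbonds) | set(pbonds), key=sorted):
        i, j = sorted(key)
        order_r, stereo_r = rbonds.get(key, (0, Stereo.NONE))
        order_p, stereo_p = pbonds.get(key, (0, Stereo.NONE))
        if i in leaving and j in leaving:
            order_p, stereo_p = order_r, stereo_r
        elif i in leaving or j in leaving:
            order_p, stereo_p = 0, Stereo.NONE
        bonds.append(CGRBond(index[i], index[j], order_r, order_p,
                             stereo_r, stereo_p))

    # depths: union adjacency for kept atoms, reactant adjacency for leaving
    union_adj: dict[int, set[int]] = {n: set() for n in maps}
    react_adj: dict[int, set[int]] = {n: set() for n in maps}
    for key in set(rbonds) | set(pbonds):
        i, j = tuple(key)
        union_adj[i].add(j)
        union_adj[j].add(i)
    for key in rbonds:
        i, j = tuple(key)
        react_adj[i].add(j)
        react_adj[j].add(i)

    centers = {n for n, role in roles.items() if role == Role.CENTER}
    union_depth = _bfs_depths(centers, union_adj)
    react_depth = _bfs_depths(centers, react_adj)

    atoms: list[CGRAtom] = []
    for n in maps:
        ratom = ratoms[n]
        patom = patoms.get(n)
        role = roles[n]
        if role == Role.LEAVING:
            if n not in react_depth:
                raise MappingError(
                    f"leaving atom {n} is disconnected from the reaction "
                    "center; remove spectators first")
            depth = react_depth[n]
        else:
            if n not in union_depth:
                raise MappingError(
                    f"atom {n} is disconnected from the reaction center; "
                    "remove spectators first")
            depth = union_depth[n]
        iso_r = _isotope_delta(ratom)
        atom = CGRAtom(
            element=ratom.GetAtomicNum(), role=role, depth=depth,
            charge_r=ratom.GetFormalCharge(),
            charge_p=(patom.GetFormalCharge() if patom is not None
                      else ratom.GetFormalCharge()),
            isotope_r=iso_r,
            isotope_p=_isotope_delta(patom) if patom is not None else iso_r,
            radical_r=ratom.GetNumRadicalElectrons(),
            radical_p=(patom.GetNumRadicalElectrons() if patom is not None
                       else ratom.GetNumRadicalElectrons()),
            stereo_r=_atom_stereo(ratom),
            stereo_p=(_atom_stereo(patom) if patom is not None
                      else _atom_stereo(ratom)),
            map_number=n,
        )
        atoms.append(atom)
    return CGR(atoms, bonds)


_PT = Chem.GetPeriodicTable()


def _isotope_delta(atom: Chem.Atom) -> int:
    iso = atom.GetIsotope()
    if iso == 0:
        return 0
    return iso - _PT.GetMostCommonIsotope(atom.GetAtomicNum())


# ---------------------------------------------------------------------------
# reconstruction (shared by the decoder and the fixture generator)


_BOND_TYPES = {1: BondType.SINGLE, 2: BondType.DOUBLE, 3: BondType.TRIPLE,
               AROMATIC_ORDER: BondType.AROMATIC}


def _build_side(cgr: CGR, side: str, keep: set[int], extra_bonds=(),
                kekulize: bool = True, map_numbers=None):
    """RWMol of one side; returns (mols, kekulization_failures)."""
    mol = Chem.RWMol()
    handle: dict[int, int] = {}
    aromatic: set[int] = set()
    for i in sorted(keep):
        a = cgr.atoms[i]
        atom = Chem.Atom(a.element)
        leaving_in_products = side == "p" and a.role == Role.LEAVING
        charge = a.charge_r if side == "r" or leaving_in_products else a.charge_p
        iso = a.isotope_r if side == "r" or leaving_in_products else a.isotope_p
        rad = a.radical_r if side == "r" or leaving_in_products else a.radical_p
        st = a.stereo_r if side == "r" or leaving_in_products else a.stereo_p
        atom.SetFormalCharge(charge)
        if iso != 0:
            atom.SetIsotope(_PT.GetMostCommonIsotope(a.element) + iso)
        if st == Stereo.CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
        elif st == Stereo.CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        n = (map_numbers[i] if map_numbers else i + 1)
        atom.SetAtomMapNum(n)
        handle[i] = mol.AddAtom(atom)
        if rad > 0:
            atom = mol.GetAtomWithIdx(handle[i])
            atom.SetNumRadicalElectrons(rad)

    order_sum: dict[int, float] = {i: 0.0 for i in keep}
    cis_trans: list[tuple[int, Stereo]] = []
    all_bonds = list(cgr.bonds) + list(extra_bonds)
    for b in all_bonds:
        if b.i not in keep or b.j not in keep:
            continue
        leaving_pair = (cgr.atoms[b.i].role == Role.LEAVING
                        and cgr.atoms[b.j].role == Role.LEAVING)
        order = b.order_r if side == "r" else b.order_p
        stereo = b.stereo_r if side == "r" else b.stereo_p
        if side == "p" and leaving_pair and b.order_p == 0:
            # leaving-internal bonds persist when the fragment is a product
            order, stereo = b.order_r, b.stereo_r
        if order == 0:
            continue
        bi = mol.AddBond(handle[b.i], handle[b.j],
                         _BOND_TYPES[order]) - 1
        bond = mol.GetBondWithIdx(bi)
        if order == AROMATIC_ORDER:
            bond.SetIsAromatic(True)
            aromatic.update((handle[b.i], handle[b.j]))
            order_sum[b.i] += 1.5
            order_sum[b.j] += 1.5
        else:
            order_sum[b.i] += order
            order_sum[b.j] += order
        if stereo == Stereo.UP:
            bond.SetBondDir(Chem.BondDir.ENDUPRIGHT)
        elif stereo == Stereo.DOWN:
            bond.SetBondDir(Chem.BondDir.ENDDOWNRIGHT)
        elif stereo in (Stereo.CIS, Stereo.TRANS):
            cis_trans.append((bi, stereo))

    # cis/trans needs reference atoms on both ends; set them once the whole
    # connection table exists (skipped when an end has no other neighbor)
    for bi, stereo in cis_trans:
        bond = mol.GetBondWithIdx(bi)
        refs = []
        for end in (bond.GetBeginAtom(), bond.GetEndAtom()):
            nbrs = [a.GetIdx() for a in end.GetNeighbors()
                    if a.GetIdx() not in (bond.GetBeginAtomIdx(),
                                          bond.GetEndAtomIdx())]
            refs.append(min(nbrs) if nbrs else None)
        if None not in refs:
            bond.SetStereoAtoms(refs[0], refs[1])
            bond.SetStereo(Chem.BondStereo.STEREOCIS
                           if stereo == Stereo.CIS
                           else Chem.BondStereo.STEREOTRANS)

    for idx in aromatic:
        mol.GetAtomWithIdx(idx).SetIsAromatic(True)

    # hydrogen model: standard valences; radicals consume valence slots
    for i in keep:
        a = cgr.atoms[i]
        leaving_in_products = side == "p" and a.role == Role.LEAVING
        rad = a.radical_r if side == "r" or leaving_in_products else a.radical_p
        if rad > 0:
            atom = mol.GetAtomWithIdx(handle[i])
            dv = _PT.GetDefaultValence(a.element)
            nh = max(int(dv - order_sum[i] - rad), 0)
            atom.SetNumExplicitHs(nh)
            atom.SetNoImplicit(True)

    failures = 0
    out = mol.GetMol()
    partial = (Chem.SanitizeFlags.SANITIZE_ALL
               ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    try:
        if kekulize:
            Chem.SanitizeMol(out)
        else:
            Chem.SanitizeMol(out, partial)
    except Chem.rdchem.KekulizeException:
        failures += 1
        Chem.SanitizeMol(out, partial)
    except Exception as exc:
        raise DecodingError(f"reconstructed {side!r} side failed valence "
                            f"sanitization: {exc}") from None
    frags = Chem.GetMolFrags(out, asMols=True, sanitizeFrags=False)
    return list(frags), failures


def cgr_to_reaction(cgr: CGR, include_leaving: bool = True,
                    kekulize_final: bool = True, extra_bonds=(),
                    map_numbers=None):
    """Reconstruct a :class:`MappedReaction` from a CGR.

    Reactant side: every atom, bonds with a non-zero reactant order.
    Product side: center + remaining atoms (plus leaving atoms when
    ``include_leaving``, which regenerates a balanced reaction), bonds with
    a non-zero product order.  ``extra_bonds`` lets the rebalancer add
    deduced made bonds.  Returns ``(reaction, kekulization_failures)``.
    """
    every = set(range(len(cgr.atoms)))
    kept = {i for i in every if cgr.atoms[i].role != Role.LEAVING}
    if not include_leaving:
        product_atoms = kept
    else:
        product_atoms = every
    reactants, f1 = _build_side(cgr, "r", every, (), kekulize_final,
                                map_numbers)
    products, f2 = _build_side(cgr, "p", product_atoms, extra_bonds,
                               kekulize_final, map_numbers)
    return MappedReaction(reactants, [], products), f1 + f2


# ---------------------------------------------------------------------------
# pseudo-molecule export

_ROLE_TAG = {Role.CENTER: "C", Role.REMAINING: "R", Role.LEAVING: "L"}
_TAG_ROLE = {v: k for k, v in _ROLE_TAG.items()}


def export_pseudo_molecule(cgr: CGR) -> str:
    """One SD-file record of the pseudo-molecule.

    The V2000 connection table carries the reactant-side orders (made bonds
    are written single so every CGR bond is present); the dual bond states,
    roles, depths and dual atom states live in the ``RC_ATOMS`` / ``RC_BONDS``
    property fields, making the record lossless with respect to the CGR.
    """
    mol = Chem.RWMol()
    for a in cgr.atoms:
        atom = Chem.Atom(a.element)
        atom.SetAtomMapNum(a.map_number or 0)
        mol.AddAtom(atom)
    for b in cgr.bonds:
        order = b.order_r if b.order_r else b.order_p
        mol.AddBond(b.i, b.j, _BOND_TYPES[1 if order == AROMATIC_ORDER
                                          else order])
    out = mol.GetMol()
    out.UpdatePropertyCache(strict=False)
    block = Chem.MolToMolBlock(out, kekulize=False)

    atom_lines = [
        f"{i} {_ROLE_TAG[a.role]} {a.depth} {a.element} "
        f"{a.charge_r} {a.charge_p} {a.isotope_r} {a.isotope_p} "
        f"{a.radical_r} {a.radical_p} {a.stereo_r.value} {a.stereo_p.value} "
        f"{a.multiplicity} {a.map_number}"
        for i, a in enumerate(cgr.atoms)]
    bond_lines = [
        f"{b.i} {b.j} {b.order_r} {b.order_p} "
        f"{b.stereo_r.value} {b.stereo_p.value}"
        for b in cgr.bonds]
    rec = [block.rstrip("\n"),
           ">  <RC_ATOMS>", "\n".join(atom_lines), "",
           ">  <RC_BONDS>", "\n".join(bond_lines) or " ", "",
           "$$$$", ""]
    return "\n".join(rec)


def import_pseudo_molecule(record: str) -> CGR:
    """Invert :func:`export_pseudo_molecule`."""
    def _field(tag):
        marker = f">  <{tag}>"
        if marker not in record:
            raise ReactionCodeError(f"pseudo-molecule record lacks {tag}")
        body = record.split(marker, 1)[1]
        return [ln for ln in body.split("\n\n", 1)[0].splitlines()
                if ln.strip()]

    atoms = []
    for line in _field("RC_ATOMS"):
        (_, role, depth, z, cr, cp, ir, ip, rr, rp, sr, sp, mult,
         mapn) = line.split()
        atoms.append(CGRAtom(
            element=int(z), role=_TAG_ROLE[role], depth=int(depth),
            charge_r=int(cr), charge_p=int(cp),
            isotope_r=int(ir), isotope_p=int(ip),
            radical_r=int(rr), radical_p=int(rp),
            stereo_r=Stereo(sr), stereo_p=Stereo(sp),
            multiplicity=int(mult), map_number=int(mapn)))
    bonds = []
    for line in _field("RC_BONDS"):
        i, j, orr, orp, sr, sp = line.split()
        bonds.append(CGRBond(int(i), int(j), int(orr), int(orp),
                             Stereo(sr), Stereo(sp)))
    return CGR(atoms, bonds)


def pseudo_smiles(cgr: CGR) -> str:
    """Reactant-projection SMILES of the pseudo-molecule (informative only)."""
    mol = Chem.RWMol()
    for a in cgr.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.charge_r)
        atom.SetAtomMapNum(a.map_number or 0)
        mol.AddAtom(atom)
    for b in cgr.bonds:
        order = b.order_r if b.order_r else b.order_p
        mol.AddBond(b.i, b.j, _BOND_TYPES[1 if order == AROMATIC_ORDER
                                          else order])
    out = mol.GetMol()
    out.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(out)
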