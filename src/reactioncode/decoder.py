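"""Parsing of ReactionCode strings and reconstruction of reactions.

``parse`` produces a structural document (:class:`ReactionCodeDoc`) whose
serialization is byte-identical to its input (after whitespace removal);
``decode`` rebuilds the CGR from all or a downward-closed subset of layers
and turns it back into a mapped reaction with fresh consecutive map
numbers.  Implicit hydrogens are filled by the host toolkit's standard
valence model; kekulization of aromatic systems is attempted for final
reactions and failures are reported per reaction, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cgr import CGR, CGRAtom, CGRBond, Role, cgr_to_reaction
from .codec_tables import (STATUS_RANK, Stereo, bond_order_char,
                           bond_order_value, decode_index, element_code,
                           element_number, offset_value, stereo_value)
from .encoder import layer_depth_from_id
from .errors import DecodingError, ParseError
from .reaction_io import MappedReaction

_SUBLAYER_TAGS = "csir"


@dataclass
class BondEntryDoc:
    order_r: int
    order_p: int
    ref: str  # 2-char partner reference, kept verbatim


@dataclass
class AtomEntryDoc:
    status: str
    element: int
    bonds: list[BondEntryDoc] = field(default_factory=list)
    stoich: int = 1


@dataclass
class LayerDoc:
    id: str
    block: str  # 'main' | 'leaving'
    depth: int
    atoms: list[AtomEntryDoc] = field(default_factory=list)
    #: sub-layers in parse order: (tag, [(index, reactant char, product char)])
    sublayers: list[tuple[str, list[tuple[int, str, str]]]] = \
        field(default_factory=list)


@dataclass
class ReactionCodeDoc:
    layers: list[LayerDoc]

    def serialize(self) -> str:
        out = []
        for layer in self.layers:
            parts = [layer.id, ":"]
            for a in layer.atoms:
                parts.append(a.status + element_code(a.element) + "(")
                for b in a.bonds:
                    parts.append(bond_order_char(b.order_r)
                                 + bond_order_char(b.order_p) + b.ref)
                parts.append(")")
                if a.stoich > 1:
                    parts.append(f"[{a.stoich}]")
            for tag, entries in layer.sublayers:
                parts.append("/" + tag)
                for idx, cr, cp in entries:
                    parts.append(f"{idx:02d}{cr}{cp}")
            parts.append("|")
            out.append("".join(parts))
        return "".join(out)

    def layer_ids(self) -> list[str]:
        return [l.id for l in self.layers]


# ---------------------------------------------------------------------------
# parsing


def parse(code: str) -> ReactionCodeDoc:
    """Exact structural parse of a ReactionCode string."""
    s = "".join(code.split())
    if not s:
        raise ParseError("empty ReactionCode", pos=0)
    i, n = 0, len(s)
    layers: list[LayerDoc] = []
    while i < n:
        j = s.find(":", i)
        if j < 0:
            raise ParseError("expected ':' after a layer id", pos=i)
        lid = s[i:j]
        try:
            block, depth = layer_depth_from_id(lid)
        except ValueError:
            raise ParseError(f"malformed layer header {lid!r}", pos=i)
        i = j + 1
        layer = LayerDoc(lid, block, depth)
        while i < n and s[i] not in "/|":
            layer.atoms.append(_parse_atom(s, i))
            i = _atom_end(s, i)
        while i < n and s[i] == "/":
            if i + 1 >= n or s[i + 1] not in _SUBLAYER_TAGS:
                tag = s[i + 1] if i + 1 < n else "?"
                raise ParseError(f"unknown sub-layer tag '/{tag}'", pos=i)
            tag = s[i + 1]
            i += 2
            start = i
            while i < n and s[i] not in "/|":
                i += 1
            body = s[start:i]
            if len(body) % 4 != 0 or not body:
                raise ParseError(
                    f"sub-layer /{tag} body length {len(body)} is not a "
                    "multiple of 4", pos=start)
            entries = []
            for k in range(0, len(body), 4):
                idx_txt = body[k:k + 2]
                if not idx_txt.isdigit():
                    raise ParseError(
                        f"sub-layer entity index {idx_txt!r} is not decimal",
                        pos=start + k)
                entries.append((int(idx_txt), body[k + 2], body[k + 3]))
            layer.sublayers.append((tag, entries))
        if i >= n or s[i] != "|":
            raise ParseError("layer not terminated by '|'", pos=i)
        i += 1
        layers.append(layer)

    _validate_structure(layers)
    return ReactionCodeDoc(layers)


def _parse_atom(s: str, i: int) -> AtomEntryDoc:
    n = len(s)
    if i + 3 > n:
        raise ParseError("truncated atom code", pos=i)
    status = s[i]
    if status not in STATUS_RANK:
        raise ParseError(f"invalid atom status character {status!r}", pos=i)
    try:
        element = element_number(s[i + 1:i + 3])
    except ValueError as exc:
        raise ParseError(str(exc), pos=i + 1)
    i += 3
    if i >= n or s[i] != "(":
        raise ParseError("expected '(' opening a connection table", pos=i)
    i += 1
    bonds = []
    while i < n and s[i] != ")":
        if i + 4 > n:
            raise ParseError("truncated bond entry", pos=i)
        try:
            order_r = bond_order_value(s[i])
            order_p = bond_order_value(s[i + 1])
        except ValueError as exc:
            raise ParseError(str(exc), pos=i)
        if order_r == 0 and order_p == 0:
            raise ParseError("bond entry absent on both sides", pos=i)
        ref = s[i + 2:i + 4]
        try:
            decode_index(ref)
        except ValueError as exc:
            raise ParseError(str(exc), pos=i + 2)
        bonds.append(BondEntryDoc(order_r, order_p, ref))
        i += 4
    if i >= n:
        raise ParseError("connection table not closed", pos=i)
    i += 1
    stoich = 1
    if i < n and s[i] == "[":
        j = s.find("]", i)
        if j < 0 or not s[i + 1:j].isdigit():
            raise ParseError("malformed stoichiometry bracket", pos=i)
        stoich = int(s[i + 1:j])
        if stoich < 1:
            raise ParseError("stoichiometry must be positive", pos=i)
    return AtomEntryDoc(status, element, bonds, stoich)


def _atom_end(s: str, i: int) -> int:
    i += 3  # atom code
    i = s.find(")", i) + 1
    if i < len(s) and s[i] == "[":
        i = s.find("]", i) + 1
    return i


def _validate_structure(layers: list[LayerDoc]) -> None:
    if not layers or layers[0].id != "0":
        raise ParseError("the code must start with the depth-0 layer '0:'",
                         pos=0)
    if not layers[0].atoms:
        raise ParseError("empty reaction center (depth-0 layer has no atoms)",
                         pos=2)
    seen_letter = False
    prev = {"main": -1, "leaving": 0}
    for layer in layers:
        if layer.block == "leaving":
            seen_letter = True
        elif seen_letter:
            raise ParseError("numeric layers must precede letter layers")
        if layer.depth <= prev[layer.block]:
            raise ParseError(
                f"layer ids must be strictly increasing ({layer.id!r})")
        prev[layer.block] = layer.depth


# ---------------------------------------------------------------------------
# document -> CGR


def doc_to_cgr(doc: ReactionCodeDoc) -> tuple[CGR, dict[str, list[int]]]:
    """Rebuild the CGR; also returns the per-layer global atom ids."""
    atoms: list[CGRAtom] = []
    bonds: list[CGRBond] = []
    main_pos: list[int] = []   # global atom id of each main-block position
    leave_pos: list[int] = []
    membership: dict[str, list[int]] = {}

    for layer in doc.layers:
        layer_atom_ids = []
        entities: list[tuple[str, int]] = []  # ('a', atom id) / ('b', bond #)
        for entry in layer.atoms:
            gid = len(atoms)
            role = (Role.LEAVING if layer.block == "leaving"
                    else Role.CENTER if layer.depth == 0 else Role.REMAINING)
            atoms.append(CGRAtom(
                element=entry.element, role=role, depth=layer.depth,
                multiplicity=entry.stoich, status_char=entry.status))
            layer_atom_ids.append(gid)
            entities.append(("a", gid))
            if layer.block == "main":
                main_pos.append(gid)
            else:
                leave_pos.append(gid)
            for b in entry.bonds:
                blk, pos = decode_index(b.ref)
                table = main_pos if blk == "main" else leave_pos
                if pos >= len(table) or table[pos] == gid:
                    raise ParseError(
                        f"dangling partner index {b.ref!r} in layer "
                        f"{layer.id!r}")
                bonds.append(CGRBond(table[pos], gid, b.order_r, b.order_p))
                entities.append(("b", len(bonds) - 1))
        membership[layer.id] = layer_atom_ids
        _apply_sublayers(layer, entities, atoms, bonds)
    return CGR(atoms, bonds), membership


def _apply_sublayers(layer, entities, atoms, bonds) -> None:
    for tag, entries in layer.sublayers:
        for idx, cr, cp in entries:
            if idx >= len(entities):
                raise ParseError(
                    f"sub-layer /{tag} entity index {idx} out of range in "
                    f"layer {layer.id!r}")
            kind, x = entities[idx]
            try:
                if tag == "s":
                    sr, sp = stereo_value(cr), stereo_value(cp)
                    obj = atoms[x] if kind == "a" else bonds[x]
                    obj.stereo_r, obj.stereo_p = sr, sp
                    continue
                vr, vp = offset_value(cr), offset_value(cp)
            except ValueError as exc:
                raise ParseError(f"sub-layer /{tag}: {exc}")
            if kind != "a":
                raise ParseError(
                    f"sub-layer /{tag} entity {idx} is a bond; only atoms "
                    "carry this property")
            atom = atoms[x]
            if tag == "c":
                atom.charge_r, atom.charge_p = vr, vp
            elif tag == "i":
                atom.isotope_r, atom.isotope_p = vr, vp
            elif tag == "r":
                atom.radical_r, atom.radical_p = vr, vp


# ---------------------------------------------------------------------------
# decoding


@dataclass
class DecodeOptions:
    """Options of :func:`decode`.

    ``layers``: subset of layer ids to decode (default: all).  The subset
    must be downward-closed per block -- depth 2 cannot be taken without
    depths 0 and 1.
    ``include_leaving``: keep the leaving atoms on the product side, which
    regenerates a balanced reaction; with ``False`` the original unbalanced
    reaction is regenerated.
    ``correct_products``: run the missing-bond deduction of the rebalancer.
    ``kekulize_final``: attempt kekulization of the reconstructed molecules;
    failures are counted in the reaction's ``kekulization_failures``
    property either way.
    """

    layers: set[str] | None = None
    include_leaving: bool = True
    correct_products: bool = False
    kekulize_final: bool = True
    original_product_maps: set[int] | None = None
    flagged_atoms: set[int] | None = None


def _check_downward_closed(doc: ReactionCodeDoc, wanted: set[str]) -> None:
    unknown = wanted - set(doc.layer_ids())
    if unknown:
        raise ValueError(f"unknown layer ids {sorted(unknown)}")
    for block in ("main", "leaving"):
        depths = sorted(l.depth for l in doc.layers
                        if l.block == block and l.id in wanted)
        lowest = 0 if block == "main" else 1
        if depths and depths != list(range(lowest, lowest + len(depths))):
            raise ValueError(
                f"layer filter is not downward-closed in the {block} block")
    if "0" not in wanted:
        raise ValueError("the depth-0 layer cannot be excluded")


def decode(doc: ReactionCodeDoc,
           opts: DecodeOptions | None = None) -> MappedReaction:
    """Reconstruct a mapped reaction from a parsed ReactionCode."""
    opts = opts or DecodeOptions()
    cgr, membership = doc_to_cgr(doc)
    if opts.layers is not None:
        wanted = set(opts.layers)
        _check_downward_closed(doc, wanted)
        keep = {gid for lid in wanted for gid in membership[lid]}
        cgr = cgr.subgraph(keep)

    extra_bonds = []
    if opts.correct_products:
        from .rebalance import deduce_missing_bonds  # local: avoids a cycle
        product_maps = opts.original_product_maps
        extra_bonds = deduce_missing_bonds(
            cgr, original_product_maps=product_maps,
            flagged_atoms=opts.flagged_atoms)

    reaction, failures = cgr_to_reaction(
        cgr, include_leaving=opts.include_leaving,
        kekulize_final=opts.kekulize_final, extra_bonds=extra_bonds)
    reaction.properties["kekulization_failures"] = str(failures)
    return reaction


def decode_code(code: str, opts: DecodeOptions | None = None) -> MappedReaction:
    """Convenience: parse then decode."""
    return decode(parse(code), opts)
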