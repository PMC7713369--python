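"""Canonical serialization of a CGR into the layered ReactionCode string.

Structure of the output::

    0:<atom entries>[/c...][/s...][/i...][/r...]|1:...|...|A:...|B:...|

The numeric block (reaction center at depth 0, then the remaining shells)
precedes the letter block (leaving shells, A = depth 1).  Every layer is
``<id>:`` followed by its atom entries, the optional sub-layers in the fixed
order /c, /s, /i, /r, and the ``|`` terminator.  An atom entry is the 3-char
atom code (highest incident bond status + 2-char element code), a
parenthesized connection table whose 4-character bond entries reference only
atoms already emitted (reactant-order char, product-order char, 2-char
partner index), and an optional ``[k]`` stoichiometry bracket.

Canonical ordering.  Within each layer the atoms are ordered so that the
serialized layer -- and, among layer ties, the whole remaining code -- is
lexicographically maximal over every layer-respecting ordering ("reverse
sorted", with conflicts resolved through the connection tables, the atom
properties and finally the deeper layers, which is exactly what maximizing
the tail of the string compares).  The search is exact: a depth-first
enumeration of in-layer orderings with prefix pruning (all candidate layer
strings have equal length, so a partial emission that drops below the best
known prefix can never recover), plus branching over layer-level ties.
Layers larger than ``_EXACT_LIMIT`` atoms fall back to a wide beam search.
"""

from __future__ import annotations

from rdkit import Chem

from .cgr import CGR, Role, build_cgr
from .codec_tables import (INDEX_CAPACITY, STATUS_RANK, Stereo,
                           bond_order_char, element_code, leaving_index_code,
                           main_index_code, offset_char)
from .errors import EmptyReactionCenterError, EncodingError
from .reaction_io import MappedReaction, remove_spectators

_EXACT_LIMIT = 12  # layer size beyond which the exact search becomes a beam
_BEAM_WIDTH = 12
_TIE_CAP = 16     # layer-level tie orderings carried into deeper layers
_PATH_CAP = 256   # complete serializations compared at the end


def letter_layer_id(depth: int) -> str:
    """Letter id of a leaving layer: 1 -> 'A', 26 -> 'Z', 27 -> 'AA'."""
    if depth < 1:
        raise ValueError("leaving depths start at 1")
    s = ""
    while depth > 0:
        depth, r = divmod(depth - 1, 26)
        s = chr(ord("A") + r) + s
    return s


def layer_depth_from_id(layer_id: str) -> tuple[str, int]:
    """('main'|'leaving', depth) from a layer id string."""
    if layer_id.isdigit():
        return "main", int(layer_id)
    if layer_id.isalpha() and layer_id.isupper():
        d = 0
        for c in layer_id:
            d = d * 26 + (ord(c) - ord("A") + 1)
        return "leaving", d
    raise ValueError(f"invalid layer id {layer_id!r}")


class _Encoder:
    def __init__(self, cgr: CGR):
        self.cgr = cgr
        self.adj = cgr.adjacency()
        self.codes = [self._atom_code(i) for i in range(len(cgr.atoms))]
        main_layers: dict[int, list[int]] = {}
        leave_layers: dict[int, list[int]] = {}
        for i, a in enumerate(cgr.atoms):
            target = leave_layers if a.role == Role.LEAVING else main_layers
            target.setdefault(a.depth, []).append(i)
        if 0 not in main_layers:
            raise EmptyReactionCenterError("CGR has no depth-0 layer")
        self.layers = (
            [(str(d), "main", main_layers[d]) for d in sorted(main_layers)]
            + [(letter_layer_id(d), "leaving", leave_layers[d])
               for d in sorted(leave_layers)])
        n_main = sum(len(v) for v in main_layers.values())
        n_leave = sum(len(v) for v in leave_layers.values())
        if n_main > INDEX_CAPACITY or n_leave > INDEX_CAPACITY:
            raise EncodingError(
                f"block size exceeds the {INDEX_CAPACITY}-atom index capacity")

    def _atom_code(self, i: int) -> str:
        a = self.cgr.atoms[i]
        status = a.status_char
        if status is None:
            status = "0"
            for _, b in self.adj[i]:
                s = b.status
                if STATUS_RANK[s] > STATUS_RANK[status]:
                    status = s
        return status + element_code(a.element)

    # -- entry emission ----------------------------------------------------

    def _entry(self, i: int, refs: dict[int, str]):
        """(serialized atom entry, incident bonds in emitted table order)."""
        table = []
        for j, b in self.adj[i]:
            ref = refs.get(j)
            if ref is None:
                continue
            chars = (bond_order_char(b.order_r) + bond_order_char(b.order_p)
                     + ref)
            table.append((chars, b))
        table.sort(key=lambda t: t[0], reverse=True)
        a = self.cgr.atoms[i]
        text = (self.codes[i] + "("
                + "".join(chars for chars, _ in table) + ")")
        if a.multiplicity > 1:
            text += f"[{a.multiplicity}]"
        return text, [b for _, b in table]

    def _sublayers(self, order, bondlists) -> str:
        atoms = self.cgr.atoms
        entities: list[tuple[str, object]] = []
        for i, blist in zip(order, bondlists):
            entities.append(("a", i))
            entities.extend(("b", b) for b in blist)
        if len(entities) > 100:
            raise EncodingError("more than 100 entities in one layer; the "
                                "2-digit sub-layer index overflows")
        parts = []
        for tag in "csir":
            chunk = []
            for idx, (kind, x) in enumerate(entities):
                if tag == "c" and kind == "a":
                    a = atoms[x]
                    if (a.charge_r, a.charge_p) != (0, 0):
                        chunk.append(f"{idx:02d}" + offset_char(a.charge_r)
                                     + offset_char(a.charge_p))
                elif tag == "i" and kind == "a":
                    a = atoms[x]
                    if (a.isotope_r, a.isotope_p) != (0, 0):
                        chunk.append(f"{idx:02d}" + offset_char(a.isotope_r)
                                     + offset_char(a.isotope_p))
                elif tag == "r" and kind == "a":
                    a = atoms[x]
                    if (a.radical_r, a.radical_p) != (0, 0):
                        chunk.append(f"{idx:02d}" + offset_char(a.radical_r)
                                     + offset_char(a.radical_p))
                elif tag == "s":
                    obj = atoms[x] if kind == "a" else x
                    if (obj.stereo_r, obj.stereo_p) != (Stereo.NONE,
                                                        Stereo.NONE):
                        chunk.append(f"{idx:02d}" + obj.stereo_r.value
                                     + obj.stereo_p.value)
            if chunk:
                parts.append("/" + tag + "".join(chunk))
        return "".join(parts)

    # -- in-layer canonical ordering ---------------------------------------

    def _ref_for(self, block: str, position: int) -> str:
        return (main_index_code(position) if block == "main"
                else leaving_index_code(position))

    def _layer_candidates(self, atom_ids, block, refs, start_pos):
        """Orderings of one layer maximizing its serialization.

        Returns ``(layer_text, orderings)``; every ordering in ``orderings``
        yields exactly ``layer_text`` (main sub-layer + optional sub-layers).
        """
        if len(atom_ids) > _EXACT_LIMIT:
            return self._layer_beam(atom_ids, block, refs, start_pos)
        best_main: str | None = None
        leaves: list[tuple[str, list[int], list[list]]] = []

        def rec(order, remaining, partial, local_refs, bondlists):
            nonlocal best_main
            if best_main is not None:
                prefix = best_main[:len(partial)]
                if partial < prefix:
                    return
            if not remaining:
                if best_main is None or partial > best_main:
                    best_main = partial
                    leaves.clear()
                if partial == best_main and len(leaves) < 4 * _TIE_CAP:
                    leaves.append((partial, list(order), list(bondlists)))
                return
            scored = []
            for i in remaining:
                entry, bonds = self._entry(i, local_refs)
                scored.append((entry, i, bonds))
            scored.sort(key=lambda t: t[0], reverse=True)
            for entry, i, bonds in scored:
                pos = start_pos + len(order)
                local_refs[i] = self._ref_for(block, pos)
                order.append(i)
                bondlists.append(bonds)
                rec(order, remaining - {i}, partial + entry, local_refs,
                    bondlists)
                order.pop()
                bondlists.pop()
                del local_refs[i]

        rec([], set(atom_ids), "", dict(refs), [])
        best_full = None
        orders = []
        for partial, order, bondlists in leaves:
            full = partial + self._sublayers(order, bondlists)
            if best_full is None or full > best_full:
                best_full = full
                orders = [order]
            elif full == best_full:
                orders.append(order)
        return best_full, orders[:_TIE_CAP]

    def _layer_beam(self, atom_ids, block, refs, start_pos):
        """Greedy beam fallback for very large layers (documented cap)."""
        beam = [("", [], dict(refs), [])]
        for _ in range(len(atom_ids)):
            nxt = []
            for partial, order, local_refs, bondlists in beam:
                remaining = [i for i in atom_ids if i not in order]
                for i in remaining:
                    entry, bonds = self._entry(i, local_refs)
                    r2 = dict(local_refs)
                    r2[i] = self._ref_for(block, start_pos + len(order))
                    nxt.append((partial + entry, order + [i], r2,
                                bondlists + [bonds]))
            nxt.sort(key=lambda t: t[0], reverse=True)
            beam = nxt[:_BEAM_WIDTH]
        best_full, orders = None, []
        for partial, order, _, bondlists in beam:
            full = partial + self._sublayers(order, bondlists)
            if best_full is None or full > best_full:
                best_full, orders = full, [order]
            elif full == best_full:
                orders.append(order)
        return best_full, orders[:_TIE_CAP]

    # -- full-code search ---------------------------------------------------

    def encode(self) -> str:
        results: list[str] = []

        def rec(li, refs, positions, prefix):
            if len(results) >= _PATH_CAP:
                return
            if li == len(self.layers):
                results.append(prefix)
                return
            layer_id, block, atom_ids = self.layers[li]
            start = positions[block]
            text, orders = self._layer_candidates(atom_ids, block, refs,
                                                  start)
            chunk = f"{layer_id}:{text}|"
            for order in orders:
                new_refs = dict(refs)
                for k, i in enumerate(order):
                    new_refs[i] = self._ref_for(block, start + k)
                new_pos = dict(positions)
                new_pos[block] = start + len(order)
                rec(li + 1, new_refs, new_pos, prefix + chunk)

        rec(0, {}, {"main": 0, "leaving": 0}, "")
        return max(results)

    def serialize_with_order(self, orderings) -> str:
        """Serialize with explicit per-layer atom orderings (oracle hook).

        ``orderings`` matches ``self.layers``: one list of atom ids per
        layer, each a permutation of that layer's atoms.
        """
        refs: dict[int, str] = {}
        positions = {"main": 0, "leaving": 0}
        out = []
        for (layer_id, block, atom_ids), order in zip(self.layers, orderings):
            if sorted(order) != sorted(atom_ids):
                raise ValueError("ordering does not match the layer")
            partial = ""
            bondlists = []
            for i in order:
                entry, bonds = self._entry(i, refs)
                refs[i] = self._ref_for(block, positions[block])
                positions[block] += 1
                partial += entry
                bondlists.append(bonds)
            out.append(f"{layer_id}:{partial}"
                       f"{self._sublayers(order, bondlists)}|")
        return "".join(out)


def encode(cgr: CGR) -> str:
    """Canonical ReactionCode of a CGR."""
    return _Encoder(cgr).encode()


def layer_plan(cgr: CGR):
    """The (id, block, atom ids) layers the encoder would emit (test hook)."""
    return _Encoder(cgr).layers


def serialize_with_order(cgr: CGR, orderings) -> str:
    return _Encoder(cgr).serialize_with_order(orderings)


def encode_reaction(r: MappedReaction, strip_spectators: bool = True,
                    use_bond_orders: bool = False) -> str:
    """Pipeline helper: mapped reaction -> canonical ReactionCode.

    ``use_bond_orders=True`` kekulizes every molecule and clears the
    aromatic flags first, so aromatic systems are encoded with alternating
    single/double orders instead of the default aromatic character.
    """
    if strip_spectators:
        r = remove_spectators(r)
    if use_bond_orders:
        r = r.copy()
        for mol in r.reactants + r.products:
            Chem.Kekulize(mol, clearAromaticFlags=True)
    return encode(build_cgr(r))
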