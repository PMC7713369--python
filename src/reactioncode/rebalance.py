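"""Rebalancing of unbalanced reactions through the CGR.

An unbalanced reaction (products missing) encodes with leaving layers.
Because the code carries both bond states, default decoding already
regenerates the departed fragments as product molecules; what it cannot
know is whether a *made* bond between two of those fragments is missing.
:func:`deduce_missing_bonds` applies the deliberately narrow deduction
rule: a new bond is proposed between a depth-A leaving atom and a
reaction-center atom of status '7' only when both are carbons and neither
is detected in the original products.  ("Non-heteroatom" is read as
carbon, so only C-C bonds are ever deduced.)

:func:`encode_and_rebalance` wraps the whole cycle: encode the unbalanced
reaction (the *non-final* code), decode it with correction, and re-encode
the corrected, balanced reaction into a *final* code -- one whose own
decode/re-encode cycle reproduces it byte-identically.  Atoms that appear
in the given products as lone disconnected fragments of a broken bond are
flagged as already correct and excluded from any correction; the flags are
an annotation of the non-final code's document, never serialized.
"""

from __future__ import annotations

from .cgr import CGR, CGRBond, Role, build_cgr, cgr_to_reaction
from .codec_tables import STATUS_RANK
from .encoder import encode
from .errors import ReactionCodeError
from .reaction_io import MappedReaction, remove_spectators

_CARBON = 6


def _atom_status(cgr: CGR, i: int) -> str:
    a = cgr.atoms[i]
    if a.status_char is not None:
        return a.status_char
    status = "0"
    for _, b in cgr.neighbors(i):
        if STATUS_RANK[b.status] > STATUS_RANK[status]:
            status = b.status
    return status


def deduce_missing_bonds(cgr: CGR, original_product_maps=None,
                         flagged_atoms=None) -> list[CGRBond]:
    """Candidate made bonds restoring the balance of a corrected reaction.

    Candidates are pairs (leaving atom at letter depth A) x (CENTER atom
    with status '7'); a bond (order_r=0, order_p=1) is proposed when both
    atoms are carbon and neither is detected in the original products.
    Detection is by map number against ``original_product_maps`` when
    given; otherwise every non-leaving atom counts as detected (a CGR built
    from a reaction always has its kept atoms in the products, so with no
    external information the deduction is conservative and returns
    nothing).  ``flagged_atoms`` (CGR atom indices) are excluded outright.
    """
    flagged = flagged_atoms or set()

    def detected(i: int) -> bool:
        a = cgr.atoms[i]
        if original_product_maps is None:
            return a.role != Role.LEAVING
        return a.map_number in original_product_maps

    new_bonds: list[CGRBond] = []
    for i, a in enumerate(cgr.atoms):
        if a.role != Role.LEAVING or a.depth != 1 or a.element != _CARBON:
            continue
        if i in flagged or detected(i):
            continue
        for j, c in enumerate(cgr.atoms):
            if c.role != Role.CENTER or c.element != _CARBON:
                continue
            if j in flagged or detected(j):
                continue
            if _atom_status(cgr, j) != "7":
                continue
            new_bonds.append(CGRBond(i, j, 0, 1))
    return new_bonds


def _flagged_atoms(cgr: CGR, r: MappedReaction) -> set[int]:
    """Atoms present in the given products as lone broken-bond fragments."""
    lone_maps = set()
    for mol in r.products:
        if mol.GetNumHeavyAtoms() == 1:
            atom = next(a for a in mol.GetAtoms() if a.GetAtomicNum() != 1)
            if atom.GetAtomMapNum() > 0:
                lone_maps.add(atom.GetAtomMapNum())
    out = set()
    for i, a in enumerate(cgr.atoms):
        if a.map_number in lone_maps and _atom_status(cgr, i) == "7":
            out.add(i)
    return out


def encode_and_rebalance(r: MappedReaction,
                         strip_spectators: bool = True
                         ) -> tuple[str, MappedReaction]:
    """(final ReactionCode, corrected balanced reaction) of ``r``.

    For a balanced reaction this is exactly ``encode``; the reaction is
    returned unchanged.  Otherwise the leaving fragments are re-homed as
    product molecules (with any deduced made bonds applied) and the
    corrected reaction is re-encoded; the returned code is final.
    """
    if strip_spectators:
        r = remove_spectators(r)
    cgr = build_cgr(r)
    if not any(a.role == Role.LEAVING for a in cgr.atoms):
        return encode(cgr), r

    product_maps = set()
    for mol in r.products:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum() > 0:
                product_maps.add(atom.GetAtomMapNum())

    flagged = _flagged_atoms(cgr, r)
    extra = deduce_missing_bonds(cgr, original_product_maps=product_maps,
                                 flagged_atoms=flagged)
    corrected, _ = cgr_to_reaction(
        cgr, include_leaving=True, extra_bonds=extra,
        map_numbers=[a.map_number for a in cgr.atoms])
    final_cgr = build_cgr(corrected)
    if any(a.role == Role.LEAVING for a in final_cgr.atoms):
        raise ReactionCodeError(
            "rebalancing failed to produce a balanced reaction")
    return encode(final_cgr), corrected
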