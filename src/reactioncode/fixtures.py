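"""Deterministic generator of mapped reactions with known ground truth.

Reactions are grown CGR-first: a reaction-center scaffold with planted bond
changes, remaining shells attached at controlled depths, an optional
leaving fragment hung off the center by a broken bond, then optional
charges, isotopes, radicals, stereo bond directions, an aromatic ring and
unmapped spectator molecules.  Because the CGR is the source, the planted
roles, depths, leaving atoms and spectators are recorded exactly
(:class:`GroundTruth`) and every module can be tested without external
data.  Chemical plausibility of the transformations is a non-goal; valence
feasibility is enforced so every fixture sanitizes.

All randomness flows from the ``seed`` argument; the same seed and request
always produce the same reaction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import networkx as nx
from rdkit import Chem

from .cgr import CGR, CGRAtom, CGRBond, Role, cgr_to_reaction
from .codec_tables import Stereo
from .errors import FixtureError
from .reaction_io import MappedReaction, read_reaction

_MAX_VALENCE = {6: 4, 7: 3, 8: 2, 9: 1, 14: 4, 15: 3, 16: 2, 17: 1, 35: 1}
_BACKBONE = [6, 6, 6, 6, 7, 8, 16, 14]  # C-heavy draw for skeleton atoms
_LEAVING = [6, 8, 17, 35]
_SPECTATORS = ["O", "CCO", "ClCCl", "C1CCOC1"]


@dataclass
class FixtureSpec:
    """Requested shape of a generated reaction."""

    center_size: int = 3
    remaining_depth: int = 2
    leaving_size: int = 0
    n_charges: int = 0
    n_isotopes: int = 0
    n_radicals: int = 0
    n_stereo_bonds: int = 0
    aromatic: bool = False
    spectators: int = 0
    #: None, "swapped_maps" (a wrong but element-consistent mapping, which
    #: the format transports faithfully) or "corrupt_mapping" (an
    #: element-inconsistent mapping, which refuses to encode)
    defect: str | None = None


@dataclass
class GroundTruth:
    roles: dict[int, Role]      # by map number
    depths: dict[int, int]      # by map number (leaving: letter depth)
    leaving_maps: set[int]
    spectator_count: int
    defect: str | None = None


class _Retry(Exception):
    pass


def make_reaction(seed: int, spec: FixtureSpec | None = None,
                  **kwargs) -> tuple[MappedReaction, GroundTruth]:
    """Generate one mapped reaction plus its ground truth."""
    spec = spec or FixtureSpec(**kwargs)
    if spec.center_size < 1:
        raise FixtureError("center_size must be >= 1")
    if spec.center_size == 1 and spec.leaving_size == 0:
        raise FixtureError("a single-atom center needs a leaving partner "
                           "to carry a bond change")
    for attempt in range(30):
        rng = random.Random(seed * 1009 + attempt)
        try:
            return _generate(rng, spec)
        except _Retry:
            continue
    raise FixtureError(f"could not realize {spec} (seed {seed})")


def _generate(rng: random.Random, spec: FixtureSpec):
    elements: list[int] = []
    depths: list[int] = []      # planted depth (letter depth for leaving)
    leaving: list[bool] = []
    bonds: list[list] = []      # [i, j, order_r, order_p]
    val_r: list[float] = []
    val_p: list[float] = []

    def add_atom(z, depth, is_leaving=False):
        elements.append(z)
        depths.append(depth)
        leaving.append(is_leaving)
        val_r.append(0.0)
        val_p.append(0.0)
        return len(elements) - 1

    def room(i, side, amount=1):
        v = val_r[i] if side == "r" else val_p[i]
        return v + amount <= _MAX_VALENCE[elements[i]]

    def add_bond(i, j, order_r, order_p):
        bonds.append([i, j, order_r, order_p])
        val_r[i] += 1.5 if order_r == 9 else order_r
        val_r[j] += 1.5 if order_r == 9 else order_r
        val_p[i] += 1.5 if order_p == 9 else order_p
        val_p[j] += 1.5 if order_p == 9 else order_p

    # --- reaction center scaffold ----------------------------------------
    for _ in range(spec.center_size):
        add_atom(rng.choice(_BACKBONE), 0)
    changed = [False] * spec.center_size
    for i in range(1, spec.center_size):
        parent = rng.randrange(i)
        kind = rng.choice(["made", "broken", "order", "kept", "kept"])
        if kind == "made" and room(i, "p") and room(parent, "p"):
            add_bond(parent, i, 0, 1)
            changed[parent] = changed[i] = True
        elif kind == "broken" and room(i, "r") and room(parent, "r"):
            add_bond(parent, i, 1, 0)
            changed[parent] = changed[i] = True
        elif (kind == "order" and room(i, "r") and room(parent, "r")
              and room(i, "p", 2) and room(parent, "p", 2)):
            add_bond(parent, i, 1, 2)
            changed[parent] = changed[i] = True
        else:
            if not (room(i, "r") and room(parent, "r")
                    and room(i, "p") and room(parent, "p")):
                raise _Retry
            add_bond(parent, i, 1, 1)

    # --- leaving fragment (letter depths; root broken off the center) -----
    leaving_ids = []
    for k in range(spec.leaving_size):
        z = rng.choice(_LEAVING if k == 0 or rng.random() < 0.5
                       else [6, 6, 8])
        if k == 0:
            anchors = [c for c in range(spec.center_size) if room(c, "r")]
            if not anchors:
                raise _Retry
            anchor = rng.choice(anchors)
            i = add_atom(z, 1, True)
            add_bond(anchor, i, 1, 0)
            changed[anchor] = True
        else:
            anchors = [a for a in leaving_ids
                       if room(a, "r")
                       and _MAX_VALENCE[elements[a]] > 1]
            if not anchors:
                raise _Retry
            anchor = rng.choice(anchors)
            if not room(anchor, "r") or _MAX_VALENCE[z] < 1:
                raise _Retry
            i = add_atom(z, depths[anchor] + 1, True)
            add_bond(anchor, i, 1, 1)
        leaving_ids.append(i)

    # every center atom must sit on a changed bond
    for c in range(spec.center_size):
        if changed[c]:
            continue
        fixed = False
        for b in bonds:
            if c in (b[0], b[1]) and b[2] == b[3] == 1:
                o = b[1] if b[0] == c else b[0]
                if depths[o] == 0 and not leaving[o]:
                    if room(c, "p") and room(o, "p"):
                        b[3] = 2
                        val_p[c] += 1
                        val_p[o] += 1
                    else:
                        b[3] = 0
                        val_p[c] -= 1
                        val_p[o] -= 1
                    changed[c] = changed[o] = True
                    fixed = True
                    break
        if not fixed:
            raise _Retry

    # --- remaining shells --------------------------------------------------
    shell_prev = list(range(spec.center_size))
    for depth in range(1, spec.remaining_depth + 1):
        count = rng.randint(1, 2)
        shell_now = []
        for _ in range(count):
            z = rng.choice(_BACKBONE)
            anchors = [a for a in shell_prev
                       if room(a, "r") and room(a, "p")]
            if not anchors:
                continue
            anchor = rng.choice(anchors)
            i = add_atom(z, depth)
            add_bond(anchor, i, 1, 1)
            shell_now.append(i)
        if not shell_now:
            break
        shell_prev = shell_now

    # --- aromatic ring -----------------------------------------------------
    if spec.aromatic:
        anchors = [i for i in range(len(elements))
                   if not leaving[i] and elements[i] == 6
                   and room(i, "r") and room(i, "p")]
        if not anchors:
            raise _Retry
        anchor = rng.choice(anchors)
        ring = [add_atom(6, depths[anchor] + 1) for _ in range(6)]
        add_bond(anchor, ring[0], 1, 1)
        for k in range(6):
            add_bond(ring[k], ring[(k + 1) % 6], 9, 9)

    # --- decorations --------------------------------------------------------
    kept = [i for i in range(len(elements)) if not leaving[i]]
    decorated: set[int] = set()

    def pick(pool):
        pool = [i for i in pool if i not in decorated]
        if not pool:
            raise _Retry
        i = rng.choice(pool)
        decorated.add(i)
        return i

    charges = [0] * len(elements)
    for _ in range(spec.n_charges):
        i = pick([k for k in kept
                  if (elements[k] == 7 and val_r[k] <= 3 and val_p[k] <= 3)
                  or (elements[k] == 8 and val_r[k] <= 1 and val_p[k] <= 1)])
        charges[i] = 1 if elements[i] == 7 else -1
    isotopes = [0] * len(elements)
    for _ in range(spec.n_isotopes):
        isotopes[pick(kept)] = rng.choice([1, 2])
    radicals = [0] * len(elements)
    for _ in range(spec.n_radicals):
        i = pick([k for k in kept if charges[k] == 0 and elements[k] == 6
                  and val_r[k] <= 3 and val_p[k] <= 3])
        radicals[i] = 1
    stereo = [Stereo.NONE] * len(bonds)
    if spec.n_stereo_bonds:
        singles = [k for k, b in enumerate(bonds) if b[2] == b[3] == 1]
        rng.shuffle(singles)
        for k in singles[:spec.n_stereo_bonds]:
            stereo[k] = rng.choice([Stereo.UP, Stereo.DOWN])
        if len(singles) < spec.n_stereo_bonds:
            raise _Retry

    # --- assemble the CGR ---------------------------------------------------
    n = len(elements)
    maps = list(range(1, n + 1))
    rng.shuffle(maps)
    atoms = []
    for i in range(n):
        atoms.append(CGRAtom(
            element=elements[i],
            role=(Role.LEAVING if leaving[i] else Role.REMAINING),
            depth=depths[i],
            charge_r=charges[i], charge_p=charges[i],
            isotope_r=isotopes[i], isotope_p=isotopes[i],
            radical_r=radicals[i], radical_p=radicals[i],
            map_number=maps[i]))
    cgr_bonds = []
    for k, (i, j, orr, orp) in enumerate(bonds):
        cgr_bonds.append(CGRBond(i, j, orr, orp,
                                 stereo_r=stereo[k], stereo_p=stereo[k]))
    center = {i for i in range(n)
              if not leaving[i]
              and any(i in (b.i, b.j) and b.order_r != b.order_p
                      for b in cgr_bonds)}
    for i in center:
        atoms[i].role = Role.CENTER
    cgr = CGR(atoms, cgr_bonds)

    # ground truth depths from an independent shortest-path oracle
    union = nx.Graph()
    react = nx.Graph()
    union.add_nodes_from(range(n))
    react.add_nodes_from(range(n))
    for b in cgr_bonds:
        union.add_edge(b.i, b.j)
        if b.order_r > 0:
            react.add_edge(b.i, b.j)
    du = nx.multi_source_dijkstra_path_length(union, center)
    dr = nx.multi_source_dijkstra_path_length(react, center)
    gt_depths = {}
    for i in range(n):
        d = dr[i] if leaving[i] else du[i]
        gt_depths[maps[i]] = int(d)
        atoms[i].depth = int(d)
        if d == 0:
            atoms[i].role = Role.CENTER
        elif not leaving[i]:
            atoms[i].role = (Role.CENTER if i in center else Role.REMAINING)

    try:
        reaction, failures = cgr_to_reaction(
            cgr, include_leaving=False, map_numbers=maps)
    except Exception:
        raise _Retry
    if failures:
        raise _Retry

    spectator_count = 0
    for _ in range(spec.spectators):
        mol = Chem.MolFromSmiles(rng.choice(_SPECTATORS))
        reaction.reactants.append(mol)
        spectator_count += 1

    defect = None
    if spec.defect == "swapped_maps":
        if not _swap_product_maps(reaction, rng, same_element=True):
            raise _Retry
        defect = "swapped_maps"
    elif spec.defect == "corrupt_mapping":
        if not _swap_product_maps(reaction, rng, same_element=False):
            raise _Retry
        defect = "corrupt_mapping"
    elif spec.defect is not None:
        raise FixtureError(f"unknown defect {spec.defect!r}")

    gt = GroundTruth(
        roles={maps[i]: atoms[i].role for i in range(n)},
        depths=gt_depths,
        leaving_maps={maps[i] for i in range(n) if leaving[i]},
        spectator_count=spectator_count,
        defect=defect)
    if defect != "corrupt_mapping":
        try:
            reaction.validate()
        except Exception:
            raise _Retry
    return reaction, gt


def _swap_product_maps(reaction: MappedReaction, rng: random.Random,
                       same_element: bool) -> bool:
    """Swap two product-atom maps (same element + different degree, or
    different elements for a corrupt, refuses-to-encode mapping)."""
    candidates = []
    for mol in reaction.products:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum() > 0:
                candidates.append(atom)
    rng.shuffle(candidates)
    for a in range(len(candidates)):
        for b in range(a + 1, len(candidates)):
            aa, ba = candidates[a], candidates[b]
            if same_element:
                good = (aa.GetAtomicNum() == ba.GetAtomicNum()
                        and aa.GetDegree() != ba.GetDegree())
            else:
                good = aa.GetAtomicNum() != ba.GetAtomicNum()
            if good:
                na, nb = aa.GetAtomMapNum(), ba.GetAtomMapNum()
                aa.SetAtomMapNum(nb)
                ba.SetAtomMapNum(na)
                return True
    return False


def perturb_atom_order(r: MappedReaction, seed: int) -> MappedReaction:
    """Isomorphic copy with shuffled atom and molecule order."""
    rng = random.Random(seed)

    def shuffle_mol(mol):
        perm = list(range(mol.GetNumAtoms()))
        rng.shuffle(perm)
        return Chem.RenumberAtoms(mol, perm)

    out = MappedReaction(
        [shuffle_mol(m) for m in r.reactants],
        [shuffle_mol(m) for m in r.agents],
        [shuffle_mol(m) for m in r.products],
        dict(r.properties))
    rng.shuffle(out.reactants)
    rng.shuffle(out.products)
    return out


def fixture_corpus(seed: int, n: int,
                   spec: FixtureSpec | None = None, **kwargs):
    """List of ``n`` (reaction, ground truth) pairs from consecutive seeds."""
    spec = spec or FixtureSpec(**kwargs)
    return [make_reaction(seed + k, spec) for k in range(n)]


# ---------------------------------------------------------------------------
# worked examples

_EXAMPLES = {
    # Si carrying 2 unchanged, 1 broken and 1 made single bond (code "90E")
    "silicon_substitution":
        "[CH3:2][SiH:1]([CH3:3])[Cl:4].[OH2:5]"
        ">>[CH3:2][SiH:1]([CH3:3])[OH:5]",
    # alkoxide bystander: remaining-layer oxygen with charge -1 both sides
    "charged_alkoxide":
        "[CH3:4][CH:1]([O-:3])[Br:2].[OH2:5]>>[CH3:4][CH:1]([O-:3])[OH:5]",
    # 18-O (+2 neutrons) and 11-C (-1) bystanders
    "isotopic_substitution":
        "[11CH3:4][CH:1]([18OH:3])[Br:2].[OH2:5]"
        ">>[11CH3:4][CH:1]([18OH:3])[OH:5]",
    # methylene radical count growing from 1 to 2
    "radical_growth":
        "[CH2:4][CH2:1][Br:2].[OH2:5]>>[CH:4][CH2:1][OH:5]",
    # trans-alkene dibromination: /s content plus an order change
    "stereo_addition":
        "[CH3:1]/[CH:2]=[CH:3]/[CH3:4].[Br:5][Br:6]"
        ">>[CH3:1][CH:2]([Br:5])[CH:3]([Br:6])[CH3:4]",
    # fully unbalanced: the bromide is simply missing from the products
    "fully_unbalanced": "[CH3:1][Br:2]>>[CH4:1]",
    # partially balanced: lone chloride present, methoxide fragment missing
    "partially_balanced":
        "[Cl:3][C:1]([CH3:4])([CH3:5])[O:2][CH3:6]"
        ">>[CH2:1]([CH3:4])[CH3:5].[ClH:3]",
}


def worked_examples() -> dict[str, MappedReaction]:
    """Small named collection of hand-built archetype reactions."""
    return {name: read_reaction(smi, "reaction-smiles")
            for name, smi in _EXAMPLES.items()}
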