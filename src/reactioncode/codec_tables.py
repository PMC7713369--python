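"""Character alphabets of the ReactionCode format.

Every table here is the single source of truth shared by the encoder, the
decoder and the documentation emitter.  All mappings are injective and
round-trip exactly; the anchored values below are fixed:

* element codes are the 2-digit uppercase hexadecimal of the atomic number
  (Si = 14 -> "0E", O = 8 -> "08");
* bond status: unchanged -> '0', broken -> '7', made -> '9'; an order change
  between two non-zero orders uses the intermediate digit '5', so the total
  order of statuses is '0' < '5' < '7' < '9';
* bond orders: absent '0', single '1', double '2', triple '3', aromatic '9';
* signed offsets (shared by the charge, isotope and radical sub-layers):
  letters around the pivot H = -1 / I = +1 (J = +2, G = -2, ... A = -8,
  P = +8); the zero/default state is the digit '0';
* stereo descriptors: bond DOWN -> '4', UP -> '6'; the remaining descriptors
  (tetrahedral CW/CCW, cis/trans) take distinct digits documented below.

Atom *indices* use two disjoint alphabets so a bond partner reference is
self-describing: atoms of the numeric block (reaction center + remaining
group) use base-16 over "GHIJKLMNOPQRSTUV" (G = 0 ... V = 15, two characters,
so "GG" is the first atom), while atoms of the letter block (leaving group)
use plain 2-digit hexadecimal.  Both alphabets address up to 256 atoms.
"""

from __future__ import annotations

import enum

# ---------------------------------------------------------------------------
# bond orders

AROMATIC_ORDER = 9  #: sentinel integer used for aromatic bonds throughout

_ORDER_TO_CHAR = {0: "0", 1: "1", 2: "2", 3: "3", AROMATIC_ORDER: "9"}
_CHAR_TO_ORDER = {v: k for k, v in _ORDER_TO_CHAR.items()}


def bond_order_char(order: int) -> str:
    """Character for a bond order (0 = absent, 9 = aromatic)."""
    try:
        return _ORDER_TO_CHAR[order]
    except KeyError:
        raise ValueError(f"unsupported bond order {order!r}") from None


def bond_order_value(char: str) -> int:
    try:
        return _CHAR_TO_ORDER[char]
    except KeyError:
        raise ValueError(f"unsupported bond-order character {char!r}") from None


# ---------------------------------------------------------------------------
# bond change status

#: total order of the status characters, lowest (no change) to highest (made)
STATUS_RANK = {"0": 0, "5": 1, "7": 2, "9": 3}


def bond_status(order_r: int, order_p: int) -> str:
    """Status digit of a CGR bond from its (reactant, product) orders.

    Unchanged bonds are '0'; a bond broken (absent in products) is '7'; a
    bond made (absent in reactants) is '9', the highest status; a change
    between two non-zero orders is '5'.
    """
    if order_r == 0 and order_p == 0:
        raise ValueError("a CGR bond must exist on at least one side")
    if order_r == order_p:
        return "0"
    if order_p == 0:
        return "7"
    if order_r == 0:
        return "9"
    return "5"


# ---------------------------------------------------------------------------
# element codes

_MAX_Z = 118


def element_code(z: int) -> str:
    """2-character uppercase hexadecimal code of atomic number ``z``."""
    if not 1 <= z <= _MAX_Z:
        raise ValueError(f"atomic number {z} outside 1..{_MAX_Z}")
    return f"{z:02X}"


def element_number(code: str) -> int:
    try:
        z = int(code, 16)
    except ValueError:
        raise ValueError(f"invalid element code {code!r}") from None
    if not 1 <= z <= _MAX_Z:
        raise ValueError(f"element code {code!r} outside 1..{_MAX_Z}")
    return z


# ---------------------------------------------------------------------------
# atom index alphabets

#: base-16 alphabet of the numeric block (reaction center + remaining group)
MAIN_INDEX_ALPHABET = "GHIJKLMNOPQRSTUV"
#: plain hexadecimal alphabet of the letter block (leaving group)
LEAVING_INDEX_ALPHABET = "0123456789ABCDEF"

_MAIN_VAL = {c: i for i, c in enumerate(MAIN_INDEX_ALPHABET)}
_LEAVING_VAL = {c: i for i, c in enumerate(LEAVING_INDEX_ALPHABET)}

INDEX_CAPACITY = 256  #: per block; two characters in a base-16 alphabet


def main_index_code(i: int) -> str:
    """Reference code of the ``i``-th atom of the numeric block ("GG" = 0)."""
    if not 0 <= i < INDEX_CAPACITY:
        raise ValueError(f"main-block index {i} outside 0..{INDEX_CAPACITY - 1}")
    return MAIN_INDEX_ALPHABET[i // 16] + MAIN_INDEX_ALPHABET[i % 16]


def leaving_index_code(i: int) -> str:
    """Reference code of the ``i``-th atom of the letter block ("00" = 0)."""
    if not 0 <= i < INDEX_CAPACITY:
        raise ValueError(f"leaving-block index {i} outside 0..{INDEX_CAPACITY - 1}")
    return f"{i:02X}"


def decode_index(code: str) -> tuple[str, int]:
    """Invert a 2-character partner reference.

    Returns ``("main", i)`` or ``("leaving", i)``; the two alphabets are
    disjoint so the block is recovered from the characters alone.
    """
    if len(code) != 2:
        raise ValueError(f"index code {code!r} must have 2 characters")
    a, b = code
    if a in _MAIN_VAL and b in _MAIN_VAL:
        return "main", _MAIN_VAL[a] * 16 + _MAIN_VAL[b]
    if a in _LEAVING_VAL and b in _LEAVING_VAL:
        return "leaving", _LEAVING_VAL[a] * 16 + _LEAVING_VAL[b]
    raise ValueError(f"index code {code!r} mixes alphabets or is invalid")


# ---------------------------------------------------------------------------
# signed offsets (charge, isotope mass delta, radical count)

OFFSET_RANGE = 8  #: |delta| <= 8
OFFSET_ZERO_CHAR = "0"  #: default / zero state


def offset_char(delta: int) -> str:
    """Letter for a signed offset; H = -1, I = +1, J = +2, G = -2 ... '0' = 0."""
    if delta == 0:
        return OFFSET_ZERO_CHAR
    if not -OFFSET_RANGE <= delta <= OFFSET_RANGE:
        raise ValueError(f"offset {delta} outside +/-{OFFSET_RANGE}")
    if delta > 0:
        return chr(ord("H") + delta)
    return chr(ord("H") + 1 + delta)


def offset_value(char: str) -> int:
    if char == OFFSET_ZERO_CHAR:
        return 0
    v = ord(char) - ord("H")
    if 1 <= v <= OFFSET_RANGE:
        return v
    v -= 1
    if -OFFSET_RANGE <= v <= -1:
        return v
    raise ValueError(f"invalid offset character {char!r}")


# ---------------------------------------------------------------------------
# stereo descriptors


class Stereo(enum.Enum):
    """Stereo descriptors carried by the /s sub-layer.

    ``DOWN``/``UP`` are wedge-style bond directions; ``CIS``/``TRANS``
    qualify double bonds; ``CW``/``CCW`` are tetrahedral atom parities.
    """

    NONE = "0"
    CW = "1"
    CCW = "2"
    CIS = "3"
    DOWN = "4"
    TRANS = "5"
    UP = "6"


_STEREO_BY_CHAR = {s.value: s for s in Stereo}


def stereo_char(descriptor: Stereo) -> str:
    if not isinstance(descriptor, Stereo):
        raise ValueError(f"unsupported stereo descriptor {descriptor!r}")
    return descriptor.value


def stereo_value(char: str) -> Stereo:
    try:
        return _STEREO_BY_CHAR[char]
    except KeyError:
        raise ValueError(f"invalid stereo character {char!r}") from None


# ---------------------------------------------------------------------------
# reference document


def reference_markdown() -> str:
    """Human-readable dump of every alphabet, for auditing."""
    lines = [
        "# ReactionCode character tables",
        "",
        "## Bond orders (reactant/product characters of a bond entry)",
        "",
        "| order | char |",
        "|---|---|",
    ]
    for order, ch in sorted(_ORDER_TO_CHAR.items()):
        name = {0: "absent", 1: "single", 2: "double", 3: "triple",
                AROMATIC_ORDER: "aromatic"}[order]
        lines.append(f"| {name} | `{ch}` |")
    lines += [
        "",
        "## Bond change status (first character of an atom code)",
        "",
        "| change | char |",
        "|---|---|",
        "| unchanged | `0` |",
        "| order change | `5` |",
        "| broken | `7` |",
        "| made | `9` |",
        "",
        "Ordering: `0` < `5` < `7` < `9`; an atom code carries the highest",
        "status among its incident bonds.",
        "",
        "## Element codes",
        "",
        "2-digit uppercase hexadecimal of the atomic number",
        "(H=`01`, C=`06`, O=`08`, Si=`0E`, ...).",
        "",
        "## Atom index alphabets",
        "",
        f"* numeric block (center + remaining): base-16 over `{MAIN_INDEX_ALPHABET}`,",
        "  two characters; `GG` = index 0.",
        "* letter block (leaving group): 2-digit hexadecimal; `00` = index 0.",
        "",
        "The alphabets are disjoint, so a partner reference identifies its",
        "block by itself.",
        "",
        "## Signed offsets (/c charge, /i isotope mass delta, /r radical count)",
        "",
        "| delta | char |",
        "|---|---|",
    ]
    for d in range(-OFFSET_RANGE, OFFSET_RANGE + 1):
        lines.append(f"| {d:+d} | `{offset_char(d)}` |" if d else "| 0 | `0` |")
    lines += [
        "",
        "## Stereo descriptors (/s)",
        "",
        "| descriptor | char |",
        "|---|---|",
    ]
    for s in Stereo:
        lines.append(f"| {s.name} | `{s.value}` |")
    lines.append("")
    return "\n".join(lines)
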