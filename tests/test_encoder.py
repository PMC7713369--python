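"""Canonical encoding: structure, invariance, tie-breaking, prefix logic."""

import itertools
import math

import pytest

import reactioncode as rc
from reactioncode.cgr import Role, build_cgr
from reactioncode.encoder import _Encoder, layer_plan
from reactioncode.errors import EmptyReactionCenterError


class TestStructure:
    def test_code_starts_with_depth_zero_layer(self, mixed_corpus):
        for r, _ in mixed_corpus[:20]:
            code = rc.encode_reaction(r)
            assert code.startswith("0:")
            assert code.endswith("|")

    def test_unbalanced_code_has_letter_layers(self):
        r, _ = rc.make_reaction(3, center_size=2, remaining_depth=0,
                                leaving_size=1)
        code = rc.encode_reaction(r)
        assert "|A:" in code

    def test_balanced_code_has_no_letter_layers(self):
        r, _ = rc.make_reaction(3, center_size=2, remaining_depth=2,
                                leaving_size=0)
        assert "A:" not in rc.encode_reaction(r)

    def test_connection_tables_reference_lower_indices_only(self):
        """Reserializing the parse reproduces the code, and every bond ref
        resolves to an atom already emitted (the parser enforces it)."""
        for seed in range(10):
            r, _ = rc.make_reaction(seed, center_size=3, remaining_depth=2,
                                    leaving_size=2)
            code = rc.encode_reaction(r)
            assert rc.parse(code).serialize() == code

    def test_empty_center_is_an_error(self):
        r = rc.read_reaction("[CH4:1]>>[CH4:1]")
        with pytest.raises(EmptyReactionCenterError):
            rc.encode_reaction(r, strip_spectators=False)


class TestCanonicality:
    def test_invariant_under_atom_order_permutation(self, mixed_corpus):
        for r, _ in mixed_corpus[:40]:
            code = rc.encode_reaction(r)
            for k in range(5):
                p = rc.perturb_atom_order(r, 31 * k + 7)
                assert rc.encode_reaction(p) == code

    def test_symmetric_shell_is_order_insensitive(self):
        # a benzene ring in the remaining shells: fully symmetric atoms may
        # tie in any order without affecting the string
        r, _ = rc.make_reaction(11, center_size=2, remaining_depth=1,
                                leaving_size=0, aromatic=True)
        code = rc.encode_reaction(r)
        for k in range(20):
            assert rc.encode_reaction(rc.perturb_atom_order(r, k)) == code

    def test_charge_breaks_a_tie_deterministically(self):
        # two otherwise identical methyls; one on a charged nitrogen path
        smi = ("[CH3:1][C:2]([CH3:3])([NH3+:4])[Cl:5].[OH2:6]"
               ">>[CH3:1][C:2]([CH3:3])([NH3+:4])[OH:6]")
        r = rc.read_reaction(smi)
        code = rc.encode_reaction(r)
        for k in range(10):
            assert rc.encode_reaction(rc.perturb_atom_order(r, k)) == code


class TestBruteForceOracle:
    def oracle(self, cgr, cap=40_000):
        enc = _Encoder(cgr)
        if math.prod(math.factorial(len(a))
                     for _, _, a in enc.layers) > cap:
            return None
        best = None
        for perms in itertools.product(
                *[itertools.permutations(a) for _, _, a in enc.layers]):
            s = enc.serialize_with_order([list(p) for p in perms])
            if best is None or s > best:
                best = s
        return best

    def test_encoder_is_lexicographic_maximum(self):
        """The canonical code equals the maximum serialization over every
        layer-respecting ordering, brute-forced for small instances."""
        tested = 0
        for seed in range(120):
            r, _ = rc.make_reaction(
                seed, center_size=2, remaining_depth=1,
                leaving_size=seed % 3, n_charges=seed % 2)
            g = build_cgr(rc.remove_spectators(r))
            if len(g.atoms) > 8:
                continue
            want = self.oracle(g)
            if want is None:
                continue
            tested += 1
            assert rc.encode(g) == want
        assert tested >= 50


class TestPrefixStability:
    def test_layers_depend_only_on_shallower_layers(self, mixed_corpus):
        """Dropping every layer deeper than k and re-encoding reproduces
        layers 0..k byte-identically (atom statuses travel with the doc)."""
        from reactioncode.decoder import doc_to_cgr
        for r, _ in mixed_corpus[:20]:
            full = rc.encode_reaction(r)
            doc = rc.parse(full)
            cgr, membership = doc_to_cgr(doc)
            chunks = full.split("|")[:-1]
            for cut in range(1, len(doc.layers) + 1):
                keep = {gid for layer in doc.layers[:cut]
                        for gid in membership[layer.id]}
                sub = cgr.subgraph(keep)
                assert rc.encode(sub) == "|".join(chunks[:cut]) + "|"


def test_stoichiometry_bracket_roundtrips():
    r = rc.read_reaction("[CH3:1][Cl:2].[OH2:3]>>[CH3:1][OH:3]")
    g = build_cgr(r)
    g.atoms[0].multiplicity = 2
    code = rc.encode(g)
    assert "[2]" in code
    doc = rc.parse(code)
    assert doc.serialize() == code
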