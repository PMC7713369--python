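"""Parsing exactness, decode semantics and partial decoding."""

import pytest

import reactioncode as rc
from reactioncode.decoder import DecodeOptions, doc_to_cgr
from reactioncode.errors import ParseError


class TestParse:
    def test_serialize_is_byte_identical(self, mixed_corpus):
        for r, _ in mixed_corpus[:40]:
            code = rc.encode_reaction(r)
            assert rc.parse(code).serialize() == code

    def test_whitespace_is_normalized(self):
        code = rc.encode_reaction(
            rc.read_reaction("[CH3:1][Br:2].[OH2:3]>>[CH3:1][OH:3]"))
        spaced = code.replace("|", "|\n ")
        assert rc.parse(spaced).serialize() == code

    @pytest.mark.parametrize("bad,match", [
        ("0:|", "empty reaction center"),
        ("0:906()", "not terminated"),
        ("0:906()/x0000|", "unknown sub-layer"),
        ("0:906()/c000|", "multiple of 4"),
        ("0:9zz()|", "element code"),
        ("0:906(11ZZ)|", "index code"),
        ("0:906(1)|", "truncated bond entry"),
        ("1:906()|", "depth-0"),
        ("0:906(11GG)|", "dangling partner"),
        ("junk", "expected ':'"),
    ])
    def test_malformed_codes_report_position(self, bad, match):
        with pytest.raises(ParseError, match=match):
            doc = rc.parse(bad)
            doc_to_cgr(doc)  # referential errors surface here

    def test_sublayer_order_is_accepted_in_any_order(self):
        # emitter order is /c,/s,/i,/r; the parser accepts any order
        a = rc.parse("0:906()708(10GG)/i00II/c00HH|")
        b = rc.parse("0:906()708(10GG)/c00HH/i00II|")
        ca, _ = doc_to_cgr(a)
        cb, _ = doc_to_cgr(b)
        assert ca.atoms[0].charge_r == cb.atoms[0].charge_r == -1
        assert ca.atoms[0].isotope_r == cb.atoms[0].isotope_r == 1


class TestDecode:
    def test_idempotence_on_balanced_reactions(self):
        for seed in range(40):
            r, _ = rc.make_reaction(seed, center_size=2 + seed % 3,
                                    remaining_depth=1 + seed % 2,
                                    leaving_size=0, n_charges=seed % 2)
            code = rc.encode_reaction(r)
            assert rc.encode_reaction(rc.decode_code(code)) == code

    def test_balanced_decode_regenerates_leaving_fragment(self):
        r = rc.read_reaction("[CH3:1][Br:2].[OH2:3]>>[CH3:1][OH:3]")
        dec = rc.decode_code(rc.encode_reaction(r))
        assert len(dec.products) == 2  # methanol + regenerated HBr

    def test_include_leaving_false_regenerates_unbalanced(self):
        for seed in range(10):
            r, gt = rc.make_reaction(seed, center_size=2, remaining_depth=1,
                                     leaving_size=2)
            dec = rc.decode_code(rc.encode_reaction(r),
                                 DecodeOptions(include_leaving=False))
            assert rc.roundtrip_similar(rc.remove_spectators(r), dec)
            n_dec = sum(m.GetNumHeavyAtoms() for m in dec.products)
            n_org = sum(m.GetNumHeavyAtoms() for m in r.products)
            assert n_dec == n_org  # planted leaving group stays out

    def test_partial_decode_is_monotonic(self):
        r, _ = rc.make_reaction(17, center_size=2, remaining_depth=3,
                                leaving_size=2)
        doc = rc.parse(rc.encode_reaction(r))
        ids = doc.layer_ids()
        prev = 0
        for k in range(1, len(ids) + 1):
            wanted = set(ids[:k])
            try:
                rc.decoder._check_downward_closed(doc, wanted)
            except ValueError:
                continue
            dec = rc.decode(doc, DecodeOptions(layers=wanted))
            n = sum(m.GetNumHeavyAtoms() for m in dec.reactants)
            assert n >= prev
            prev = n

    def test_layer_zero_only_contains_center_atoms(self):
        r, gt = rc.make_reaction(23, center_size=3, remaining_depth=2,
                                 leaving_size=1)
        doc = rc.parse(rc.encode_reaction(r))
        dec = rc.decode(doc, DecodeOptions(layers={"0"}))
        n_center = sum(1 for role in gt.roles.values()
                       if role == rc.Role.CENTER)
        assert sum(m.GetNumHeavyAtoms() for m in dec.reactants) == n_center

    def test_layer_zero_reencodes_to_the_same_depth0_layer(self,
                                                           mixed_corpus):
        for r, _ in mixed_corpus[:20]:
            code = rc.encode_reaction(r)
            doc = rc.parse(code)
            cgr, membership = doc_to_cgr(doc)
            sub = cgr.subgraph(set(membership["0"]))
            assert rc.encode(sub) == code.split("|")[0] + "|"

    def test_non_downward_closed_filter_rejected(self):
        r, _ = rc.make_reaction(17, center_size=2, remaining_depth=2,
                                leaving_size=0)
        doc = rc.parse(rc.encode_reaction(r))
        with pytest.raises(ValueError, match="downward-closed"):
            rc.decode(doc, DecodeOptions(layers={"0", "2"}))

    def test_fresh_consecutive_map_numbers(self):
        r, _ = rc.make_reaction(5, center_size=2, remaining_depth=1,
                                leaving_size=1)
        dec = rc.decode_code(rc.encode_reaction(r))
        maps = sorted(a.GetAtomMapNum()
                      for m in dec.reactants for a in m.GetAtoms())
        assert maps == list(range(1, len(maps) + 1))


class TestStateRoundTrip:
    def test_charges_isotopes_radicals_stereo_survive(self):
        r, _ = rc.make_reaction(8, center_size=2, remaining_depth=2,
                                leaving_size=0, n_charges=1, n_isotopes=1,
                                n_radicals=1, n_stereo_bonds=1)
        code = rc.encode_reaction(r)
        assert "/c" in code and "/i" in code and "/r" in code \
            and "/s" in code
        assert rc.encode_reaction(rc.decode_code(code)) == code

    def test_aromatic_ring_kekulizes_on_decode(self):
        r, _ = rc.make_reaction(4, center_size=2, remaining_depth=1,
                                leaving_size=0, aromatic=True)
        code = rc.encode_reaction(r)
        assert "99" in code  # aromatic bond entries
        dec = rc.decode_code(code)
        assert dec.properties["kekulization_failures"] == "0"
        assert rc.roundtrip_similar(rc.remove_spectators(r), dec)
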