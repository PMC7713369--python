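"""Reading/writing mapped reactions and spectator removal."""

import pytest
from rdkit import Chem

import reactioncode as rc
from reactioncode.errors import MappingError, ParseError


def triples(r):
    return sorted(
        (a.GetAtomicNum(), a.GetAtomMapNum(), a.GetFormalCharge())
        for m in r.reactants + r.products for a in m.GetAtoms())


class TestReadWrite:
    def test_minimal_mapped_reaction(self):
        r = rc.read_reaction("[CH4:1]>>[CH3:1]Cl")
        assert len(r.reactants) == 1 and len(r.products) == 1
        assert r.reactants[0].GetAtomWithIdx(0).GetAtomMapNum() == 1

    def test_agent_component_is_flagged(self):
        r = rc.read_reaction("[CH4:1]>O>[CH4:1]")
        assert len(r.agents) == 1
        out = rc.write_reaction(r)
        assert out.split(">")[1] == "O"

    def test_rxn_preserves_molecule_counts(self):
        r = rc.read_reaction("[CH4:1].[OH2:2]>>[CH3:1][OH:2]")
        block = rc.write_reaction(r, "rxn")
        back = rc.read_reaction(block, "rxn")
        assert len(back.reactants) == 2 and len(back.products) == 1

    def test_v3000_is_rejected(self):
        with pytest.raises(ParseError, match="V3000"):
            rc.read_reaction("$RXN\n\n\n\nV3000 somewhere\n", "rxn")

    def test_rdf_stream_with_data_fields(self):
        r1 = rc.read_reaction("[CH4:1]>>[CH4:1]")
        r1.properties["rxn_id"] = "a1"
        r2 = rc.read_reaction("[CH3:1][Br:2].[OH2:3]>>[CH3:1][OH:3]")
        text = rc.write_reactions([r1, r2], "rdf")
        back = list(rc.read_reactions(text, "rdf"))
        assert len(back) == 2
        assert back[0].properties["rxn_id"] == "a1"
        assert triples(back[1]) == triples(r2)

    def test_empty_product_side(self):
        r = rc.read_reaction("[CH4:1]>>")
        assert r.products == []
        assert rc.write_reaction(r).endswith(">")

    def test_bad_smiles_reports_component(self):
        with pytest.raises(ParseError, match="reactant"):
            rc.read_reaction("C(Q>>C")

    @pytest.mark.parametrize("fmt", ["reaction-smiles", "rxn", "rdf"])
    def test_roundtrip_preserves_atom_triples(self, fmt, mixed_corpus):
        for r, _ in mixed_corpus[:25]:
            back = rc.read_reaction(rc.write_reaction(r, fmt), fmt)
            assert triples(back) == triples(r)


class TestValidate:
    def test_duplicate_map_rejected(self):
        r = rc.read_reaction("[CH4:1].[CH4:1]>>[CH4:1]")
        with pytest.raises(MappingError, match="duplicated"):
            r.validate()

    def test_element_mismatch_rejected(self):
        r = rc.read_reaction("[CH4:1]>>[OH2:1]")
        with pytest.raises(MappingError):
            r.validate()


class TestRemoveSpectators:
    def test_unmapped_solvent_removed(self):
        r = rc.read_reaction("[CH3:1][Br:2].O>>[CH3:1][OH:3]")
        # note: the hydroxide oxygen must come from somewhere; keep the
        # mapped water so only the unmapped solvent is a spectator
        r2 = rc.remove_spectators(r)
        assert len(r2.reactants) == 1

    def test_agents_dropped(self):
        r = rc.read_reaction("[CH4:1]>[Pd]>[CH4:1]")
        assert rc.remove_spectators(r).agents == []

    def test_unchanged_mapped_pair_dropped(self):
        r = rc.read_reaction(
            "[CH3:1][Br:2].[CH4:9]>>[CH3:1]Cl.[CH4:9]")
        r2 = rc.remove_spectators(r)
        assert len(r2.reactants) == 1 and len(r2.products) == 1

    def test_planted_spectators_drop_exactly(self):
        for seed in range(5):
            r, gt = rc.make_reaction(seed, center_size=2, remaining_depth=1,
                                     leaving_size=0, spectators=3)
            r2 = rc.remove_spectators(r)
            assert len(r.reactants) - len(r2.reactants) == 3
            assert gt.spectator_count == 3

    def test_idempotent(self, mixed_corpus):
        for r, _ in mixed_corpus[:20]:
            once = rc.remove_spectators(r)
            twice = rc.remove_spectators(once)
            assert triples(once) == triples(twice)

    def test_all_spectators_yields_empty_reaction(self):
        r = rc.read_reaction("O.CC>>")
        r2 = rc.remove_spectators(r)
        assert r2.reactants == [] and r2.products == []
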