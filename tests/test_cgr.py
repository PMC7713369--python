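"""Role classification, depth assignment and pseudo-molecule export."""

import networkx as nx
import pytest

import reactioncode as rc
from reactioncode.cgr import Role, build_cgr, classify_roles
from reactioncode.errors import EmptyReactionCenterError, MappingError


class TestClassifyRoles:
    def test_substitution_roles(self):
        r = rc.read_reaction("[CH3:1][Cl:2].[OH2:3]>>[CH3:1][OH:3]")
        roles = classify_roles(r)[0]
        assert roles[1] == Role.CENTER      # carbon: broken + made bond
        assert roles[2] == Role.LEAVING     # chlorine vanishes
        assert roles[3] == Role.CENTER      # oxygen gains a bond

    def test_charge_flip_alone_is_not_a_center(self):
        r = rc.read_reaction("[CH3:1][O-:2]>>[CH3:1][OH:2]")
        roles = classify_roles(r)[0]
        assert all(role != Role.CENTER for role in roles.values())
        with pytest.raises(EmptyReactionCenterError):
            build_cgr(r)

    def test_condensation_roles(self):
        # ester-style condensation: carbonyl C loses OH, gains OR
        r = rc.read_reaction(
            "[CH3:1][C:2](=[O:3])[OH:4].[OH:5][CH3:6]"
            ">>[CH3:1][C:2](=[O:3])[O:5][CH3:6]")
        roles = classify_roles(r)[0]
        assert roles[2] == Role.CENTER and roles[5] == Role.CENTER
        assert roles[4] == Role.LEAVING
        assert roles[1] == Role.REMAINING and roles[3] == Role.REMAINING

    def test_unmapped_heavy_atom_rejected(self):
        r = rc.read_reaction("[CH3:1]C>>[CH4:1]")
        with pytest.raises(MappingError, match="unmapped heavy atom"):
            classify_roles(r)

    def test_ground_truth_roles_match(self, mixed_corpus):
        for r, gt in mixed_corpus[:30]:
            roles = classify_roles(rc.remove_spectators(r))[0]
            assert roles == gt.roles


class TestBuildCgr:
    def test_balanced_reaction_has_no_leaving_atoms(self):
        r, _ = rc.make_reaction(5, center_size=3, remaining_depth=2,
                                leaving_size=0)
        g = build_cgr(r)
        n_products = sum(m.GetNumAtoms() for m in r.products)
        assert all(a.role != Role.LEAVING for a in g.atoms)
        assert len(g.atoms) == n_products

    def test_letter_and_numeric_shells_both_present(self):
        r, _ = rc.make_reaction(5, center_size=2, remaining_depth=1,
                                leaving_size=2)
        g = build_cgr(r)
        assert any(a.role == Role.LEAVING and a.depth == 1 for a in g.atoms)
        assert any(a.role == Role.REMAINING and a.depth == 1
                   for a in g.atoms)

    def test_atom_conservation(self, mixed_corpus):
        for r, gt in mixed_corpus[:30]:
            g = build_cgr(rc.remove_spectators(r))
            n_reactant = sum(m.GetNumAtoms()
                             for m in rc.remove_spectators(r).reactants)
            assert len(g.atoms) == n_reactant

    def test_depths_match_shortest_path_oracle(self, mixed_corpus):
        """Depth = multi-source BFS distance from the center, union graph
        for kept atoms and reactant graph for leaving atoms."""
        for r, gt in mixed_corpus[:50]:
            g = build_cgr(rc.remove_spectators(r))
            union, react = nx.Graph(), nx.Graph()
            union.add_nodes_from(range(len(g.atoms)))
            react.add_nodes_from(range(len(g.atoms)))
            for b in g.bonds:
                union.add_edge(b.i, b.j)
                if b.order_r > 0:
                    react.add_edge(b.i, b.j)
            centers = {i for i, a in enumerate(g.atoms)
                       if a.role == Role.CENTER}
            du = nx.multi_source_dijkstra_path_length(union, centers)
            dr = nx.multi_source_dijkstra_path_length(react, centers)
            for i, a in enumerate(g.atoms):
                want = dr[i] if a.role == Role.LEAVING else du[i]
                assert a.depth == want

    def test_role_depth_consistency(self, mixed_corpus):
        for r, _ in mixed_corpus[:30]:
            g = build_cgr(rc.remove_spectators(r))
            for a in g.atoms:
                assert (a.role == Role.CENTER) == (a.depth == 0) or \
                    a.role == Role.LEAVING


class TestPseudoMolecule:
    def test_sdf_record_roundtrip(self, mixed_corpus):
        for r, _ in mixed_corpus[:15]:
            g = build_cgr(rc.remove_spectators(r))
            g2 = rc.import_pseudo_molecule(rc.export_pseudo_molecule(g))
            assert rc.encode(g) == rc.encode(g2)

    def test_broken_bond_is_recorded(self):
        r = rc.read_reaction("[CH3:1][Cl:2].[OH2:3]>>[CH3:1][OH:3]")
        rec = rc.export_pseudo_molecule(build_cgr(r))
        g2 = rc.import_pseudo_molecule(rec)
        assert sum(1 for b in g2.bonds
                   if b.order_r == 1 and b.order_p == 0) == 1

    def test_atom_count_preserved(self):
        r, _ = rc.make_reaction(9, center_size=2, remaining_depth=2,
                                leaving_size=0)
        g = build_cgr(r)
        assert rc.pseudo_smiles(g).count("[") == len(g.atoms)
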