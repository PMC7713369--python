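"""Diversity tables and the round-trip validation harness."""

import pytest

import reactioncode as rc
from reactioncode.analysis import diversity_tables, layer_prefix


class TestDiversity:
    def test_identical_codes_collapse_to_one_row(self):
        r, _ = rc.make_reaction(1, center_size=2, remaining_depth=2,
                                leaving_size=0)
        code = rc.encode_reaction(r)
        res = diversity_tables([code] * 10, max_depth=4)
        for d in range(5):
            assert len(res.tables[d]) == 1
            assert int(res.tables[d].occurrences.iloc[0]) == 10

    def test_planted_prefix_collisions_are_counted(self):
        # same center, different shells: depth-0 collides, deeper splits
        base = "0:906()706(10GG)|"
        codes = [base + "1:006(11GH)|", base + "1:008(11GH)|", base]
        res = diversity_tables(codes, max_depth=1)
        assert len(res.tables[0]) == 1
        assert int(res.tables[0].occurrences.iloc[0]) == 3
        assert len(res.tables[1]) == 3

    def test_cumulative_coverage_sums_rows(self, mixed_corpus):
        codes = [rc.encode_reaction(r) for r, _ in mixed_corpus[:50]]
        res = diversity_tables(codes, max_depth=2)
        t0 = res.tables[0]
        cov = res.coverage(0)
        assert int(cov.iloc[-1]) == 50
        if len(t0) > 1:
            assert int(cov.iloc[1]) == int(t0.occurrences.iloc[0]
                                           + t0.occurrences.iloc[1])

    def test_deeper_tables_refine_shallower_ones(self, mixed_corpus):
        codes = [rc.encode_reaction(r) for r, _ in mixed_corpus[:50]]
        res = diversity_tables(codes, max_depth=3)
        for d in range(3):
            shallow = dict(res.tables[d].itertuples(index=False))
            deep = res.tables[d + 1]
            sums: dict[str, int] = {}
            for prefix, count in deep.itertuples(index=False):
                parent = next(p for p in shallow if prefix.startswith(p))
                sums[parent] = sums.get(parent, 0) + count
            assert sums == shallow

    def test_unparseable_codes_are_skipped_with_count(self):
        res = diversity_tables(["garbage", "0:906()708(10GG)|"])
        assert res.skipped == 1
        assert len(res.tables[0]) == 1

    def test_csv_files_written(self, tmp_path, mixed_corpus):
        codes = [rc.encode_reaction(r) for r, _ in mixed_corpus[:10]]
        diversity_tables(codes, max_depth=9, out_dir=tmp_path)
        files = sorted(p.name for p in tmp_path.glob("d*.csv"))
        assert files == [f"d{d}.csv" for d in range(10)]
        header = (tmp_path / "d0.csv").read_text().splitlines()[0]
        assert header == "partial_reaction_code,occurrences"

    def test_prefix_excludes_letter_block(self):
        r, _ = rc.make_reaction(3, center_size=2, remaining_depth=1,
                                leaving_size=2)
        code = rc.encode_reaction(r)
        assert "A:" in code
        assert "A:" not in layer_prefix(code, 9)


class TestRoundtripSimilar:
    def test_identical_reactions_are_similar(self, examples):
        for r in examples.values():
            assert rc.roundtrip_similar(r, r)

    def test_extra_product_keeps_containment(self):
        a = rc.read_reaction("[CH3:1][Br:2].[OH2:3]>>[CH3:1][OH:3]")
        b = rc.decode_code(rc.encode_reaction(a))  # adds HBr back
        assert rc.roundtrip_similar(a, b)
        assert not rc.roundtrip_similar(b, a)

    def test_missing_ring_is_dissimilar(self):
        a = rc.read_reaction("[CH2:1]1[CH2:2][CH2:3]1>>[CH2:1]1[CH2:2][CH2:3]1")
        b = rc.read_reaction("[CH3:1][CH2:2][CH3:3]>>[CH3:1][CH2:2][CH3:3]")
        assert not rc.roundtrip_similar(a, b)


class TestRunValidation:
    def test_empty_stream_is_all_zero(self):
        counts = rc.run_validation([], 1)
        assert counts["total"] == 0 and counts["similar"] == 0

    @pytest.mark.parametrize("protocol", [1, 2, 3])
    def test_balanced_corpus_has_no_non_identical(self, protocol):
        reactions = [rc.make_reaction(400 + s, center_size=2 + s % 2,
                                      remaining_depth=1 + s % 2,
                                      leaving_size=0,
                                      aromatic=(s % 4 == 0))[0]
                     for s in range(24)]
        counts = rc.run_validation(reactions, protocol)
        assert counts["total"] == 24
        assert counts["non_identical"] == 0
        assert counts["similar"] + counts["non_identical"] == counts["total"]

    def test_corrupt_mappings_fall_in_non_identical(self):
        reactions = [rc.make_reaction(s, center_size=3, remaining_depth=2,
                                      defect="corrupt_mapping")[0]
                     for s in range(8)]
        counts = rc.run_validation(reactions, 1)
        assert counts["non_identical"] == 8

    def test_element_consistent_swap_is_transported_faithfully(self):
        reactions = [rc.make_reaction(s, center_size=3, remaining_depth=2,
                                      defect="swapped_maps")[0]
                     for s in range(8)]
        counts = rc.run_validation(reactions, 1)
        assert counts["similar"] == 8

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            rc.run_validation([], 4)
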