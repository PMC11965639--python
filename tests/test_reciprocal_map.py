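"""Forward and reverse integration: name/EC matching, overlap, neighborhoods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recip import metabolome_model as mm
from recip import reciprocal_map as rm
from recip.genome_model import BgcRegion, CdsRecord, GenomeAnnotation


def merged_from(rows):
    table = pd.DataFrame(
        rows, columns=["feature_id", "name", "structure_key", "tier", "score",
                       "mz_error_ppm"]
    )
    return mm.MergedAnnotations(table=table, tier_counts={}, n_unannotated=0)


class TestNameNormalization:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("Cinerubin B", "cinerubin-B"),
            ("loseolamycin A1", "Loseolamycin  A1"),
            ("bleomycin A2", "BLEOMYCIN_A2"),
        ],
    )
    def test_variants_normalize_equal(self, a, b):
        assert rm.normalize_name(a) == rm.normalize_name(b)

    def test_distinct_names_stay_distinct(self):
        assert rm.normalize_name("kedarcidin") != rm.normalize_name("pradimicin A")


class TestCompoundPresence:
    def test_name_match_is_punctuation_insensitive(self):
        merged = merged_from([[5, "cinerubin-B", None, 1, 0.9, None]])
        hit = rm.compound_presence(rm.PredictedCompound(name="Cinerubin B"), merged)
        assert hit == [5]

    def test_inchikey_skeleton_match(self):
        key = "ABCDEFGHIJKLMN-OPQRSTUVWX-N"
        merged = merged_from([[5, "something", key, 1, 0.9, None]])
        predicted = rm.PredictedCompound(
            name="other", structure_key="ABCDEFGHIJKLMN-ZZZZZZZZZZ-N"
        )
        assert rm.compound_presence(predicted, merged) == [5]

    def test_different_skeleton_blocks_do_not_match(self):
        merged = merged_from(
            [[5, "something", "AAAAAAAAAAAAAA-OPQRSTUVWX-N", 1, 0.9, None]]
        )
        predicted = rm.PredictedCompound(
            name="other", structure_key="BBBBBBBBBBBBBB-OPQRSTUVWX-N"
        )
        assert rm.compound_presence(predicted, merged) == []

    def test_planted_absent_compounds_have_zero_presence(self, scenario_ctx):
        ctx, truth = scenario_ctx
        for name in truth.predicted_compound_names:
            assert rm.compound_presence(
                rm.PredictedCompound(name=name), ctx.merged
            ) == []


class TestClassifyPredicted:
    def test_packaged_compounds_fall_into_six_classes(self):
        from importlib import resources

        path = resources.files("recip.data").joinpath(
            "bra006_predicted_compounds.tsv"
        )
        with resources.as_file(path) as p:
            compounds = rm.load_predicted_compounds(p)
        assert len(compounds) == 7
        groups, n = rm.classify_predicted(compounds)
        assert n == 6
        assert len(groups["Organooxygen compounds"]) == 2

    def test_empty_input_gives_zero_classes(self):
        assert rm.classify_predicted([]) == ({}, 0)

    def test_shared_class_counts_once(self):
        compounds = [
            rm.PredictedCompound(name="a", chem_class="Phenols"),
            rm.PredictedCompound(name="b", chem_class="Phenols"),
        ]
        groups, n = rm.classify_predicted(compounds)
        assert n == 1 and len(groups["Phenols"]) == 2

    def test_classless_compound_listed_under_none(self):
        groups, n = rm.classify_predicted([rm.PredictedCompound(name="x")])
        assert n == 0 and [c.name for c in groups["None"]] == ["x"]


class TestForwardClassSearch:
    def test_counts_match_planted_class_sizes(self, scenario_ctx):
        ctx, truth = scenario_ctx
        result = rm.forward_class_search(
            sorted(truth.class_counts), ctx.merged, ctx.taxonomy
        )
        assert {cls: n for cls, (n, _) in result.items()} == truth.class_counts

    def test_absent_class_counts_zero(self, scenario_ctx):
        ctx, _ = scenario_ctx
        result = rm.forward_class_search(["Anthracyclines"], ctx.merged, ctx.taxonomy)
        assert result["Anthracyclines"] == (0, [])

    def test_invariant_to_row_order(self, scenario_ctx):
        ctx, truth = scenario_ctx
        shuffled = mm.MergedAnnotations(
            table=ctx.merged.table.sample(frac=1.0, random_state=5),
            tier_counts=ctx.merged.tier_counts,
            n_unannotated=ctx.merged.n_unannotated,
        )
        a = rm.forward_class_search(sorted(truth.class_counts), ctx.merged, ctx.taxonomy)
        b = rm.forward_class_search(sorted(truth.class_counts), shuffled, ctx.taxonomy)
        assert a == b

    def test_unmapped_keys_never_counted(self):
        merged = merged_from([[1, "x", "UNSEENKEY", 1, 0.9, None]])
        tax = mm.ChemTaxonomy(table={})
        assert rm.forward_class_search(["Phenols"], merged, tax) == {
            "Phenols": (0, [])
        }


valid_ec = st.lists(
    st.one_of(st.just("-"), st.integers(1, 40).map(str)), min_size=4, max_size=4
).map(".".join)


class TestEcMatching:
    @pytest.mark.parametrize(
        "pattern,candidate,expected",
        [
            ("6.3.2.-", "6.3.2.26", True),
            ("6.3.2.-", "6.3.1.2", False),
            ("-.-.-.-", "1.14.13.7", True),
            ("2.7.11.1", "2.7.11.1", True),
        ],
    )
    def test_wildcard_semantics(self, pattern, candidate, expected):
        assert rm.ec_matches(pattern, candidate) is expected

    def test_malformed_ec_raises(self):
        with pytest.raises(ValueError):
            rm.ec_matches("6.3.2", "6.3.2.1")
        with pytest.raises(ValueError):
            rm.ec_matches("6.3.2.1", "six.3.2.1")

    @settings(max_examples=60, deadline=None)
    @given(a=valid_ec, b=valid_ec)
    def test_symmetric(self, a, b):
        assert rm.ec_matches(a, b) == rm.ec_matches(b, a)

    @settings(max_examples=30, deadline=None)
    @given(a=valid_ec)
    def test_reflexive(self, a):
        assert rm.ec_matches(a, a)


class TestReversePathwayMap:
    def test_planted_metabolite_is_unique_hit(self, scenario_ctx):
        ctx, truth = scenario_ctx
        hits = rm.reverse_pathway_map(ctx.merged, ctx.pathway_db)
        assert hits == [(truth.pathway_metabolite_node, [truth.pathway_id])]

    def test_empty_db_gives_empty_result(self, scenario_ctx):
        ctx, _ = scenario_ctx
        assert rm.reverse_pathway_map(ctx.merged, rm.PathwayDb({}, {})) == []

    def test_metabolite_in_two_pathways_reports_both(self):
        merged = merged_from([[1, "compound x", None, 1, 0.9, None]])
        db = rm.PathwayDb(
            compound_to_pathways={"Compound-X": ["P1", "P2"]},
            pathway_to_enzymes={"P1": [], "P2": []},
        )
        assert rm.reverse_pathway_map(merged, db) == [(1, ["P1", "P2"])]


class TestMatchPathwayEnzymes:
    def test_planted_enzymes_all_found_with_expected_keys(self, scenario_ctx):
        ctx, truth = scenario_ctx
        matches = rm.match_pathway_enzymes(truth.pathway_id, ctx.pathway_db, ctx.genome)
        assert len(matches) == len(truth.pathway_cds)
        assert {m.cds.locus_tag for m in matches} == set(truth.pathway_cds)
        assert {m.enzyme_name: m.matched_by for m in matches} == truth.expected_matched_by

    def test_unknown_pathway_raises(self, scenario_ctx):
        ctx, _ = scenario_ctx
        with pytest.raises(KeyError):
            rm.match_pathway_enzymes("KO_MISSING", ctx.pathway_db, ctx.genome)

    def test_genome_without_qualifiers_warns_and_returns_empty(self, caplog):
        genome = GenomeAnnotation(
            contigs={"1": 1000},
            cds=[CdsRecord("1", 0, 300, "+", "g1", protein_seq="M" * 10)],
        )
        db = rm.PathwayDb(
            compound_to_pathways={},
            pathway_to_enzymes={"P": [rm.PathwayEnzyme("1.1.1.1", None, "e")]},
        )
        with caplog.at_level("WARNING"):
            assert rm.match_pathway_enzymes("P", db, genome) == []
        assert "no EC or COG" in caplog.text

    def test_cds_matching_both_keys_reports_both(self):
        genome = GenomeAnnotation(
            contigs={"1": 1000},
            cds=[CdsRecord("1", 0, 300, "+", "g1", ec_numbers=["1.1.1.1"],
                           cog_id="COG0001")],
        )
        db = rm.PathwayDb(
            compound_to_pathways={},
            pathway_to_enzymes={"P": [rm.PathwayEnzyme("1.1.1.-", "COG0001", "e")]},
        )
        (match,) = rm.match_pathway_enzymes("P", db, genome)
        assert match.matched_by == "both"


def region(rid, contig, start, end):
    return BgcRegion(region_id=rid, contig_id=contig, start=start, end=end,
                     bgc_type="NRPS")


def match_at(contig, start, end, tag):
    cds = CdsRecord(contig, start, end, "+", tag)
    return rm.EnzymeMatch("P", f"enzyme {tag}", "EC", cds)


class TestOverlapWithBgcs:
    def test_half_open_overlap_semantics(self):
        counts, _ = rm.overlap_with_bgcs(
            [match_at("1", 100, 200, "a")], [region("1.1", "1", 150, 400)]
        )
        assert counts == {"1.1": 1}
        counts, _ = rm.overlap_with_bgcs(
            [match_at("1", 100, 200, "a")], [region("1.1", "1", 200, 400)]
        )
        assert counts == {"1.1": 0}

    def test_equals_per_base_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            c_start = int(rng.integers(0, 1500))
            c_end = c_start + 1 + int(rng.integers(0, 400))
            r_start = int(rng.integers(0, 1500))
            r_end = r_start + 1 + int(rng.integers(0, 400))
            m = [match_at("1", c_start, c_end, "a")]
            r = [region("1.1", "1", r_start, r_end)]
            counts, _ = rm.overlap_with_bgcs(m, r)
            brute = len(
                set(range(c_start, c_end)) & set(range(r_start, r_end))
            ) > 0
            assert counts["1.1"] == int(brute)

    def test_different_contigs_never_overlap(self):
        counts, _ = rm.overlap_with_bgcs(
            [match_at("2", 100, 200, "a")], [region("1.1", "1", 0, 1000)]
        )
        assert counts == {"1.1": 0}

    def test_planted_region_top_ranked_with_planted_count(self, scenario_ctx):
        ctx, truth = scenario_ctx
        matches = rm.match_pathway_enzymes(truth.pathway_id, ctx.pathway_db, ctx.genome)
        counts, ranking = rm.overlap_with_bgcs(matches, ctx.regions)
        assert ranking[0] == truth.target_region_id
        assert counts[truth.target_region_id] == len(truth.in_region_cds)
        # uniqueness: strictly more overlap than any other region
        runner_up = max(v for k, v in counts.items() if k != truth.target_region_id)
        assert counts[truth.target_region_id] > runner_up

    def test_duplicate_cds_counted_once_per_region(self):
        cds = CdsRecord("1", 100, 200, "+", "a")
        matches = [
            rm.EnzymeMatch("P", "e1", "EC", cds),
            rm.EnzymeMatch("P", "e2", "EC", cds),
        ]
        counts, _ = rm.overlap_with_bgcs(matches, [region("1.1", "1", 0, 1000)])
        assert counts == {"1.1": 1}


class TestNeighborhood:
    def test_planted_hub_reports_neighbors_and_sharers(self, scenario_ctx):
        ctx, truth = scenario_ctx
        report = rm.neighborhood_report(
            ctx.network, truth.hub_id, ctx.merged, ctx.scaffold_flags
        )
        assert report.n_neighbors == len(truth.hub_neighbors)
        assert report.n_scaffold_sharing == truth.hub_scaffold_sharers

    def test_isolated_node_has_no_neighbors(self):
        net = mm.MolecularNetwork(nodes={1: (300.0, 5.0)}, edges=[])
        report = rm.neighborhood_report(net, 1, merged_from([]), {})
        assert report.n_neighbors == 0

    def test_unannotated_neighbor_listed_as_such(self):
        net = mm.MolecularNetwork(
            nodes={1: (300.0, 5.0), 2: (301.0, 6.0)},
            edges=[mm.NetworkEdge(1, 2, 0.9, 1.0)],
        )
        report = rm.neighborhood_report(net, 1, merged_from([]), {})
        assert report.neighbors[0].tier == "unannotated"

    def test_unknown_node_raises(self):
        net = mm.MolecularNetwork(nodes={1: (300.0, 5.0)}, edges=[])
        with pytest.raises(KeyError):
            rm.neighborhood_report(net, 99, merged_from([]), {})
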