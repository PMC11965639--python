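"""Modified cosine, network construction, tier merging and composition."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recip import metabolome_model as mm


def spec(fid, pre, rt, peaks):
    return mm.Spectrum(fid, pre, rt, np.asarray(peaks, dtype=float))


def exhaustive_modified_cosine(s1, s2, frag_tol=0.02):
    """Oracle: maximize the product sum over ALL one-to-one matchings."""
    w1 = np.sqrt(s1.peaks[:, 1])
    w2 = np.sqrt(s2.peaks[:, 1])
    shift = s1.precursor_mz - s2.precursor_mz
    candidates = [
        (i, j)
        for i in range(s1.n_peaks)
        for j in range(s2.n_peaks)
        if abs(s1.peaks[i, 0] - s2.peaks[j, 0]) <= frag_tol
        or abs(s1.peaks[i, 0] - s2.peaks[j, 0] - shift) <= frag_tol
    ]
    best = 0.0
    best_n = 0
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            if len({i for i, _ in subset}) < r or len({j for _, j in subset}) < r:
                continue
            total = sum(w1[i] * w2[j] for i, j in subset)
            if total > best:
                best, best_n = total, r
    norm = np.linalg.norm(w1) * np.linalg.norm(w2)
    return min(best / norm, 1.0), best_n


def random_toy_pair(rng, shift=0.0):
    """Toy spectra whose peaks are spaced far apart (unambiguous matching)."""
    n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
    mz1 = np.sort(rng.choice(np.arange(100, 400, 5.0), size=n1, replace=False))
    keep = rng.integers(1, n1 + 1)
    mz2 = np.sort(
        np.concatenate(
            [mz1[:keep] + shift, rng.uniform(401, 500, size=n2 - keep)
             if n2 > keep else np.empty(0)]
        )
    )[:n2]
    s1 = spec(1, 350.0, 5.0, np.column_stack([mz1, rng.uniform(10, 100, n1)]))
    s2 = spec(2, 350.0 + shift, 6.0, np.column_stack([mz2, rng.uniform(10, 100, len(mz2))]))
    return s1, s2


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = spec(1, 300.0, 5.0, [[100.0, 10.0], [150.0, 40.0], [200.0, 5.0]])
        cosine, n = mm.modified_cosine(s, s)
        assert cosine == pytest.approx(1.0)
        assert n == 3

    def test_no_pairable_peaks_gives_zero(self):
        s1 = spec(1, 300.0, 5.0, [[100.0, 10.0], [150.0, 10.0]])
        s2 = spec(2, 300.0, 6.0, [[120.0, 10.0], [170.0, 10.0]])
        assert mm.modified_cosine(s1, s2) == (0.0, 0)

    def test_equals_exhaustive_matching_oracle_on_toy_spectra(self):
        rng = np.random.default_rng(17)
        for k in range(30):
            # shifts sit half-way between the 5-Da peak grid steps, so a
            # peak pair is either a direct or a shifted candidate, never both
            shift = 0.0 if k % 2 == 0 else float(rng.integers(1, 6)) * 5 + 2.5
            s1, s2 = random_toy_pair(rng, shift)
            ours = mm.modified_cosine(s1, s2)
            oracle = exhaustive_modified_cosine(s1, s2)
            assert ours[0] == pytest.approx(oracle[0], abs=1e-9)
            assert ours[1] == oracle[1]

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            s1, s2 = random_toy_pair(rng, float(rng.uniform(0, 20)))
            c12 = mm.modified_cosine(s1, s2)[0]
            c21 = mm.modified_cosine(s2, s1)[0]
            assert c12 == pytest.approx(c21, abs=1e-9)
            scaled = spec(3, s2.precursor_mz, s2.rt,
                          np.column_stack([s2.peaks[:, 0], s2.peaks[:, 1] * 7.5]))
            assert mm.modified_cosine(s1, scaled)[0] == pytest.approx(c12, abs=1e-9)

    def test_agrees_with_independent_reference_implementation(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(3)
        for shift in (0.0, 14.0157):
            s1, s2 = random_toy_pair(rng, shift)
            ours, _ = mm.modified_cosine(s1, s2)
            m1 = matchms.Spectrum(
                mz=s1.peaks[:, 0], intensities=np.sqrt(s1.peaks[:, 1]),
                metadata={"precursor_mz": s1.precursor_mz},
                metadata_harmonization=False,
            )
            m2 = matchms.Spectrum(
                mz=s2.peaks[:, 0], intensities=np.sqrt(s2.peaks[:, 1]),
                metadata={"precursor_mz": s2.precursor_mz},
                metadata_harmonization=False,
            )
            theirs = ModifiedCosine(tolerance=0.02).pair(m1, m2)
            assert ours == pytest.approx(float(theirs["score"]), abs=1e-6)

    def test_empty_peaks_rejected(self):
        s = spec(1, 300.0, 5.0, [[100.0, 10.0]])
        empty = mm.Spectrum(2, 300.0, 5.0, np.empty((0, 2)))
        with pytest.raises(ValueError):
            mm.modified_cosine(s, empty)


class TestBuildNetwork:
    def test_identical_spectra_form_one_edge(self):
        peaks = [[100.0 + 7 * i, 50.0] for i in range(8)]
        s1, s2 = spec(1, 300.0, 5.0, peaks), spec(2, 300.0, 6.0, peaks)
        net = mm.build_network([s1, s2])
        assert len(net.edges) == 1
        assert set(net.nodes) == {1, 2}
        assert net.n_components == 1

    def test_dissimilar_spectra_give_empty_network(self):
        s1 = spec(1, 300.0, 5.0, [[100.0 + 7 * i, 50.0] for i in range(8)])
        s2 = spec(2, 500.0, 6.0, [[601.0 + 9 * i, 50.0] for i in range(8)])
        net = mm.build_network([s1, s2])
        assert net.nodes == {} and net.edges == []

    def test_component_count_matches_planted_truth(self, tmp_path):
        from recip.synthetic_data import ScenarioParams, generate_scenario

        params = ScenarioParams(
            seed=13, n_network_nodes=45, n_components=5, tier_counts=(10, 20, 5),
            n_isomer_pairs=2,
        )
        files, truth = generate_scenario(params, tmp_path)
        spectra = mm.read_mgf(files.spectra_mgf)
        net = mm.build_network(spectra)
        assert net.n_components == truth.n_components == 5
        assert len(net.nodes) == truth.n_network_nodes == 45

    def test_node_count_monotone_in_cosine_threshold(self, scenario):
        files, _ = scenario
        spectra = mm.read_mgf(files.spectra_mgf)
        sizes = [
            len(mm.build_network(spectra, cosine_min=c).nodes)
            for c in (0.5, 0.7, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestMgfRoundTrip:
    def test_write_then_read_preserves_spectra(self, tmp_path, scenario):
        files, _ = scenario
        spectra = mm.read_mgf(files.spectra_mgf)
        out = tmp_path / "rt.mgf"
        mm.write_mgf(spectra, out)
        again = mm.read_mgf(out)
        assert [s.feature_id for s in again] == [s.feature_id for s in spectra]
        for a, b in zip(spectra, again):
            assert a.precursor_mz == pytest.approx(b.precursor_mz)
            assert a.rt == pytest.approx(b.rt, abs=1e-4)
            np.testing.assert_allclose(a.peaks, b.peaks, rtol=1e-9)


def toy_network(n_nodes=6):
    nodes = {i: (300.0 + i, 5.0 + i) for i in range(1, n_nodes + 1)}
    edges = [mm.NetworkEdge(i, i + 1, 0.9, 1.0) for i in range(1, n_nodes)]
    return mm.MolecularNetwork(nodes=nodes, edges=edges)


class TestMergeAnnotations:
    def test_earlier_tier_wins_regardless_of_score(self):
        net = toy_network()
        t1 = [mm.AnnotationRecord(1, "library hit", None, 1, 0.5)]
        t3 = [mm.AnnotationRecord(1, "in silico guess", None, 3, 0.99)]
        merged = mm.merge_annotations(net, t1, [], t3)
        assert merged.annotation_for(1).name == "library hit"
        assert merged.tier_counts == {1: 1, 2: 0, 3: 0}

    def test_within_tier_highest_score_then_name(self):
        net = toy_network()
        t1 = [
            mm.AnnotationRecord(1, "zzz", None, 1, 0.9),
            mm.AnnotationRecord(1, "aaa", None, 1, 0.9),
            mm.AnnotationRecord(1, "low", None, 1, 0.5),
        ]
        merged = mm.merge_annotations(net, t1)
        assert merged.annotation_for(1).name == "aaa"

    def test_counts_sum_to_node_count(self, scenario_ctx):
        ctx, truth = scenario_ctx
        merged = ctx.merged
        assert (
            sum(merged.tier_counts.values()) + merged.n_unannotated
            == len(ctx.network.nodes)
        )
        assert tuple(merged.tier_counts[t] for t in (1, 2, 3)) == truth.tier_counts

    def test_order_independent_within_tier(self):
        net = toy_network()
        records = [
            mm.AnnotationRecord(i, f"name{i}{j}", None, 1, 0.5 + 0.1 * j)
            for i in (1, 2, 3)
            for j in range(3)
        ]
        a = mm.merge_annotations(net, records)
        b = mm.merge_annotations(net, records[::-1])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_unknown_node_dropped_with_log(self, caplog):
        net = toy_network()
        with caplog.at_level("WARNING"):
            merged = mm.merge_annotations(
                net, [mm.AnnotationRecord(99, "ghost", None, 1, 0.9)]
            )
        assert merged.table.empty
        assert "unknown node" in caplog.text

    def test_no_annotations_leaves_all_unannotated(self):
        net = toy_network()
        merged = mm.merge_annotations(net, [])
        assert merged.n_unannotated == len(net.nodes)


class TestComposition:
    def make_taxonomy(self, mapping):
        return mm.ChemTaxonomy(
            table={k: ("Organic compounds", v, v) for k, v in mapping.items()}
        )

    def merged_with_keys(self, keys):
        net = mm.MolecularNetwork(
            nodes={i: (300.0, 5.0) for i in range(1, len(keys) + 1)},
            edges=[mm.NetworkEdge(i, i + 1, 0.9, 0.0) for i in range(1, len(keys))],
        )
        records = [
            mm.AnnotationRecord(i + 1, f"c{i}", k, 1, 0.9)
            for i, k in enumerate(keys)
        ]
        return mm.merge_annotations(net, records)

    def test_single_class_is_100_percent(self):
        merged = self.merged_with_keys(["K1"] * 10)
        tax = self.make_taxonomy({"K1": "Lipids"})
        assert mm.composition_summary(merged, tax) == [("Lipids", 10, 100.0)]

    def test_planted_composition_recovered(self):
        keys = ["A"] * 30 + ["B"] * 50 + ["X"] * 20  # X unmapped -> None
        merged = self.merged_with_keys(keys)
        tax = self.make_taxonomy({"A": "ClassA", "B": "ClassB"})
        out = dict((label, (c, p)) for label, c, p in mm.composition_summary(merged, tax))
        assert out == {"ClassB": (50, 50.0), "ClassA": (30, 30.0), "None": (20, 20.0)}

    def test_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(2)
        keys = [f"K{rng.integers(0, 7)}" for _ in range(37)]
        merged = self.merged_with_keys(keys)
        tax = self.make_taxonomy({f"K{i}": f"C{i}" for i in range(7)})
        total = sum(p for _, _, p in mm.composition_summary(merged, tax))
        assert 99.8 <= total <= 100.2

    def test_empty_table_is_an_error(self):
        net = toy_network()
        merged = mm.merge_annotations(net, [])
        with pytest.raises(ValueError):
            mm.composition_summary(merged, self.make_taxonomy({}))


class TestIsomerCandidates:
    def test_ppm_close_far_rt_adjacent_pair_is_reported(self):
        net = mm.MolecularNetwork(
            nodes={1: (344.1601, 8.0), 2: (344.1603, 12.5)},
            edges=[mm.NetworkEdge(1, 2, 0.9, 0.0002)],
        )
        assert mm.find_isomer_candidates(net) == [(1, 2)]

    def test_small_rt_difference_is_not_reported(self):
        net = mm.MolecularNetwork(
            nodes={1: (344.1601, 8.0), 2: (344.1603, 8.2)},
            edges=[mm.NetworkEdge(1, 2, 0.9, 0.0002)],
        )
        assert mm.find_isomer_candidates(net) == []

    def test_non_adjacent_pair_requires_flag(self):
        net = mm.MolecularNetwork(
            nodes={1: (344.1601, 8.0), 2: (344.1603, 12.5), 3: (500.0, 5.0)},
            edges=[mm.NetworkEdge(1, 3, 0.9, 0.0), mm.NetworkEdge(2, 3, 0.9, 0.0)],
        )
        assert mm.find_isomer_candidates(net) == []
        assert mm.find_isomer_candidates(net, require_adjacent=False) == [(1, 2)]

    def test_planted_pairs_recovered_exactly(self, scenario_ctx):
        ctx, truth = scenario_ctx
        found = mm.find_isomer_candidates(ctx.network)
        assert found == sorted(truth.isomer_pairs)
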