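import pytest

from metabokg.errors import ParameterError, ValidationError
from metabokg.ingest import Feature, FeatureList
from metabokg.queries import (
    GraphIndex,
    _FeatureInfo,
    activity_filters,
    annotation_agreement,
    chembl_activity_join,
    class_count_per_sample,
    cross_polarity_pairs,
    fragment_presence,
    group_specificity,
    same_annotation_cross_polarity,
    shared_words_ranking,
    tanimoto_filter,
)
from tests.conftest import feature_iri, make_spectrum


def small_index():
    """Hand-built index: 2 samples, canopus/sirius/isdb annotations with
    boundary scores, bioactivity, chembl rows."""
    idx = GraphIndex()
    idx.samples = {
        "S1": {"iri": "s1", "sample_type": "sample", "source_id": "A", "taxon": "X y"},
        "S2": {"iri": "s2", "sample_type": "sample", "source_id": "B", "taxon": "Z w"},
    }
    for sid, fid, words in [("S1", 1, {"peak@1.00", "peak@2.00", "loss@3.00"}),
                            ("S1", 2, {"peak@9.00"}),
                            ("S2", 1, {"peak@1.00", "peak@2.00", "loss@3.00"}),
                            ("S2", 2, {"peak@1.00"})]:
        iri = feature_iri(sid, "PI", fid)
        idx.features[iri] = _FeatureInfo(iri, sid, "PI", fid, 100.0 + fid, 60.0 * fid)
        idx.words[iri] = frozenset(words)
    idx.canopus = {
        feature_iri("S1", "PI", 1): {"npc_class": "Q", "probability": 0.9},
        feature_iri("S1", "PI", 2): {"npc_class": "Q", "probability": 0.5},  # boundary
        feature_iri("S2", "PI", 1): {"npc_class": "Q", "probability": 0.7},
    }
    idx.isdb = {
        feature_iri("S1", "PI", 1): {"inchikey2d": "A" * 14, "taxo_score": 8, "rank": 1},
        feature_iri("S2", "PI", 1): {"inchikey2d": "B" * 14, "taxo_score": 5, "rank": 1},
    }
    idx.sirius = {
        feature_iri("S1", "PI", 1): {"inchikey2d": "A" * 14, "cosmic": 0.9,
                                     "zodiac": 0.95, "adduct": "[M+H]+"},
        feature_iri("S2", "PI", 1): {"inchikey2d": "C" * 14, "cosmic": 0.9,
                                     "zodiac": 0.95, "adduct": "[M+H]+"},
    }
    idx.bioactivity = {
        "S1": {"inhib": 90.0, "cytotoxicity": 10.0},
        "S2": {"inhib": 90.0, "cytotoxicity": 80.0},
    }
    idx.structure_taxa = {"A" * 14: ("X y",), "B" * 14: ("Z w",)}
    idx.chembl = [
        {"inchikey2d": "A" * 14, "target": "T", "activity_value": 1.0, "np_likeness": 1.0},
        {"inchikey2d": "D" * 14, "target": "T", "activity_value": 2.0, "np_likeness": 1.0},
    ]
    return idx


class TestSharedWords:
    def test_known_overlaps_ranked(self):
        idx = small_index()
        r = shared_words_ranking(feature_iri("S1", "PI", 1), idx, top_k=10)
        assert [(row["sample_id"], row["shared_words"]) for row in r.rows] == [
            ("S2", 3), ("S2", 1)]  # zero-overlap S1/2 excluded

    def test_planted_copy_ranks_first_with_full_word_count(self, default_study):
        ledger = default_study["ledger"]
        sc = ledger["shared_compound"]
        sid, fid = sc["occurrences"][0]
        r = shared_words_ranking(feature_iri(sid, "PI", fid),
                                 default_study["result"].index, top_k=3)
        assert r.rows[0]["shared_words"] == sc["word_count"]
        other_samples = {s for s, _ in sc["occurrences"][1:]}
        assert r.rows[0]["sample_id"] in other_samples

    def test_symmetry_of_overlap_counts(self):
        idx = small_index()
        a, b = feature_iri("S1", "PI", 1), feature_iri("S2", "PI", 1)
        ra = {row["feature"]: row["shared_words"] for row in
              shared_words_ranking(a, idx).rows}
        rb = {row["feature"]: row["shared_words"] for row in
              shared_words_ranking(b, idx).rows}
        assert ra[b] == rb[a]

    def test_feature_without_document_rejected(self):
        with pytest.raises(ValidationError):
            shared_words_ranking("missing", small_index())


class TestClassCount:
    def test_strictly_above_cutoff(self):
        r = class_count_per_sample(small_index(), "Q", prob_cutoff=0.5)
        # the p=0.5 feature is NOT counted: "above" is strict
        assert [(row["sample_id"], row["count"]) for row in r.rows] == [("S1", 1), ("S2", 1)]

    def test_absent_class_empty(self):
        assert class_count_per_sample(small_index(), "Nope").rows == []


def test_annotation_agreement_on_2d_key():
    r = annotation_agreement(small_index())
    assert len(r.rows) == 1
    assert r.rows[0]["inchikey2d"] == "A" * 14


class TestCrossPolarity:
    def _idx(self, ni_mz_offset=0.0, rt_offset=0.0, annotate=True):
        from metabokg.annotation import PROTON_MASS
        idx = GraphIndex()
        idx.samples = {"S1": {}}
        pi = feature_iri("S1", "PI", 1)
        ni = feature_iri("S1", "NI", 1)
        pi_mz = 465.3002
        idx.features[pi] = _FeatureInfo(pi, "S1", "PI", 1, pi_mz, 300.0)
        idx.features[ni] = _FeatureInfo(
            ni, "S1", "NI", 1, pi_mz - 2 * PROTON_MASS + ni_mz_offset, 300.0 + rt_offset)
        if annotate:
            idx.sirius[pi] = {"inchikey2d": "A" * 14, "cosmic": 0.9, "zodiac": 0.9,
                              "adduct": "[M+H]+"}
        return idx

    def test_two_proton_pair_found(self):
        assert len(cross_polarity_pairs(self._idx()).rows) == 1

    def test_rt_window_excludes(self):
        assert cross_polarity_pairs(self._idx(rt_offset=4.0)).rows == []

    def test_ppm_window_excludes(self):
        assert cross_polarity_pairs(self._idx(ni_mz_offset=463.0 * 20e-6)).rows == []

    def test_all_pi_considered_without_annotations(self):
        r = cross_polarity_pairs(self._idx(annotate=False))
        assert len(r.rows) == 1
        assert r.parameters["restricted_to_MplusH"] is False

    def test_exact_planted_pairs_on_study(self, default_study):
        r = cross_polarity_pairs(default_study["result"].index)
        got = sorted((row["sample_id"],
                      int(row["pi_feature"].rsplit("_", 1)[1]),
                      int(row["ni_feature"].rsplit("_", 1)[1])) for row in r.rows)
        assert got == sorted(map(tuple, default_study["ledger"]["cross_polarity_pairs"]))


class TestSameAnnotationCrossPolarity:
    def _idx(self, ik_ni="A" * 14, rt_ni=300.0):
        idx = GraphIndex()
        pi, ni = feature_iri("S1", "PI", 1), feature_iri("S1", "NI", 1)
        idx.features[pi] = _FeatureInfo(pi, "S1", "PI", 1, 465.3, 300.0)
        idx.features[ni] = _FeatureInfo(ni, "S1", "NI", 1, 463.29, rt_ni)
        idx.sirius[pi] = {"inchikey2d": "A" * 14}
        idx.sirius[ni] = {"inchikey2d": ik_ni}
        return idx

    def test_matching_keys_paired(self):
        assert len(same_annotation_cross_polarity(self._idx()).rows) == 1

    def test_equal_keys_far_rt_empty(self):
        assert same_annotation_cross_polarity(self._idx(rt_ni=310.0)).rows == []

    def test_different_keys_empty(self):
        assert same_annotation_cross_polarity(self._idx(ik_ni="B" * 14)).rows == []


class TestFragmentPresence:
    def _fl(self, peaks):
        s = make_spectrum(peaks, precursor=400.0)
        return FeatureList("S1", "PI", [Feature(1, 400.0, 100.0, 1.0, s)])

    def test_fragment_with_sufficient_relative_intensity(self):
        fl = self._fl([(201.091, 0.7), (300.0, 1.0)])
        assert len(fragment_presence([fl]).rows) == 1

    def test_weak_fragment_dropped(self):
        fl = self._fl([(201.091, 0.4), (300.0, 1.0)])
        assert fragment_presence([fl]).rows == []

    def test_out_of_tolerance_dropped(self):
        fl = self._fl([(201.15, 1.0), (300.0, 1.0)])
        assert fragment_presence([fl]).rows == []


class TestGroupSpecificity:
    def test_ratio_definition(self):
        idx = GraphIndex()
        idx.samples = {f"S{i}": {} for i in range(1, 8)}
        # structure X annotated in 5 of 6 group samples and nowhere else
        for i in range(1, 6):
            iri = feature_iri(f"S{i}", "PI", 1)
            idx.features[iri] = _FeatureInfo(iri, f"S{i}", "PI", 1)
            idx.isdb[iri] = {"inchikey2d": "X" * 14}
        r = group_specificity(idx, {f"S{i}" for i in range(1, 7)})
        assert r.rows[0] == {"inchikey2d": "X" * 14, "count_in_group": 5,
                             "group_specificity": 1.0}

    def test_ubiquitous_structure_specificity_is_group_fraction(self):
        idx = GraphIndex()
        idx.samples = {f"S{i}": {} for i in range(1, 5)}
        for i in range(1, 5):
            iri = feature_iri(f"S{i}", "PI", 1)
            idx.features[iri] = _FeatureInfo(iri, f"S{i}", "PI", 1)
            idx.isdb[iri] = {"inchikey2d": "X" * 14}
        r = group_specificity(idx, {"S1", "S2"})
        assert r.rows[0]["group_specificity"] == pytest.approx(2 / 4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            group_specificity(small_index(), set())

    def test_planted_active_class_fully_specific(self, default_study):
        ledger = default_study["ledger"]
        active_iks = {e.inchikey2d for e in default_study["library"]
                      if e.npc_class == ledger["active_class"]}
        r = group_specificity(default_study["result"].index, ledger["active_group"])
        seen = {row["inchikey2d"]: row for row in r.rows}
        for ik in active_iks:
            if ik in seen:
                assert seen[ik]["group_specificity"] == 1.0


class TestActivityFilters:
    def test_active_and_noncytotoxic(self):
        r = activity_filters(small_index(), "inhib", 80.0, cytotox_max=20.0)
        assert [row["sample_id"] for row in r.rows] == ["S1"]

    def test_trivial_thresholds_keep_all(self):
        r = activity_filters(small_index(), "inhib", 0.0, cytotox_max=100.0)
        assert len(r.rows) == 2

    def test_unknown_assay_rejected(self):
        with pytest.raises(ParameterError):
            activity_filters(small_index(), "nope", 50.0)


class TestChemblJoin:
    def test_confident_annotations_joined_with_taxa(self):
        r = chembl_activity_join(small_index(), "T")
        # only A... is confidently annotated (sirius gates pass); D... never annotated
        assert [row["inchikey2d"] for row in r.rows] == ["A" * 14]
        assert r.rows[0]["reported_taxa"] == "X y"

    def test_empty_activity_table_empty_result(self):
        idx = small_index()
        idx.chembl = []
        assert chembl_activity_join(idx, "T").rows == []


class TestTanimoto:
    def test_identical_vectors_kept(self):
        r = tanimoto_filter({"a": [1, 1, 0], "ref": [1, 1, 0]}, "ref", 0.8)
        assert {row["structure"] for row in r.rows} == {"a", "ref"}

    def test_disjoint_vectors_dropped(self):
        r = tanimoto_filter({"a": [0, 0, 1, 1]}, [1, 1, 0, 0], 0.1)
        assert r.rows == []

    def test_bit_arithmetic(self):
        r = tanimoto_filter({"a": [1, 1, 0, 0]}, [1, 0, 1, 0], min_sim=0.0)
        assert r.rows[0]["tanimoto"] == pytest.approx(1 / 3)

    def test_threshold_inclusive(self):
        r = tanimoto_filter({"a": [1, 1, 0, 0, 1]}, [1, 1, 0, 0, 0], min_sim=2 / 3)
        assert len(r.rows) == 1  # similarity exactly 2/3 kept

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto_filter({"a": [1, 0]}, [1, 0, 1], 0.5)


def test_queries_are_pure_functions_of_the_graph(default_study):
    idx = default_study["result"].index
    for fn, args in [
        (annotation_agreement, ()),
        (cross_polarity_pairs, ()),
        (class_count_per_sample, (default_study["ledger"]["active_class"],)),
        (group_specificity, (default_study["ledger"]["active_group"],)),
    ]:
        assert fn(idx, *args).rows == fn(idx, *args).rows
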