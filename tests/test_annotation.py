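import pytest

from metabokg.annotation import (
    ADDUCTS,
    ConfidenceThresholds,
    ExternalAnnotation,
    LibraryEntry,
    PROTON_MASS,
    adduct_mz,
    chemical_consistency_reweight,
    confidence_filter,
    isdb_spectral_match,
    load_chembl_table,
    load_external_annotations,
    monoisotopic_mass,
    ms1_annotate,
    taxonomic_reweight,
)
from metabokg.errors import ParameterError, ParseError, SchemaError, ValidationError
from metabokg.ingest import Peak
from metabokg.spectral import MNParams, MolecularNetwork, ScorePair
from metabokg.taxonomy import resolve_taxon
from tests.conftest import make_spectrum

# independent element masses (CODATA/AME) for the oracle sums
_EL = {"C": 12.0, "H": 1.00782503207, "O": 15.9949146196}


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("H2O", 2 * _EL["H"] + _EL["O"]),
            ("C", 12.0),
            ("C30H40O5", 30 * _EL["C"] + 40 * _EL["H"] + 5 * _EL["O"]),
        ],
    )
    def test_element_sum_oracle(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=1e-5)

    def test_unknown_element_rejected(self):
        with pytest.raises(ParseError):
            monoisotopic_mass("C5Xx2")

    def test_garbage_rejected(self):
        with pytest.raises(ParseError):
            monoisotopic_mass("not a formula")


class TestAdductMz:
    @pytest.mark.parametrize(
        "formula,printed,max_ppm",
        [
            ("C30H40O5", 481.2950, 1.0),
            ("C30H40O4", 465.3002, 1.0),
            ("C30H38O6", 495.2754, 3.0),
        ],
    )
    def test_protonated_masses_match_measured_values(self, formula, printed, max_ppm):
        calc = adduct_mz(formula, "[M+H]+")
        assert abs(printed - calc) / calc * 1e6 <= max_ppm

    def test_proton_difference_between_polarities(self):
        plus = adduct_mz("C30H40O5", "[M+H]+")
        minus = adduct_mz("C30H40O5", "[M-H]-")
        assert plus - minus == pytest.approx(2 * PROTON_MASS, abs=1e-12)

    def test_unsupported_adduct(self):
        with pytest.raises(ParameterError):
            adduct_mz("C30H40O5", "[M+2H]2+")

    def test_all_supported_adducts_computable(self):
        for name in ADDUCTS:
            assert adduct_mz("C10H14N2O3", name) > 0


def entry(structure_id="LIB1", formula="C20H24O4", taxa=("Waltheria indica",),
          peaks=None, npc_class="Quinoline alkaloids", inchikey2d=None):
    peaks = peaks or [(60.0 + 10 * k, 0.2 + 0.1 * k) for k in range(8)]
    return LibraryEntry(
        structure_id=structure_id,
        inchikey2d=inchikey2d or (structure_id + "X" * (14 - len(structure_id))).upper()[:14],
        smiles="CC",
        formula=formula,
        exact_mass=monoisotopic_mass(formula),
        taxa=tuple(taxa),
        peaks=tuple(Peak(m, i) for m, i in peaks),
        npc_class=npc_class,
    )


class TestIsdbSpectralMatch:
    def test_planted_copy_scores_one(self):
        e = entry()
        s = make_spectrum([(p.mz, p.intensity) for p in e.peaks],
                          precursor=e.precursor_mz("PI"))
        cands = isdb_spectral_match(s, [e])
        assert len(cands) == 1
        assert cands[0].spectral_score == pytest.approx(1.0, abs=1e-12)

    def test_too_few_matching_fragments_rejected(self):
        e = entry(peaks=[(60.0 + 10 * k, 1.0) for k in range(5)])  # only 5 peaks
        s = make_spectrum([(p.mz, p.intensity) for p in e.peaks],
                          precursor=e.precursor_mz("PI"))
        assert isdb_spectral_match(s, [e]) == []  # score 1.0 but 5 < 6 matches

    def test_low_cosine_rejected_despite_enough_matches(self):
        # entry shares 6 near-zero-intensity peaks; its dominant peak is absent
        shared = [(60.0 + 10 * k, 0.01) for k in range(6)]
        e = entry(peaks=shared + [(250.0, 1.0)])
        s = make_spectrum(shared + [(180.0, 1.0)], precursor=e.precursor_mz("PI"))
        assert isdb_spectral_match(s, [e]) == []

    def test_parent_mass_gate(self):
        e = entry()
        s = make_spectrum([(p.mz, p.intensity) for p in e.peaks],
                          precursor=e.precursor_mz("PI") + 0.05)
        assert isdb_spectral_match(s, [e]) == []

    def test_empty_library_is_empty_result(self):
        s = make_spectrum([(100.0, 1.0)])
        assert isdb_spectral_match(s, []) == []


class TestMs1Annotate:
    def test_in_species_adduct_match(self, toy_taxonomy):
        e = entry()
        taxon = resolve_taxon("Waltheria indica", toy_taxonomy)
        mz = adduct_mz(e.formula, "[M+Na]+")
        cands = ms1_annotate(mz, taxon, [e], ppm=10)
        assert [c.adduct for c in cands] == ["[M+Na]+"]
        assert cands[0].spectral_score == 0.0 and cands[0].source == "isdb_ms1"

    def test_out_of_species_excluded(self, toy_taxonomy):
        e = entry(taxa=("Datura stramonium",))
        taxon = resolve_taxon("Waltheria indica", toy_taxonomy)
        assert ms1_annotate(adduct_mz(e.formula, "[M+H]+"), taxon, [e]) == []

    def test_ppm_gate(self, toy_taxonomy):
        e = entry()
        taxon = resolve_taxon("Waltheria indica", toy_taxonomy)
        mz = adduct_mz(e.formula, "[M+H]+")
        assert ms1_annotate(mz * (1 + 12e-6), taxon, [e], ppm=10) == []
        assert len(ms1_annotate(mz * (1 + 5e-6), taxon, [e], ppm=10)) == 1


class TestTaxonomicReweight:
    def _cands(self, entries, spectral=0.5):
        out = []
        for e in entries:
            c_kwargs = dict(feature_id=1, structure_id=e.structure_id,
                            inchikey2d=e.inchikey2d, spectral_score=spectral,
                            n_matched_fragments=6, source="isdb_ms2")
            from metabokg.annotation import AnnotationCandidate
            c = AnnotationCandidate(**c_kwargs)
            c.recompute_final()
            out.append(c)
        return out

    def test_points_scale(self, toy_taxonomy):
        sample_taxon = resolve_taxon("Waltheria indica", toy_taxonomy)
        e_species = entry("LIBA", taxa=("Waltheria indica",))
        e_family = entry("LIBB", formula="C21H26O4", taxa=("Melochia umbellata",))
        e_none = entry("LIBC", formula="C22H28O4", taxa=("Unknown plant",))
        lib = {e.structure_id: e for e in (e_species, e_family, e_none)}
        cands = taxonomic_reweight(self._cands(lib.values()), sample_taxon, lib, toy_taxonomy)
        by_id = {c.structure_id: c for c in cands}
        assert by_id["LIBA"].taxo_score == 8
        assert by_id["LIBB"].taxo_score == 6  # same family -> passes the >=6 gate
        assert by_id["LIBC"].taxo_score == 0
        assert [c.structure_id for c in cands] == ["LIBA", "LIBB", "LIBC"]
        # final score convention: (spectral + taxo/8) * boost
        assert by_id["LIBA"].final_score == pytest.approx(0.5 + 8 / 8)

    def test_rank1_invariant_under_input_permutation(self, toy_taxonomy):
        sample_taxon = resolve_taxon("Waltheria indica", toy_taxonomy)
        entries = [entry(f"LIB{k}", formula=f"C2{k}H26O4", taxa=("Waltheria indica",))
                   for k in range(3, 7)]
        lib = {e.structure_id: e for e in entries}
        orders = [entries, entries[::-1], entries[2:] + entries[:2]]
        winners = set()
        for order in orders:
            cands = taxonomic_reweight(self._cands(order), sample_taxon, lib, toy_taxonomy)
            winners.add(cands[0].structure_id)
        assert len(winners) == 1

    def test_unresolved_sample_taxon_leaves_scores_zero(self, toy_taxonomy):
        e = entry()
        lib = {e.structure_id: e}
        cands = taxonomic_reweight(self._cands([e]), None, lib, toy_taxonomy)
        assert cands[0].taxo_score == 0


class TestChemicalConsistencyReweight:
    def _setup(self, classes, component_ids):
        entries = {}
        cands = {}
        from metabokg.annotation import AnnotationCandidate
        for fid, cls in classes.items():
            e = entry(f"L{fid}", formula=f"C{20 + fid}H26O4", npc_class=cls)
            entries[e.structure_id] = e
            c = AnnotationCandidate(feature_id=fid, structure_id=e.structure_id,
                                    inchikey2d=e.inchikey2d, spectral_score=0.8,
                                    n_matched_fragments=6, source="isdb_ms2")
            c.recompute_final()
            c.rank = 1
            cands[fid] = [c]
        edges = []
        ids = sorted(classes)
        net = MolecularNetwork(
            nodes=ids,
            edges=edges,
            components=[frozenset(c) for c in component_ids],
            params=MNParams(),
        )
        return net, cands, entries

    def test_modal_class_boosted(self):
        net, cands, lib = self._setup(
            {1: "Q", 2: "Q", 3: "Q", 4: "R"}, [{1, 2, 3, 4}]
        )
        out = chemical_consistency_reweight(net, cands, lib)
        assert out[1][0].consensus_boost == 1.5
        assert out[4][0].consensus_boost == 1.0

    def test_singleton_component_skipped(self):
        net, cands, lib = self._setup({1: "Q"}, [{1}])
        out = chemical_consistency_reweight(net, cands, lib)
        assert out[1][0].consensus_boost == 1.0

    def test_modal_tie_applies_no_boost(self):
        net, cands, lib = self._setup({1: "Q", 2: "Q", 3: "R", 4: "R"}, [{1, 2, 3, 4}])
        out = chemical_consistency_reweight(net, cands, lib)
        assert all(out[f][0].consensus_boost == 1.0 for f in out)


class TestExternalAnnotations:
    def test_sirius_rows_parsed(self, tmp_path):
        p = tmp_path / "sirius.tsv"
        p.write_text(
            "feature_id\tinchikey2d\tcosmic\tzodiac\tadduct\n"
            "1\tAAAAAAAAAAAAAA\t0.6\t0.9\t[M+H]+\n"
            "2\tBBBBBBBBBBBBBB\t0.4\t0.95\t[M+H]+\n"
            "3\tCCCCCCCCCCCCCC\t0.9\t0.85\t[M+Na]+\n"
        )
        anns = load_external_annotations(sirius_tsv=p)
        assert len(anns) == 3 and all(a.kind == "sirius_structure" for a in anns)

    def test_canopus_probability_row(self, tmp_path):
        p = tmp_path / "canopus.tsv"
        p.write_text("feature_id\tnpc_class\tclass_probability\n1\tQuinone methides\t0.6\n")
        (a,) = load_external_annotations(canopus_tsv=p)
        assert a.kind == "canopus_class" and a.scores["class_probability"] == 0.6

    def test_probability_above_one_rejected(self, tmp_path):
        p = tmp_path / "canopus.tsv"
        p.write_text("feature_id\tnpc_class\tclass_probability\n1\tX\t1.4\n")
        with pytest.raises(ValidationError):
            load_external_annotations(canopus_tsv=p)

    def test_missing_feature_id_column(self, tmp_path):
        p = tmp_path / "sirius.tsv"
        p.write_text("id\tinchikey2d\tcosmic\tzodiac\n1\tA\t0.5\t0.9\n")
        with pytest.raises(SchemaError):
            load_external_annotations(sirius_tsv=p)


class TestConfidenceFilter:
    def _sirius(self, cosmic, zodiac, fid=1):
        return ExternalAnnotation(fid, "sirius_structure", "A" * 14,
                                  {"cosmic": cosmic, "zodiac": zodiac})

    def _isdb(self, taxo, fid=1):
        from metabokg.annotation import AnnotationCandidate
        c = AnnotationCandidate(feature_id=fid, structure_id="L1", inchikey2d="B" * 14,
                                spectral_score=0.9, n_matched_fragments=8,
                                source="isdb_ms2", taxo_score=taxo, rank=1)
        c.recompute_final()
        return {fid: [c]}

    @pytest.mark.parametrize(
        "cosmic,zodiac,kept",
        [(0.6, 0.9, True), (0.6, 0.7, False), (0.5, 0.9, False),
         (0.51, 0.8, False), (0.51, 0.81, True)],
    )
    def test_sirius_gates_strict(self, cosmic, zodiac, kept):
        out = confidence_filter({}, [self._sirius(cosmic, zodiac)])
        assert (len(out) == 1) is kept

    @pytest.mark.parametrize("taxo,kept", [(8, True), (6, True), (5, False), (0, False)])
    def test_isdb_taxo_gate_inclusive(self, taxo, kept):
        out = confidence_filter(self._isdb(taxo), [])
        assert (len(out) == 1) is kept

    def test_union_records_gates(self):
        out = confidence_filter(self._isdb(7, fid=2), [self._sirius(0.9, 0.95, fid=1)])
        assert {(a.source, a.feature_id) for a in out} == {("sirius", 1), ("isdb", 2)}
        assert all(a.gate for a in out)


class TestChemblIngest:
    def test_np_unlike_rows_filtered(self, tmp_path):
        p = tmp_path / "chembl.tsv"
        p.write_text(
            "inchikey2d\ttarget\tactivity_type\tactivity_value\tnp_likeness\n"
            "AAAAAAAAAAAAAA\tT. cruzi\tIC50\t1.0\t1.5\n"
            "BBBBBBBBBBBBBB\tT. cruzi\tIC50\t2.0\t-2.0\n"
            "CCCCCCCCCCCCCC\tT. cruzi\tIC50\t3.0\t-1.0\n"
        )
        df = load_chembl_table(p)
        # > -1 is strict: the -1.0 row is excluded too
        assert list(df["inchikey2d"]) == ["AAAAAAAAAAAAAA"]
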