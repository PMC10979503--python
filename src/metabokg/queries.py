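"""Cross-sample queries over the merged knowledge graph.

Each query is a pure function of the graph: the graph is first distilled into
an in-memory index (feature table, document words, annotations, bioactivity),
then queried with deterministic row ordering, so results are testable without
a triple-store server.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from rdflib import Graph, RDF, RDFS

from metabokg.annotation import PROTON_MASS, ConfidenceThresholds
from metabokg.errors import ParameterError, ValidationError
from metabokg.ingest import FeatureList
from metabokg.kg import ENPKG, ENPKGMODULE


@dataclass
class QueryResult:
    """Rows plus the provenance (query name and parameters) that produced them."""

    rows: list[dict]
    query: str
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        params = ",".join(f"{k}={v}" for k, v in sorted(self.parameters.items()))
        header = f"# query={self.query} {params}".rstrip()
        body = self.to_dataframe().to_csv(index=False)
        Path(path).write_text(header + "\n" + body)


@dataclass
class _FeatureInfo:
    iri: str
    sample_id: str
    polarity: str
    feature_id: int
    mz: float = 0.0
    rt: float = 0.0


class GraphIndex:
    """In-memory index distilled from the RDF graph, on which every query runs."""

    def __init__(self) -> None:
        self.samples: dict[str, dict] = {}
        self.features: dict[str, _FeatureInfo] = {}
        self.words: dict[str, frozenset[str]] = {}
        self.isdb: dict[str, dict] = {}  # feature iri -> rank-1 info
        self.sirius: dict[str, dict] = {}
        self.canopus: dict[str, dict] = {}
        self.bioactivity: dict[str, dict[str, float]] = {}
        self.structure_taxa: dict[str, tuple[str, ...]] = {}
        self.chembl: list[dict] = []

    @classmethod
    def from_graph(cls, g: Graph) -> "GraphIndex":
        idx = cls()
        str_value = {}
        for snode, val in g.subject_objects(ENPKG.has_inchikey2d_value):
            str_value[snode] = str(val)

        for sample in g.subjects(RDF.type, ENPKG.Sample):
            sid = str(sample).rsplit("sample_", 1)[-1]
            info = {"iri": str(sample), "sample_type": "", "source_id": "", "taxon": ""}
            for t in g.objects(sample, ENPKG.has_sample_type):
                info["sample_type"] = str(t)
            for t in g.objects(sample, ENPKG.has_source_id):
                info["source_id"] = str(t)
            for tnode in g.objects(sample, ENPKG.has_taxon):
                for label in g.objects(tnode, ENPKG.has_species):
                    info["taxon"] = str(label)
            idx.samples[sid] = info

            for bnode in g.objects(sample, ENPKGMODULE.has_bioassay_result):
                assay = pct = None
                for a in g.objects(bnode, ENPKGMODULE.has_assay_target):
                    assay = str(a)
                for p in g.objects(bnode, ENPKGMODULE.has_percent_inhibition):
                    pct = float(p)
                if assay is not None and pct is not None:
                    idx.bioactivity.setdefault(sid, {})[assay] = pct

            for analysis in g.objects(sample, ENPKG.has_lcms_analysis):
                pol = ""
                for p in g.objects(analysis, ENPKG.has_polarity):
                    pol = str(p)
                for flnode in g.objects(analysis, ENPKG.has_lcms_feature_list):
                    for fnode in g.objects(flnode, ENPKG.has_lcms_feature):
                        fi = _FeatureInfo(str(fnode), sid, pol, 0)
                        for v in g.objects(fnode, ENPKG.has_feature_id):
                            fi.feature_id = int(v)
                        for v in g.objects(fnode, ENPKG.has_parent_mass):
                            fi.mz = float(v)
                        for v in g.objects(fnode, ENPKG.has_retention_time):
                            fi.rt = float(v)
                        idx.features[str(fnode)] = fi

                        for dnode in g.objects(fnode, ENPKG.has_spec2vec_doc):
                            words = set()
                            for pred in (ENPKG.has_spec2vec_peak, ENPKG.has_spec2vec_loss):
                                for wnode in g.objects(dnode, pred):
                                    labels = list(g.objects(wnode, RDFS.label))
                                    if labels:
                                        words.add(str(labels[0]))
                            idx.words[str(fnode)] = frozenset(words)

                        for anode in g.objects(fnode, ENPKG.has_isdb_annotation):
                            rank = min((int(r) for r in g.objects(anode, ENPKG.has_rank)),
                                       default=1)
                            if rank != 1:
                                continue
                            rec = {"rank": rank}
                            for v in g.objects(anode, ENPKG.has_InChIkey2D):
                                rec["inchikey2d"] = str_value.get(
                                    v, str(v).rsplit("structure_", 1)[-1]
                                )
                            for v in g.objects(anode, ENPKG.has_taxo_score):
                                rec["taxo_score"] = int(v)
                            for v in g.objects(anode, ENPKG.has_spectral_score):
                                rec["spectral_score"] = float(v)
                            idx.isdb[str(fnode)] = rec

                        for anode in g.objects(fnode, ENPKG.has_sirius_annotation):
                            rec = {}
                            for v in g.objects(anode, ENPKG.has_InChIkey2D):
                                rec["inchikey2d"] = str_value.get(
                                    v, str(v).rsplit("structure_", 1)[-1]
                                )
                            for v in g.objects(anode, ENPKG.has_cosmic_score):
                                rec["cosmic"] = float(v)
                            for v in g.objects(anode, ENPKG.has_zodiac_score):
                                rec["zodiac"] = float(v)
                            for v in g.objects(anode, ENPKG.has_adduct):
                                rec["adduct"] = str(v)
                            idx.sirius[str(fnode)] = rec

                        for anode in g.objects(fnode, ENPKG.has_canopus_annotation):
                            rec = {}
                            for v in g.objects(anode, ENPKG.has_canopus_npc_class):
                                rec["npc_class"] = str(v)
                            for v in g.objects(anode, ENPKG.has_class_probability):
                                rec["probability"] = float(v)
                            idx.canopus[str(fnode)] = rec

        for snode in g.subjects(RDF.type, ENPKG.ChemicalStructure):
            ik = str_value.get(snode, str(snode).rsplit("structure_", 1)[-1])
            taxa = tuple(sorted(str(t) for t in g.objects(snode, ENPKG.reported_in_taxon)))
            if taxa or ik not in idx.structure_taxa:
                idx.structure_taxa[ik] = taxa

        for anode in g.subjects(RDF.type, ENPKGMODULE.ChEMBLActivity):
            rec = {}
            for snode in g.subjects(ENPKGMODULE.has_chembl_activity, anode):
                rec["inchikey2d"] = str_value.get(snode, str(snode).rsplit("structure_", 1)[-1])
            for v in g.objects(anode, ENPKGMODULE.has_activity_target):
                rec["target"] = str(v)
            for v in g.objects(anode, ENPKGMODULE.has_activity_value):
                rec["activity_value"] = float(v)
            for v in g.objects(anode, ENPKGMODULE.has_np_likeness):
                rec["np_likeness"] = float(v)
            if "inchikey2d" in rec:
                idx.chembl.append(rec)
        idx.chembl.sort(key=lambda r: (r.get("inchikey2d", ""), r.get("target", "")))
        return idx


def _as_index(graph_or_index) -> GraphIndex:
    if isinstance(graph_or_index, GraphIndex):
        return graph_or_index
    return GraphIndex.from_graph(graph_or_index)


# ---------------------------------------------------------------------------
# queries

def shared_words_ranking(query_feature: str, graph_or_index, top_k: int = 10) -> QueryResult:
    """Rank all other features (any sample, any analysis) by the number of
    peak/loss document words shared with the query feature; zero-overlap
    features are excluded, ties break by feature IRI."""
    idx = _as_index(graph_or_index)
    if query_feature not in idx.words:
        raise ValidationError(f"feature {query_feature} has no spectral document")
    qwords = idx.words[query_feature]
    scored = []
    for firi, words in idx.words.items():
        if firi == query_feature:
            continue
        n = len(qwords & words)
        if n > 0:
            scored.append((n, firi))
    scored.sort(key=lambda t: (-t[0], t[1]))
    rows = [
        {
            "feature": firi,
            "sample_id": idx.features[firi].sample_id if firi in idx.features else "",
            "shared_words": n,
        }
        for n, firi in scored[:top_k]
    ]
    return QueryResult(rows, "shared_words_ranking",
                       {"query_feature": query_feature, "top_k": top_k})


def class_count_per_sample(graph_or_index, npc_class: str,
                           prob_cutoff: float = 0.5) -> QueryResult:
    """Samples ordered by their count of features carrying the given chemical
    class with probability strictly above the cutoff."""
    idx = _as_index(graph_or_index)
    counts: dict[str, int] = {}
    for firi, rec in idx.canopus.items():
        if rec.get("npc_class") == npc_class and rec.get("probability", 0.0) > prob_cutoff:
            sid = idx.features[firi].sample_id
            counts[sid] = counts.get(sid, 0) + 1
    rows = [
        {"sample_id": sid, "count": n}
        for sid, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return QueryResult(rows, "class_count_per_sample",
                       {"npc_class": npc_class, "prob_cutoff": prob_cutoff})


def annotation_agreement(graph_or_index) -> QueryResult:
    """Features whose rank-1 ISDB and SIRIUS structure annotations share a 2D
    InChIKey (stereoisomers count as agreement)."""
    idx = _as_index(graph_or_index)
    rows = []
    for firi in sorted(set(idx.isdb) & set(idx.sirius)):
        ik_isdb = idx.isdb[firi].get("inchikey2d")
        ik_sirius = idx.sirius[firi].get("inchikey2d")
        if ik_isdb and ik_isdb == ik_sirius:
            rows.append(
                {"feature": firi, "sample_id": idx.features[firi].sample_id,
                 "inchikey2d": ik_isdb}
            )
    return QueryResult(rows, "annotation_agreement", {})


def cross_polarity_pairs(graph_or_index, rt_tol: float = 3.0, ppm: float = 5.0) -> QueryResult:
    """PI features paired with a same-sample NI feature at the same retention
    time (±rt_tol s) whose mass matches the deprotonated ion (±ppm).

    When SIRIUS annotations exist, PI features are restricted to those
    annotated as [M+H]+; otherwise all PI features are considered (flagged in
    the result parameters).
    """
    idx = _as_index(graph_or_index)
    have_sirius = any(rec.get("adduct") for rec in idx.sirius.values())
    pi = []
    for firi, fi in idx.features.items():
        if fi.polarity != "PI":
            continue
        if have_sirius:
            if idx.sirius.get(firi, {}).get("adduct") != "[M+H]+":
                continue
        pi.append(fi)
    ni = [fi for fi in idx.features.values() if fi.polarity == "NI"]
    rows = []
    for p in sorted(pi, key=lambda f: f.iri):
        expected = p.mz - 2 * PROTON_MASS
        for n in sorted(ni, key=lambda f: f.iri):
            if n.sample_id != p.sample_id:
                continue
            if abs(p.rt - n.rt) > rt_tol:
                continue
            if abs(n.mz - expected) / n.mz <= ppm * 1e-6:
                rows.append(
                    {"pi_feature": p.iri, "ni_feature": n.iri, "sample_id": p.sample_id,
                     "pi_mz": p.mz, "ni_mz": n.mz, "rt": p.rt}
                )
    return QueryResult(rows, "cross_polarity_pairs",
                       {"rt_tol": rt_tol, "ppm": ppm,
                        "restricted_to_MplusH": have_sirius})


def same_annotation_cross_polarity(graph_or_index, rt_tol: float = 3.0) -> QueryResult:
    """PI/NI feature pairs of one sample within ±rt_tol s carrying the same
    SIRIUS 2D InChIKey."""
    idx = _as_index(graph_or_index)
    pi = [(f, idx.sirius[f.iri]["inchikey2d"]) for f in idx.features.values()
          if f.polarity == "PI" and f.iri in idx.sirius and "inchikey2d" in idx.sirius[f.iri]]
    ni = [(f, idx.sirius[f.iri]["inchikey2d"]) for f in idx.features.values()
          if f.polarity == "NI" and f.iri in idx.sirius and "inchikey2d" in idx.sirius[f.iri]]
    rows = []
    for p, ik_p in sorted(pi, key=lambda t: t[0].iri):
        for n, ik_n in sorted(ni, key=lambda t: t[0].iri):
            if n.sample_id == p.sample_id and abs(p.rt - n.rt) <= rt_tol and ik_p == ik_n:
                rows.append(
                    {"pi_feature": p.iri, "ni_feature": n.iri,
                     "sample_id": p.sample_id, "inchikey2d": ik_p}
                )
    return QueryResult(rows, "same_annotation_cross_polarity", {"rt_tol": rt_tol})


def fragment_presence(
    feature_lists: Iterable[FeatureList],
    frag_mz: float = 201.09,
    min_rel: float = 0.5,
    tol: float = 0.01,
) -> QueryResult:
    """Features whose spectrum contains a peak at frag_mz (±tol) with relative
    intensity at least min_rel of the base peak (the single-fragment MassQL
    pattern). Runs on spectra, which retain intensities the graph does not."""
    rows = []
    for fl in feature_lists:
        for f in fl:
            peaks = f.spectrum.peaks
            if not peaks:
                continue
            base = max(p.intensity for p in peaks)
            for p in peaks:
                if abs(p.mz - frag_mz) <= tol and p.intensity >= min_rel * base:
                    rows.append(
                        {"sample_id": fl.sample_id, "polarity": fl.polarity,
                         "feature_id": f.feature_id, "fragment_mz": p.mz,
                         "relative_intensity": p.intensity / base}
                    )
                    break
    rows.sort(key=lambda r: (r["sample_id"], r["polarity"], r["feature_id"]))
    return QueryResult(rows, "fragment_presence",
                       {"frag_mz": frag_mz, "min_rel": min_rel, "tol": tol})


def _annotated_structures_by_sample(idx: GraphIndex) -> dict[str, set[str]]:
    """Structures annotated per sample (rank-1 ISDB union SIRIUS)."""
    per_sample: dict[str, set[str]] = {}
    for firi, rec in idx.isdb.items():
        ik = rec.get("inchikey2d")
        if ik:
            per_sample.setdefault(idx.features[firi].sample_id, set()).add(ik)
    for firi, rec in idx.sirius.items():
        ik = rec.get("inchikey2d")
        if ik:
            per_sample.setdefault(idx.features[firi].sample_id, set()).add(ik)
    return per_sample


def group_specificity(graph_or_index, group: Iterable[str]) -> QueryResult:
    """Per annotated structure: in how many group samples it occurs
    (count_in_group) and the fraction of all its annotated samples that lie in
    the group (group_specificity); sorted by (specificity, count) descending."""
    idx = _as_index(graph_or_index)
    group = set(group)
    if not group:
        raise ValidationError("empty sample group")
    unknown = group - set(idx.samples)
    if unknown:
        raise ValidationError(f"group samples not in graph: {sorted(unknown)}")
    per_sample = _annotated_structures_by_sample(idx)
    all_structures = sorted({ik for s in per_sample.values() for ik in s})
    rows = []
    for ik in all_structures:
        samples_with = {sid for sid, s in per_sample.items() if ik in s}
        cig = len(samples_with & group)
        spec = cig / len(samples_with) if samples_with else 0.0
        rows.append({"inchikey2d": ik, "count_in_group": cig, "group_specificity": spec})
    rows.sort(key=lambda r: (-r["group_specificity"], -r["count_in_group"], r["inchikey2d"]))
    return QueryResult(rows, "group_specificity", {"group": sorted(group)})


def activity_filters(
    graph_or_index,
    assay: str,
    active_min_inhibition: float,
    cytotox_assay: str = "cytotoxicity",
    cytotox_max: float = 100.0,
) -> QueryResult:
    """Extracts active in the given assay (inhibition >= active_min) and
    non-cytotoxic (cytotoxicity inhibition <= cytotox_max). Thresholds are
    mandatory study choices; there is no silent default for activity."""
    idx = _as_index(graph_or_index)
    assays = {a for d in idx.bioactivity.values() for a in d}
    if assay not in assays:
        raise ParameterError(f"unknown assay {assay!r}; graph has {sorted(assays)}")
    rows = []
    for sid in sorted(idx.bioactivity):
        d = idx.bioactivity[sid]
        if assay not in d:
            continue
        if d[assay] >= active_min_inhibition and d.get(cytotox_assay, 0.0) <= cytotox_max:
            rows.append(
                {"sample_id": sid, "inhibition": d[assay],
                 "cytotoxicity": d.get(cytotox_assay, float("nan"))}
            )
    return QueryResult(rows, "activity_filters",
                       {"assay": assay, "active_min_inhibition": active_min_inhibition,
                        "cytotox_assay": cytotox_assay, "cytotox_max": cytotox_max})


def chembl_activity_join(
    graph_or_index,
    target: str,
    thresholds: ConfidenceThresholds | None = None,
) -> QueryResult:
    """Confidently annotated structures with reported activity against the
    target, plus the taxa in which each structure is reported.

    Confidence uses the standard gates (SIRIUS cosmic > 0.5 and zodiac > 0.8;
    ISDB taxo_score >= 6); activity rows were NP-likeness filtered on ingest.
    """
    idx = _as_index(graph_or_index)
    th = thresholds or ConfidenceThresholds()
    confident: dict[str, set[str]] = {}  # ik -> sample ids
    for firi, rec in idx.isdb.items():
        if rec.get("taxo_score", 0) >= th.taxo and rec.get("inchikey2d"):
            confident.setdefault(rec["inchikey2d"], set()).add(idx.features[firi].sample_id)
    for firi, rec in idx.sirius.items():
        if (rec.get("cosmic", 0.0) > th.cosmic and rec.get("zodiac", 0.0) > th.zodiac
                and rec.get("inchikey2d")):
            confident.setdefault(rec["inchikey2d"], set()).add(idx.features[firi].sample_id)
    rows = []
    for act in idx.chembl:
        ik = act["inchikey2d"]
        if act.get("target") != target or ik not in confident:
            continue
        rows.append(
            {"inchikey2d": ik, "target": target,
             "activity_value": act.get("activity_value"),
             "annotated_in_samples": ";".join(sorted(confident[ik])),
             "reported_taxa": ";".join(idx.structure_taxa.get(ik, ()))}
        )
    rows.sort(key=lambda r: (r["inchikey2d"], r["activity_value"]))
    return QueryResult(rows, "chembl_activity_join", {"target": target})


def tanimoto_filter(
    fingerprints: Mapping[str, Sequence[int]],
    reference: str | Sequence[int],
    min_sim: float = 0.8,
) -> QueryResult:
    """Structures whose Tanimoto similarity |a∧b|/|a∨b| to the reference
    fingerprint is at least min_sim (inclusive). Fingerprints are externally
    supplied equal-length bit vectors."""
    ref = fingerprints[reference] if isinstance(reference, str) else reference
    ref = [int(bool(b)) for b in ref]
    rows = []
    for name in sorted(fingerprints):
        fp = [int(bool(b)) for b in fingerprints[name]]
        if len(fp) != len(ref):
            raise ValidationError(
                f"fingerprint length mismatch for {name}: {len(fp)} != {len(ref)}"
            )
        inter = sum(a & b for a, b in zip(fp, ref))
        union = sum(a | b for a, b in zip(fp, ref))
        sim = inter / union if union else 0.0
        if sim >= min_sim:
            rows.append({"structure": name, "tanimoto": sim})
    rows.sort(key=lambda r: (-r["tanimoto"], r["structure"]))
    return QueryResult(rows, "tanimoto_filter",
                       {"reference": reference if isinstance(reference, str) else "<vector>",
                        "min_sim": min_sim})
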