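"""RDF knowledge-graph emission: hash-minted provenance IRIs, per-sample
Turtle graphs, deterministic serialization and incremental merging.

Every processing step's parameters are serialized canonically (sorted keys)
and hashed into the IRI of the node they produced, so two runs with identical
parameters mint identical IRIs and the provenance of every artifact is
queryable. Per-sample graphs are standalone; the study graph is their set
union, with shared nodes (taxa, structures, document words) deduplicating by
IRI.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from metabokg.errors import ValidationError
from metabokg.ingest import FeatureList, SampleRecord
from metabokg.annotation import (
    AnnotationCandidate,
    ExternalAnnotation,
    LibraryEntry,
)
from metabokg.spectral import MolecularNetwork, SpectralDocument
from metabokg.taxonomy import RANKS, TaxonRecord

ENPKG = Namespace("https://enpkg.commons-lab.org/kg/")
ENPKGMODULE = Namespace("https://enpkg.commons-lab.org/module/")

_PREFIXES = {
    "enpkg": ENPKG,
    "enpkgmodule": ENPKGMODULE,
    "rdf": RDF,
    "rdfs": RDFS,
    "xsd": XSD,
}

_LOCAL_RE = re.compile(r"[^A-Za-z0-9_]")


def _sanitize(name: str) -> str:
    return _LOCAL_RE.sub("_", name)


def mint_iri(kind: str, payload: Mapping, namespace: Namespace = ENPKG) -> URIRef:
    """Mint ``<namespace><kind>_<hash>`` from a canonical serialization of the
    payload: 128-bit hex digest of the sorted-key JSON, stable across runs,
    platforms and key orderings."""
    try:
        canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    except TypeError as exc:
        raise ValidationError(f"payload not canonically serializable: {exc}") from exc
    digest = hashlib.md5(canonical.encode()).hexdigest()
    return namespace[f"{_sanitize(kind)}_{digest}"]


def _lit(value) -> Literal:
    """Typed literal with a lexical form that survives Turtle round-trips."""
    if isinstance(value, bool):
        return Literal(value)
    if isinstance(value, int):
        return Literal(str(value), datatype=XSD.integer)
    if isinstance(value, float):
        return Literal(repr(value), datatype=XSD.double)
    return Literal(str(value), datatype=XSD.string)


@dataclass
class SampleBundle:
    """Everything known about one sample: metadata, resolved taxon, per-polarity
    analyses and their downstream products. The unit of incremental KG
    addition."""

    record: SampleRecord
    taxon: Optional[TaxonRecord] = None
    feature_lists: dict[str, FeatureList] = field(default_factory=dict)
    networks: dict[str, MolecularNetwork] = field(default_factory=dict)
    documents: dict[str, list[SpectralDocument]] = field(default_factory=dict)
    isdb_annotations: dict[str, dict[int, list[AnnotationCandidate]]] = field(default_factory=dict)
    external_annotations: dict[str, list[ExternalAnnotation]] = field(default_factory=dict)
    bioactivity: dict[str, float] = field(default_factory=dict)  # assay -> % inhibition
    parameters: dict[str, Mapping] = field(default_factory=dict)  # step -> params


def new_graph() -> Graph:
    g = Graph()
    for prefix, ns in _PREFIXES.items():
        g.bind(prefix, ns)
    return g


def _word_node(word: str) -> URIRef:
    return ENPKG[f"spec2vec_{_sanitize(word)}"]


def _taxon_node(taxon: TaxonRecord) -> URIRef:
    return ENPKG[f"taxon_{_sanitize(taxon.matched_name)}"]


def _structure_node(inchikey2d: str) -> URIRef:
    return ENPKG[f"structure_{_sanitize(inchikey2d)}"]


def sample_to_triples(
    bundle: SampleBundle,
    library_by_id: Mapping[str, LibraryEntry] | None = None,
    max_annotation_rank: int = 1,
) -> Graph:
    """Emit the standalone RDF graph of one sample bundle.

    Sample → taxon (lineage, external ids); per polarity an analysis node →
    feature-list node (parameter-hashed IRI) → feature nodes (m/z, RT, area) →
    document node → word nodes; annotation nodes with typed scores; structure
    nodes keyed by InChIKey2D; bioactivity result nodes. Annotations referring
    to unknown features raise a validation error.
    """
    g = new_graph()
    rec = bundle.record
    sample = ENPKG[f"sample_{_sanitize(rec.sample_id)}"]
    g.add((sample, RDF.type, ENPKG.Sample))
    g.add((sample, ENPKG.has_sample_type, _lit(rec.sample_type)))
    g.add((sample, ENPKG.has_source_id, _lit(rec.source_id)))

    if bundle.taxon is not None:
        tnode = _taxon_node(bundle.taxon)
        g.add((sample, ENPKG.has_taxon, tnode))
        g.add((tnode, RDF.type, ENPKG.Taxon))
        g.add((tnode, RDFS.label, _lit(bundle.taxon.matched_name)))
        for rank in RANKS:
            name = bundle.taxon.lineage.get(rank)
            if name:
                g.add((tnode, ENPKG[f"has_{rank}"], _lit(name)))
        for source, ident in sorted(bundle.taxon.external_ids.items()):
            g.add((tnode, ENPKG[f"has_{source}_id"], _lit(ident)))

    library_by_id = library_by_id or {}

    for pol, fl in sorted(bundle.feature_lists.items()):
        analysis = ENPKG[f"analysis_{_sanitize(rec.sample_id)}_{pol}"]
        g.add((sample, ENPKG.has_lcms_analysis, analysis))
        g.add((analysis, RDF.type, ENPKG.LCMSAnalysis))
        g.add((analysis, ENPKG.has_polarity, _lit(pol)))

        fl_params = dict(bundle.parameters.get(f"feature_list_{pol}", {}))
        fl_params.update({"sample_id": rec.sample_id, "polarity": pol})
        fl_node = mint_iri("lcms_feature_list", fl_params)
        g.add((analysis, ENPKG.has_lcms_feature_list, fl_node))
        g.add((fl_node, RDF.type, ENPKG.LCMSFeatureList))

        known_features = set()
        feature_nodes = {}
        for f in fl:
            fnode = ENPKG[f"feature_{_sanitize(rec.sample_id)}_{pol}_{f.feature_id}"]
            feature_nodes[f.feature_id] = fnode
            known_features.add(f.feature_id)
            g.add((fl_node, ENPKG.has_lcms_feature, fnode))
            g.add((fnode, RDF.type, ENPKG.LCMSFeature))
            g.add((fnode, ENPKG.has_feature_id, _lit(f.feature_id)))
            g.add((fnode, ENPKG.has_parent_mass, _lit(f.mz)))
            g.add((fnode, ENPKG.has_retention_time, _lit(f.rt)))
            g.add((fnode, ENPKG.has_feature_area, _lit(f.area)))
            g.add((fnode, ENPKG.has_polarity, _lit(pol)))

        for doc in bundle.documents.get(pol, []):
            if doc.feature_id not in known_features:
                raise ValidationError(
                    f"document for unknown feature {doc.feature_id} in {rec.sample_id}/{pol}"
                )
            fnode = feature_nodes[doc.feature_id]
            dnode = ENPKG[f"document_{_sanitize(rec.sample_id)}_{pol}_{doc.feature_id}"]
            g.add((fnode, ENPKG.has_spec2vec_doc, dnode))
            g.add((dnode, RDF.type, ENPKG.Spec2VecDoc))
            for word in doc.peak_words:
                w = _word_node(word)
                g.add((dnode, ENPKG.has_spec2vec_peak, w))
                g.add((w, RDFS.label, _lit(word)))
            for word in doc.loss_words:
                w = _word_node(word)
                g.add((dnode, ENPKG.has_spec2vec_loss, w))
                g.add((w, RDFS.label, _lit(word)))

        net = bundle.networks.get(pol)
        if net is not None:
            mn_params = {
                "fragment_tol": net.params.fragment_tol,
                "score_cutoff": net.params.score_cutoff,
                "top_n": net.params.top_n,
                "max_links": net.params.max_links,
                "min_matched_peaks": net.params.min_matched_peaks,
                "sample_id": rec.sample_id,
                "polarity": pol,
            }
            mn_node = mint_iri("mn_params", mn_params)
            g.add((analysis, ENPKG.has_mn_params, mn_node))
            comp_of = net.component_of()
            for fid, comp in sorted(comp_of.items()):
                if fid in feature_nodes:
                    g.add((feature_nodes[fid], ENPKG.has_mn_component, _lit(comp)))

        for fid, cands in sorted(bundle.isdb_annotations.get(pol, {}).items()):
            if fid not in known_features:
                raise ValidationError(
                    f"ISDB annotation for unknown feature {fid} in {rec.sample_id}/{pol}"
                )
            for c in cands:
                if c.rank > max_annotation_rank:
                    continue
                anode = ENPKG[
                    f"isdb_annotation_{_sanitize(rec.sample_id)}_{pol}_{fid}_{c.rank}"
                ]
                g.add((feature_nodes[fid], ENPKG.has_isdb_annotation, anode))
                g.add((anode, RDF.type, ENPKG.IsdbAnnotation))
                g.add((anode, ENPKG.has_spectral_score, _lit(c.spectral_score)))
                g.add((anode, ENPKG.has_taxo_score, _lit(c.taxo_score)))
                g.add((anode, ENPKG.has_consensus_score, _lit(c.final_score)))
                g.add((anode, ENPKG.has_rank, _lit(c.rank)))
                g.add((anode, ENPKG.has_annotation_source, _lit(c.source)))
                snode = _structure_node(c.inchikey2d)
                g.add((anode, ENPKG.has_InChIkey2D, snode))
                _add_structure(g, c.inchikey2d, library_by_id.get(c.structure_id))

        for ann in bundle.external_annotations.get(pol, []):
            if ann.feature_id not in known_features:
                raise ValidationError(
                    f"external annotation for unknown feature {ann.feature_id} "
                    f"in {rec.sample_id}/{pol}"
                )
            fnode = feature_nodes[ann.feature_id]
            if ann.kind == "sirius_structure":
                anode = ENPKG[
                    f"sirius_annotation_{_sanitize(rec.sample_id)}_{pol}_{ann.feature_id}"
                ]
                g.add((fnode, ENPKG.has_sirius_annotation, anode))
                g.add((anode, RDF.type, ENPKG.SiriusStructureAnnotation))
                g.add((anode, ENPKG.has_InChIkey2D, _structure_node(ann.value)))
                g.add((anode, ENPKG.has_cosmic_score, _lit(float(ann.scores["cosmic"]))))
                g.add((anode, ENPKG.has_zodiac_score, _lit(float(ann.scores["zodiac"]))))
                if ann.adduct:
                    g.add((anode, ENPKG.has_adduct, _lit(ann.adduct)))
                _add_structure(g, ann.value, None)
            elif ann.kind == "canopus_class":
                anode = ENPKG[
                    f"canopus_annotation_{_sanitize(rec.sample_id)}_{pol}_{ann.feature_id}"
                ]
                g.add((fnode, ENPKG.has_canopus_annotation, anode))
                g.add((anode, RDF.type, ENPKG.CanopusAnnotation))
                g.add((anode, ENPKG.has_canopus_npc_class, _lit(ann.value)))
                g.add(
                    (anode, ENPKG.has_class_probability,
                     _lit(float(ann.scores["class_probability"])))
                )

    for assay, pct in sorted(bundle.bioactivity.items()):
        bnode = ENPKGMODULE[f"bioassay_{_sanitize(rec.sample_id)}_{_sanitize(assay)}"]
        g.add((sample, ENPKGMODULE.has_bioassay_result, bnode))
        g.add((bnode, RDF.type, ENPKGMODULE.BioAssayResult))
        g.add((bnode, ENPKGMODULE.has_assay_target, _lit(assay)))
        g.add((bnode, ENPKGMODULE.has_percent_inhibition, _lit(float(pct))))

    return g


def _add_structure(g: Graph, inchikey2d: str, entry: Optional[LibraryEntry]) -> None:
    snode = _structure_node(inchikey2d)
    g.add((snode, RDF.type, ENPKG.ChemicalStructure))
    g.add((snode, ENPKG.has_inchikey2d_value, _lit(inchikey2d)))
    if entry is not None:
        g.add((snode, ENPKG.has_smiles, _lit(entry.smiles)))
        g.add((snode, ENPKG.has_formula, _lit(entry.formula)))
        g.add((snode, ENPKG.has_exact_mass, _lit(entry.exact_mass)))
        if entry.npc_pathway:
            g.add((snode, ENPKG.has_npc_pathway, _lit(entry.npc_pathway)))
        if entry.npc_superclass:
            g.add((snode, ENPKG.has_npc_superclass, _lit(entry.npc_superclass)))
        if entry.npc_class:
            g.add((snode, ENPKG.has_npc_class, _lit(entry.npc_class)))
        for taxon in entry.taxa:
            g.add((snode, ENPKG.reported_in_taxon, _lit(taxon)))


def chembl_to_triples(activity_df) -> Graph:
    """Activity rows (already NP-likeness filtered on ingest) as module triples
    hanging off the structure nodes."""
    g = new_graph()
    for idx, row in activity_df.iterrows():
        snode = _structure_node(str(row["inchikey2d"]))
        anode = ENPKGMODULE[
            f"chembl_activity_{_sanitize(str(row['inchikey2d']))}_{_sanitize(str(row['target']))}_{idx}"
        ]
        g.add((snode, RDF.type, ENPKG.ChemicalStructure))
        g.add((snode, ENPKG.has_inchikey2d_value, _lit(str(row["inchikey2d"]))))
        g.add((snode, ENPKGMODULE.has_chembl_activity, anode))
        g.add((anode, RDF.type, ENPKGMODULE.ChEMBLActivity))
        g.add((anode, ENPKGMODULE.has_activity_target, _lit(str(row["target"]))))
        g.add((anode, ENPKGMODULE.has_activity_type, _lit(str(row["activity_type"]))))
        g.add((anode, ENPKGMODULE.has_activity_value, _lit(float(row["activity_value"]))))
        g.add((anode, ENPKGMODULE.has_np_likeness, _lit(float(row["np_likeness"]))))
    return g


def serialize_turtle(g: Graph, path: str | Path | None = None) -> str:
    """Deterministic Turtle: prefix block, then one triple per line sorted by
    (subject, predicate, object). Two serializations of equal graphs are
    byte-identical; serialize → parse → serialize is a fixed point."""
    nm = new_graph().namespace_manager
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(_PREFIXES.items())]
    lines.append("")
    rendered = sorted(
        f"{s.n3(nm)} {p.n3(nm)} {o.n3(nm)} ." for s, p, o in g
    )
    text = "\n".join(lines + rendered) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_turtle(source: str | Path) -> Graph:
    """Parse a Turtle file (or literal text) back into a graph."""
    g = new_graph()
    if isinstance(source, Path) or "\n" not in str(source):
        g.parse(str(source), format="turtle")
    else:
        g.parse(data=str(source), format="turtle")
    return g


def merge_graphs(graphs: Iterable[Graph]) -> Graph:
    """Set union of per-sample graphs; shared nodes deduplicate by IRI.
    Idempotent and incremental: merging never removes or alters triples."""
    merged = new_graph()
    for g in graphs:
        for triple in g:
            merged.add(triple)
    return merged


def validate_graph(g: Graph) -> None:
    """Graph-walk assertions: every annotation node hangs off exactly one
    feature and every feature off exactly one feature list / sample chain."""
    ann_preds = (ENPKG.has_isdb_annotation, ENPKG.has_sirius_annotation,
                 ENPKG.has_canopus_annotation)
    parents: dict = {}
    for pred in ann_preds:
        for fnode, anode in g.subject_objects(pred):
            parents.setdefault(anode, set()).add(fnode)
    for anode, fs in parents.items():
        if len(fs) != 1:
            raise ValidationError(f"annotation {anode} reachable from {len(fs)} features")
    feature_parent: dict = {}
    for flnode, fnode in g.subject_objects(ENPKG.has_lcms_feature):
        feature_parent.setdefault(fnode, set()).add(flnode)
    for fnode, fls in feature_parent.items():
        if len(fls) != 1:
            raise ValidationError(f"feature {fnode} linked to {len(fls)} feature lists")
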