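"""End-to-end orchestration: run every stage over a study directory produced
by the fixture generator (or laid out the same way) and assemble the merged
knowledge graph.

This is thin glue over the stage modules — each step below is independently
usable; the pipeline only fixes the order (ingest → taxonomy → networking →
documents → MEMO → annotation → KG) and collects the per-sample bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdflib import Graph

from metabokg import annotation as ann
from metabokg import kg as kgm
from metabokg.ingest import FeatureList, SampleRecord, parse_sample_metadata, read_feature_bundle
from metabokg.memo import build_memo_matrix
from metabokg.queries import GraphIndex
from metabokg.spectral import MNParams, build_molecular_network, documents_for_feature_list
from metabokg.taxonomy import TaxonomyTable, resolve_taxon


@dataclass
class StudyResult:
    """Everything the pipeline produced for one study directory."""

    bundles: dict[str, kgm.SampleBundle]
    graph: Graph
    index: GraphIndex
    memo_matrix: pd.DataFrame
    records: list[SampleRecord] = field(default_factory=list)

    def feature_lists(self) -> list[FeatureList]:
        return [fl for b in self.bundles.values() for fl in b.feature_lists.values()]


def run_study(
    study_dir: str | Path,
    mn_params: MNParams | None = None,
    min_peaks: int = 10,
) -> StudyResult:
    """Process a study directory (metadata.tsv, taxonomy.tsv, msdata/,
    library/, externals/, bioactivity.tsv, chembl.tsv) into bundles, the MEMO
    matrix and the merged knowledge graph."""
    study = Path(study_dir)
    mn_params = mn_params or MNParams()

    records = parse_sample_metadata(study / "metadata.tsv")
    taxonomy = TaxonomyTable.from_tsv(study / "taxonomy.tsv")
    library = ann.load_library(study / "library" / "structures.tsv",
                               study / "library" / "library.mgf")
    lib_by_id = {e.structure_id: e for e in library}

    bioactivity = {}
    bio_path = study / "bioactivity.tsv"
    if bio_path.exists():
        bdf = pd.read_csv(bio_path, sep="\t", comment="#")
        for _, row in bdf.iterrows():
            bioactivity.setdefault(str(row["sample_id"]), {})[str(row["assay"])] = float(
                row["percent_inhibition"]
            )

    bundles: dict[str, kgm.SampleBundle] = {}
    all_docs: dict[str, list] = {}
    blanks = set()

    for rec in records:
        if rec.sample_type == "blank":
            blanks.add(rec.sample_id)
        taxon = resolve_taxon(rec.source_taxon, taxonomy) if rec.source_taxon else None
        bundle = kgm.SampleBundle(record=rec, taxon=taxon,
                                  bioactivity=bioactivity.get(rec.sample_id, {}))
        for pol, fname in sorted(rec.filenames.items()):
            mgf_path = study / "msdata" / fname
            quant_path = study / "msdata" / f"{Path(fname).stem}_quant.csv"
            fl = read_feature_bundle(mgf_path, quant_path, rec.sample_id, pol)
            bundle.feature_lists[pol] = fl
            docs = documents_for_feature_list(fl)
            bundle.documents[pol] = docs
            all_docs.setdefault(rec.sample_id, []).extend(docs)

            if rec.sample_type == "sample":
                net = build_molecular_network(fl, mn_params)
                bundle.networks[pol] = net
                bundle.isdb_annotations[pol] = ann.annotate_feature_list(
                    fl, library, taxon, taxonomy, network=net,
                )

            sirius_path = study / "externals" / f"{rec.sample_id}_sirius.tsv"
            canopus_path = study / "externals" / f"{rec.sample_id}_canopus.tsv"
            if pol == "PI" and (sirius_path.exists() or canopus_path.exists()):
                bundle.external_annotations[pol] = ann.load_external_annotations(
                    sirius_path if sirius_path.exists() else None,
                    canopus_path if canopus_path.exists() else None,
                )
            bundle.parameters[f"feature_list_{pol}"] = {"source": fname}
        bundles[rec.sample_id] = bundle

    memo_matrix = build_memo_matrix(all_docs, blanks=blanks, min_peaks=min_peaks)

    graphs = [kgm.sample_to_triples(b, lib_by_id) for _, b in sorted(bundles.items())]
    chembl_path = study / "chembl.tsv"
    if chembl_path.exists():
        graphs.append(kgm.chembl_to_triples(ann.load_chembl_table(chembl_path)))
    merged = kgm.merge_graphs(graphs)

    return StudyResult(
        bundles=bundles,
        graph=merged,
        index=GraphIndex.from_graph(merged),
        memo_matrix=memo_matrix,
        records=records,
    )
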