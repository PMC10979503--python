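import json
from pathlib import Path

import pytest

from metabokg.fixtures import FixtureDesign, generate_library, generate_sample_set
from metabokg.ingest import Peak, Spectrum
from metabokg.pipeline import run_study
from metabokg.taxonomy import TaxonomyTable, TaxonRecord


def make_spectrum(peaks, precursor=500.0, fid=1, rt=100.0, polarity="PI"):
    """peaks: iterable of (mz, intensity)."""
    return Spectrum(
        feature_id=fid,
        precursor_mz=precursor,
        rt=rt,
        polarity=polarity,
        peaks=tuple(Peak(m, i) for m, i in peaks),
    )


def lineage(order, family, genus, species):
    return {
        "domain": "Eukaryota",
        "kingdom": "Archaeplastida",
        "phylum": "Streptophyta",
        "class": "Magnoliopsida",
        "order": order,
        "family": family,
        "genus": genus,
        "species": species,
    }


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Three species: two sharing a genus-less family, one in another family."""
    return TaxonomyTable(
        [
            TaxonRecord("Waltheria indica", "Waltheria indica",
                        lineage("Malvales", "Malvaceae", "Waltheria", "Waltheria indica"),
                        {"ott": "1", "wikidata": "Q1"}),
            TaxonRecord("Melochia umbellata", "Melochia umbellata",
                        lineage("Malvales", "Malvaceae", "Melochia", "Melochia umbellata")),
            TaxonRecord("Datura stramonium", "Datura stramonium",
                        lineage("Solanales", "Solanaceae", "Datura", "Datura stramonium")),
        ]
    )


@pytest.fixture(scope="session")
def default_design():
    return FixtureDesign()  # seed 42, 10 samples, 2 blanks, 30 structures


@pytest.fixture(scope="session")
def default_study(tmp_path_factory, default_design):
    """The reference synthetic study, generated once and fully processed."""
    out = tmp_path_factory.mktemp("study")
    library = generate_library(default_design)
    ledger = generate_sample_set(default_design, library, out)
    result = run_study(out)
    return {"dir": out, "ledger": ledger, "result": result, "library": library}


def feature_iri(sample_id: str, polarity: str, fid: int) -> str:
    return f"https://enpkg.commons-lab.org/kg/feature_{sample_id}_{polarity}_{fid}"
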