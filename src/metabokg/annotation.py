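"""Structural annotation: library matching, taxonomic and network-consistency
reweighting, MS1 adduct annotation, exact-mass arithmetic, external-annotation
ingest and confidence filtering.

The annotation cascade scores each feature against an in-silico spectral
library (direct-match cosine, parent-mass gated), then reranks candidates by
the taxonomic distance between each candidate's reported producing organisms
and the sample's organism, and finally reweights by the chemical-class
consistency of the feature's molecular-network component. The best-ranked
candidate per feature is the retained annotation.

Scoring convention: ``final_score = (spectral + taxo_score * w_tax) * boost``
with the taxonomic points table domain=1 .. species=8 and w_tax = 1/8, so the
maximal taxonomic contribution equals the maximal spectral contribution; the
downstream confidence filter keeps ISDB annotations with taxo_score >= 6
(family or deeper).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pyteomics import mass as _pmass

from metabokg.errors import ParameterError, ParseError, SchemaError, ValidationError
from metabokg.ingest import Peak, Spectrum
from metabokg.spectral import MolecularNetwork, cosine_zero_shift
from metabokg.taxonomy import RANKS, TaxonomyTable, TaxonRecord, canonicalize_name, shared_rank_depth

ELECTRON_MASS = _pmass.nist_mass["e-"][0][0]
PROTON_MASS = _pmass.nist_mass["H"][0][0] - ELECTRON_MASS

SUPPORTED_ELEMENTS = {"C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I", "Na", "K"}

#: default taxonomic points per deepest shared rank (domain .. species)
DEFAULT_TAXO_POINTS = {rank: i + 1 for i, rank in enumerate(RANKS)}
DEFAULT_W_TAX = 1.0 / 8.0


def _parse_formula(formula: str) -> dict[str, int]:
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ParseError(f"cannot parse formula {formula!r}")
    comp = dict(_pmass.Composition(formula=formula))
    unknown = set(comp) - SUPPORTED_ELEMENTS
    if unknown:
        raise ParseError(f"unsupported element(s) {sorted(unknown)} in {formula!r}")
    return comp


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (exact) mass of a Hill-notation formula, in Da."""
    return _pmass.calculate_mass(composition=_pmass.Composition(_parse_formula(formula)))


@dataclass(frozen=True)
class AdductSpec:
    """An ionized molecular species: name, element delta, charge, as used for
    MS1 annotation and calculated-m/z values."""

    name: str
    delta: Mapping[str, int]  # signed element multiset added to M
    charge: int  # +1 or -1

    def delta_mass(self) -> float:
        m = 0.0
        for el, n in self.delta.items():
            m += n * _pmass.nist_mass[el][0][0]
        return m


#: supported adducts by polarity
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, +1),
    "[M+K]+": AdductSpec("[M+K]+", {"K": 1}, +1),
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
    "[M+Na-2H]-": AdductSpec("[M+Na-2H]-", {"Na": 1, "H": -2}, -1),
    "[M+K-2H]-": AdductSpec("[M+K-2H]-", {"K": 1, "H": -2}, -1),
}

PI_ADDUCTS = ("[M+H]+", "[M+NH4]+", "[M+K]+", "[M+Na]+")
NI_ADDUCTS = ("[M-H]-", "[M+K-2H]-", "[M+Na-2H]-")


def adduct_mz(formula: str, adduct: str | AdductSpec) -> float:
    """m/z of an adduct ion: (mass(M) + mass(delta) − charge·m_e) / |charge|.

    The electron mass is included so calculated values agree with measured
    high-resolution masses at the sub-ppm level.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ParameterError(f"unsupported adduct {adduct!r}") from None
    m = monoisotopic_mass(formula)
    return (m + adduct.delta_mass() - adduct.charge * ELECTRON_MASS) / abs(adduct.charge)


def default_adducts(polarity: str) -> list[AdductSpec]:
    names = PI_ADDUCTS if polarity == "PI" else NI_ADDUCTS
    return [ADDUCTS[n] for n in names]


# ---------------------------------------------------------------------------
# library

@dataclass(frozen=True)
class LibraryEntry:
    """One in-silico library structure with its reference spectrum and the taxa
    in which the structure has been reported."""

    structure_id: str
    inchikey2d: str
    smiles: str
    formula: str
    exact_mass: float
    taxa: tuple[str, ...]
    peaks: tuple[Peak, ...]
    npc_pathway: str = ""
    npc_superclass: str = ""
    npc_class: str = ""

    def __post_init__(self) -> None:
        if len(self.inchikey2d) != 14 or not self.inchikey2d.isupper():
            raise ValidationError(f"inchikey2d must be 14 uppercase chars: {self.inchikey2d!r}")
        if abs(self.exact_mass - monoisotopic_mass(self.formula)) > 1e-3:
            raise ValidationError(
                f"{self.structure_id}: exact_mass {self.exact_mass} inconsistent with "
                f"formula {self.formula}"
            )

    def precursor_mz(self, polarity: str) -> float:
        """Reference precursor m/z: [M+H]+ in PI, [M−H]− in NI."""
        return adduct_mz(self.formula, "[M+H]+" if polarity == "PI" else "[M-H]-")

    def reference_spectrum(self, polarity: str) -> Spectrum:
        return Spectrum(
            feature_id=1,
            precursor_mz=self.precursor_mz(polarity),
            rt=0.0,
            polarity=polarity,
            peaks=self.peaks,
        )


def load_library(table_path: str | Path, mgf_path: str | Path) -> list[LibraryEntry]:
    """Load the structure table (TSV) and reference-spectrum MGF keyed by
    structure_id."""
    from metabokg.ingest import _mgf  # reuse pyteomics reader

    df = pd.read_csv(table_path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"structure_id", "inchikey2d", "smiles", "formula", "taxa"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"library table missing columns {sorted(missing)}")

    peaks_by_id: dict[str, tuple[Peak, ...]] = {}
    with _mgf.MGF(str(mgf_path), convert_arrays=1) as reader:
        for block in reader:
            sid = block["params"].get("structure_id")
            if sid is None:
                raise ParseError("library MGF block without STRUCTURE_ID")
            peaks_by_id[str(sid)] = tuple(
                Peak(float(m), float(i))
                for m, i in zip(block["m/z array"], block["intensity array"])
            )

    entries = []
    for _, row in df.iterrows():
        sid = row["structure_id"]
        if sid not in peaks_by_id:
            raise ValidationError(f"structure {sid} has no reference spectrum in {mgf_path}")
        entries.append(
            LibraryEntry(
                structure_id=sid,
                inchikey2d=row["inchikey2d"],
                smiles=row["smiles"],
                formula=row["formula"],
                exact_mass=monoisotopic_mass(row["formula"]),
                taxa=tuple(t for t in row["taxa"].split("|") if t),
                peaks=peaks_by_id[sid],
                npc_pathway=row.get("npc_pathway", ""),
                npc_superclass=row.get("npc_superclass", ""),
                npc_class=row.get("npc_class", ""),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# candidates

@dataclass
class AnnotationCandidate:
    """A scored library hit for one feature."""

    feature_id: int
    structure_id: str
    inchikey2d: str
    spectral_score: float
    n_matched_fragments: int
    source: str  # isdb_ms2 | isdb_ms1
    taxo_score: int = 0
    consensus_boost: float = 1.0
    final_score: float = 0.0
    rank: int = 0
    adduct: str = ""

    def recompute_final(self, w_tax: float = DEFAULT_W_TAX) -> None:
        self.final_score = (self.spectral_score + self.taxo_score * w_tax) * self.consensus_boost


def _rerank(cands: list[AnnotationCandidate]) -> list[AnnotationCandidate]:
    """Deterministic ordering: final score desc, spectral desc, structure id asc."""
    cands.sort(key=lambda c: (-c.final_score, -c.spectral_score, c.structure_id))
    for k, c in enumerate(cands, start=1):
        c.rank = k
    return cands


def isdb_spectral_match(
    s: Spectrum,
    library: Sequence[LibraryEntry],
    tol: float = 0.01,
    min_cosine: float = 0.2,
    min_matches: int = 6,
) -> list[AnnotationCandidate]:
    """MS2 library search: parent-mass gate at ±tol, direct-match cosine, and
    the minimum-score / minimum-matched-fragments thresholds (score >= 0.2 and
    >= 6 matching fragments by default)."""
    cands = []
    for entry in library:
        if abs(entry.precursor_mz(s.polarity) - s.precursor_mz) > tol:
            continue
        sp = cosine_zero_shift(s, entry.reference_spectrum(s.polarity), tol)
        if sp.score >= min_cosine and sp.n_matched >= min_matches:
            c = AnnotationCandidate(
                feature_id=s.feature_id,
                structure_id=entry.structure_id,
                inchikey2d=entry.inchikey2d,
                spectral_score=sp.score,
                n_matched_fragments=sp.n_matched,
                source="isdb_ms2",
            )
            c.recompute_final()
            cands.append(c)
    return _rerank(cands)


def ms1_annotate(
    precursor_mz: float,
    sample_taxon: TaxonRecord,
    library: Sequence[LibraryEntry],
    adducts: Sequence[AdductSpec] | None = None,
    ppm: float = 10.0,
    polarity: str = "PI",
) -> list[AnnotationCandidate]:
    """Parent-mass-only annotation against structures reported in the sample's
    species, over the supported adducts (±ppm)."""
    if sample_taxon is None:
        raise ValidationError("MS1 annotation requires a resolved sample taxon")
    species = sample_taxon.lineage.get("species", "")
    adducts = list(adducts) if adducts is not None else default_adducts(polarity)
    cands = []
    for entry in library:
        canon = {canonicalize_name(t) for t in entry.taxa}
        if canonicalize_name(species) not in canon:
            continue
        for add in adducts:
            mz = adduct_mz(entry.formula, add)
            if abs(mz - precursor_mz) / precursor_mz <= ppm * 1e-6:
                c = AnnotationCandidate(
                    feature_id=0,
                    structure_id=entry.structure_id,
                    inchikey2d=entry.inchikey2d,
                    spectral_score=0.0,
                    n_matched_fragments=0,
                    source="isdb_ms1",
                    adduct=add.name,
                )
                c.recompute_final()
                cands.append(c)
    return _rerank(cands)


def taxonomic_reweight(
    cands: list[AnnotationCandidate],
    sample_taxon: Optional[TaxonRecord],
    library_by_id: Mapping[str, LibraryEntry],
    taxonomy: TaxonomyTable,
    points: Mapping[str, int] | None = None,
    w_tax: float = DEFAULT_W_TAX,
) -> list[AnnotationCandidate]:
    """Rerank candidates by the taxonomic distance between each candidate's
    reported organisms and the sample's organism.

    taxo_score is the points value of the deepest rank shared with any of the
    candidate's reported taxa (0 with no overlap); with an unresolved sample
    taxon all scores stay 0 and the order is unchanged.
    """
    points = dict(points or DEFAULT_TAXO_POINTS)
    for c in cands:
        best = 0
        if sample_taxon is not None:
            entry = library_by_id[c.structure_id]
            for taxon_name in entry.taxa:
                rec = taxonomy.resolve(taxon_name)
                if rec is None:
                    continue
                depth, deepest = shared_rank_depth(sample_taxon, rec)
                if deepest is not None:
                    best = max(best, points[deepest])
        c.taxo_score = best
        c.recompute_final(w_tax)
    return _rerank(cands)


def chemical_consistency_reweight(
    network: MolecularNetwork,
    per_feature_cands: Mapping[int, list[AnnotationCandidate]],
    library_by_id: Mapping[str, LibraryEntry],
    alpha: float = 0.5,
    w_tax: float = DEFAULT_W_TAX,
) -> dict[int, list[AnnotationCandidate]]:
    """Reweight candidates by the chemical-class consistency of their network
    component (network annotation propagation).

    Per component (size >= 2), the consensus class is the modal NPClassifier
    class among the current rank-1 candidates; candidates of that class get a
    multiplicative (1 + alpha) boost. A modal tie applies no boost.
    """
    comp_of = network.component_of()
    comp_classes: dict[int, list[str]] = {}
    for fid, cands in per_feature_cands.items():
        if not cands or fid not in comp_of:
            continue
        comp = comp_of[fid]
        if len(network.components[comp]) < 2:
            continue
        cls = library_by_id[cands[0].structure_id].npc_class
        if cls:
            comp_classes.setdefault(comp, []).append(cls)

    consensus: dict[int, str] = {}
    for comp, classes in comp_classes.items():
        counts = Counter(classes).most_common()
        if len(counts) == 1 or counts[0][1] > counts[1][1]:
            consensus[comp] = counts[0][0]
        # tie -> no consensus, no boost (conservative)

    out = {}
    for fid, cands in per_feature_cands.items():
        comp = comp_of.get(fid)
        target = consensus.get(comp) if comp is not None else None
        new = []
        for c in cands:
            c2 = replace_candidate(c)
            if target and library_by_id[c.structure_id].npc_class == target:
                c2.consensus_boost = 1.0 + alpha
            else:
                c2.consensus_boost = 1.0
            c2.recompute_final(w_tax)
            new.append(c2)
        out[fid] = _rerank(new)
    return out


def replace_candidate(c: AnnotationCandidate) -> AnnotationCandidate:
    return AnnotationCandidate(**{k: getattr(c, k) for k in c.__dataclass_fields__})


# ---------------------------------------------------------------------------
# external annotations (SIRIUS / CANOPUS exports)

@dataclass(frozen=True)
class ExternalAnnotation:
    """One row of an external annotation export: a SIRIUS/CSI:FingerID
    structure or a CANOPUS chemical class, with its confidence scores."""

    feature_id: int
    kind: str  # sirius_structure | canopus_class
    value: str  # inchikey2d or class label
    scores: Mapping[str, float]
    adduct: str = ""

    def __post_init__(self) -> None:
        for name, v in self.scores.items():
            if name in ("cosmic", "zodiac", "class_probability") and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{self.kind} score {name}={v} outside [0, 1]")


def load_external_annotations(
    sirius_tsv: str | Path | None = None, canopus_tsv: str | Path | None = None
) -> list[ExternalAnnotation]:
    """Parse SIRIUS/CSI:FingerID and CANOPUS TSV exports."""
    out: list[ExternalAnnotation] = []
    if sirius_tsv is not None:
        df = pd.read_csv(sirius_tsv, sep="\t", comment="#")
        if "feature_id" not in df.columns:
            raise SchemaError("SIRIUS table missing feature_id column")
        for _, row in df.iterrows():
            out.append(
                ExternalAnnotation(
                    feature_id=int(row["feature_id"]),
                    kind="sirius_structure",
                    value=str(row["inchikey2d"]),
                    scores={"cosmic": float(row["cosmic"]), "zodiac": float(row["zodiac"])},
                    adduct=str(row.get("adduct", "")),
                )
            )
    if canopus_tsv is not None:
        df = pd.read_csv(canopus_tsv, sep="\t", comment="#")
        if "feature_id" not in df.columns:
            raise SchemaError("CANOPUS table missing feature_id column")
        for _, row in df.iterrows():
            out.append(
                ExternalAnnotation(
                    feature_id=int(row["feature_id"]),
                    kind="canopus_class",
                    value=str(row["npc_class"]),
                    scores={"class_probability": float(row["class_probability"])},
                )
            )
    return out


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Gates for the confident-annotation set: SIRIUS structures need
    cosmic > 0.5 and zodiac > 0.8 (strict); ISDB rank-1 candidates need
    taxo_score >= 6, i.e. reported in the same family or deeper (inclusive)."""

    cosmic: float = 0.5
    zodiac: float = 0.8
    taxo: int = 6


@dataclass(frozen=True)
class ConfidentAnnotation:
    feature_id: int
    inchikey2d: str
    source: str  # isdb | sirius
    gate: str


def confidence_filter(
    isdb_cands: Mapping[int, list[AnnotationCandidate]],
    external: Iterable[ExternalAnnotation],
    thresholds: ConfidenceThresholds | None = None,
) -> list[ConfidentAnnotation]:
    """Union of SIRIUS structures passing both score gates and ISDB rank-1
    candidates passing the taxonomic gate, tagged with the gate each passed."""
    th = thresholds or ConfidenceThresholds()
    kept: list[ConfidentAnnotation] = []
    for ann in external:
        if ann.kind != "sirius_structure":
            continue
        if ann.scores.get("cosmic", 0.0) > th.cosmic and ann.scores.get("zodiac", 0.0) > th.zodiac:
            kept.append(
                ConfidentAnnotation(
                    feature_id=ann.feature_id,
                    inchikey2d=ann.value,
                    source="sirius",
                    gate=f"cosmic>{th.cosmic} & zodiac>{th.zodiac}",
                )
            )
    for fid, cands in sorted(isdb_cands.items()):
        if not cands:
            continue
        top = cands[0]
        if top.rank == 1 and top.taxo_score >= th.taxo:
            kept.append(
                ConfidentAnnotation(
                    feature_id=fid,
                    inchikey2d=top.inchikey2d,
                    source="isdb",
                    gate=f"taxo>={th.taxo}",
                )
            )
    return kept


# ---------------------------------------------------------------------------
# ChEMBL-style activity table

def load_chembl_table(path: str | Path, np_likeness_min: float = -1.0) -> pd.DataFrame:
    """Load a ChEMBL-style activity table, keeping natural-product-like rows
    (NP-likeness strictly greater than the threshold, default −1)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"inchikey2d", "target", "activity_type", "activity_value", "np_likeness"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"activity table missing columns {sorted(missing)}")
    return df[df["np_likeness"] > np_likeness_min].reset_index(drop=True)


def annotate_feature_list(
    fl,
    library: Sequence[LibraryEntry],
    sample_taxon: Optional[TaxonRecord],
    taxonomy: TaxonomyTable,
    network: MolecularNetwork | None = None,
    tol: float = 0.01,
    min_cosine: float = 0.2,
    min_matches: int = 6,
    ppm: float = 10.0,
    alpha: float = 0.5,
) -> dict[int, list[AnnotationCandidate]]:
    """Full cascade for one analysis: MS2 match, MS1 adduct fallback for
    features without an MS2 hit, taxonomic reweighting, then network
    chemical-consistency reweighting when a network is given."""
    lib_by_id = {e.structure_id: e for e in library}
    per_feature: dict[int, list[AnnotationCandidate]] = {}
    for f in fl:
        cands = isdb_spectral_match(f.spectrum, library, tol, min_cosine, min_matches)
        if not cands and sample_taxon is not None:
            cands = ms1_annotate(f.mz, sample_taxon, library, None, ppm, fl.polarity)
            for c in cands:
                c.feature_id = f.feature_id
        cands = taxonomic_reweight(cands, sample_taxon, lib_by_id, taxonomy)
        per_feature[f.feature_id] = cands
    if network is not None:
        per_feature = chemical_consistency_reweight(network, per_feature, lib_by_id, alpha)
    return per_feature
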