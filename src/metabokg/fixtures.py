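"""Deterministic synthetic multi-sample study generator with a ground-truth
ledger.

The generator emulates the structure of a real plant-extract screening
campaign at desk scale: an in-silico spectral library of natural-product
structures with taxon occurrences, per-sample MGF + quantification exports in
both ionization modes, blanks carrying instrument-background spectra that also
contaminate the samples, externally produced structure/class annotation
tables, a percent-inhibition bioactivity table, and a ChEMBL-style activity
table. Every planted fact (which structure generates which feature, shared
compounds across taxa, PI/NI ion pairs, the chemical class shared by the
"active" sample group, reported activities) is recorded in a JSON ledger so
every downstream stage and query can be checked against known truth.

All spectra are synthetic: fragmentation is random (no fragmentation
chemistry, no isotope patterns), formulas come from a small CHNO grammar so
masses are computable exactly, and retention times are arbitrary but unique
per structure. All randomness flows through one seeded generator and every
emitted file embeds the seed in a header comment.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from metabokg.annotation import PROTON_MASS, LibraryEntry, adduct_mz, monoisotopic_mass
from metabokg.errors import ValidationError
from metabokg.ingest import Feature, FeatureList, Peak, Spectrum, write_mgf, write_quant_csv
from metabokg.spectral import filter_relative_intensity, to_spectral_document

#: taxonomy used by the default design: 3 families x 2 genera x 1 species
DEFAULT_TAXA = {
    "Waltheria indica": ("Malvales", "Malvaceae", "Waltheria"),
    "Melochia umbellata": ("Malvales", "Malvaceae", "Melochia"),
    "Pristimera indica": ("Celastrales", "Celastraceae", "Pristimera"),
    "Salacia chinensis": ("Celastrales", "Celastraceae", "Salacia"),
    "Datura stramonium": ("Solanales", "Solanaceae", "Datura"),
    "Atropa belladonna": ("Solanales", "Solanaceae", "Atropa"),
}

_FAMILY_CLASS = {
    "Malvaceae": ("Quinoline alkaloids", "Alkaloids", "Tryptophan alkaloids"),
    "Celastraceae": ("Quinone methides", "Triterpenoids", "Terpenoids"),
    "Solanaceae": ("Tropane alkaloids", "Alkaloids", "Ornithine alkaloids"),
}

ACTIVE_CLASS = "Quinone methides"
ACTIVE_FAMILY = "Celastraceae"


@dataclass
class FixtureDesign:
    """Study-design knobs; the defaults are the reference conditions every
    end-to-end check runs under."""

    seed: int = 42
    n_structures: int = 30
    n_samples: int = 10
    n_blanks: int = 2
    peaks_per_spectrum: tuple[int, int] = (10, 18)
    mz_jitter: float = 0.005  # Da, per fragment peak
    precursor_jitter: float = 0.003  # Da
    intensity_jitter: float = 0.2  # +-20 %
    n_cross_polarity_pairs: int = 4
    assay: str = "Tcruzi_inhibition"
    cytotox_assay: str = "cytotoxicity"
    active_min_inhibition: float = 80.0
    cytotox_max: float = 20.0


def _random_inchikey2d(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        ik = "".join(rng.choice(list(string.ascii_uppercase), size=14))
        if ik not in taken:
            taken.add(ik)
            return ik


def _random_formula(rng: np.random.Generator, existing_masses: list[float]) -> str:
    """CHNO formula whose [M+H]+ is >= 0.05 Da away from all existing ones, so
    parent-mass gates isolate a single true candidate."""
    for _ in range(1000):
        c = int(rng.integers(15, 36))
        h = int(rng.integers(c, 2 * c + 3))
        n = int(rng.integers(0, 3))
        o = int(rng.integers(2, 9))
        formula = f"C{c}H{h}" + (f"N{n}" if n else "") + f"O{o}"
        m = monoisotopic_mass(formula)
        if all(abs(m - e) > 0.05 for e in existing_masses):
            existing_masses.append(m)
            return formula
    raise ValidationError("could not draw a mass-separated formula")


def generate_library(
    design: FixtureDesign, out_dir: str | Path | None = None
) -> list[LibraryEntry]:
    """Synthetic in-silico library: structures with CHNO formulas, fake 2D
    keys, taxon occurrences and seeded reference spectra (10-18 peaks).

    Structures are dealt round-robin over the three families; each structure's
    chemical class is its family's signature class, so the active class exists
    only in the active family's species. One structure (the planted shared
    compound) is reported in two species of different genera.
    """
    rng = np.random.default_rng(design.seed)
    species = list(DEFAULT_TAXA)
    by_family: dict[str, list[str]] = {}
    for sp, (_, family, _) in DEFAULT_TAXA.items():
        by_family.setdefault(family, []).append(sp)
    families = sorted(by_family)

    taken: set[str] = set()
    masses: list[float] = []
    entries = []
    for k in range(design.n_structures):
        family = families[k % len(families)]
        fam_species = by_family[family]
        n_taxa = int(rng.integers(1, len(fam_species) + 1))
        taxa = tuple(sorted(rng.choice(fam_species, size=n_taxa, replace=False)))
        formula = _random_formula(rng, masses)
        npc_class, npc_super, npc_path = (
            _FAMILY_CLASS[family][0],
            _FAMILY_CLASS[family][1],
            _FAMILY_CLASS[family][2],
        )
        mh = adduct_mz(formula, "[M+H]+")
        n_peaks = int(rng.integers(design.peaks_per_spectrum[0],
                                   design.peaks_per_spectrum[1] + 1))
        mzs = np.sort(rng.uniform(60.0, mh - 25.0, size=n_peaks))
        intensities = rng.uniform(0.03, 1.0, size=n_peaks) * 1e5
        peaks = tuple(
            Peak(round(float(m), 4), round(float(i), 1))
            for m, i in zip(mzs, intensities)
        )
        entries.append(
            LibraryEntry(
                structure_id=f"MKG{k:04d}",
                inchikey2d=_random_inchikey2d(rng, taken),
                smiles="C" * max(2, k % 20 + 2),  # synthetic placeholder
                formula=formula,
                exact_mass=monoisotopic_mass(formula),
                taxa=taxa,
                peaks=peaks,
                npc_pathway=npc_path,
                npc_superclass=npc_super,
                npc_class=npc_class,
            )
        )

    # planted shared compound: first Malvaceae structure reported in both
    # Malvaceae species (detected in two samples of different genera)
    shared = next(e for e in entries if "Malvaceae" == DEFAULT_TAXA[e.taxa[0]][1])
    idx = entries.index(shared)
    entries[idx] = LibraryEntry(
        structure_id=shared.structure_id,
        inchikey2d=shared.inchikey2d,
        smiles=shared.smiles,
        formula=shared.formula,
        exact_mass=shared.exact_mass,
        taxa=tuple(sorted(by_family["Malvaceae"])),
        peaks=shared.peaks,
        npc_pathway=shared.npc_pathway,
        npc_superclass=shared.npc_superclass,
        npc_class=shared.npc_class,
    )

    if out_dir is not None:
        write_library_files(entries, out_dir, design.seed)
    return entries


def write_library_files(entries: list[LibraryEntry], out_dir: str | Path, seed: int) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = ["structure_id", "inchikey2d", "smiles", "formula", "taxa",
            "npc_pathway", "npc_superclass", "npc_class"]
    lines = [f"# seed={seed}", "\t".join(cols)]
    for e in entries:
        lines.append("\t".join([
            e.structure_id, e.inchikey2d, e.smiles, e.formula, "|".join(e.taxa),
            e.npc_pathway, e.npc_superclass, e.npc_class,
        ]))
    (out / "structures.tsv").write_text("\n".join(lines) + "\n")

    mgf_lines = [f"# seed={seed}"]
    for e in entries:
        mgf_lines.append("BEGIN IONS")
        mgf_lines.append(f"STRUCTURE_ID={e.structure_id}")
        mgf_lines.append(f"PEPMASS={adduct_mz(e.formula, '[M+H]+')!r}")
        for p in e.peaks:
            mgf_lines.append(f"{p.mz!r} {p.intensity!r}")
        mgf_lines.append("END IONS")
        mgf_lines.append("")
    (out / "library.mgf").write_text("\n".join(mgf_lines))


def _write_taxonomy_tsv(path: Path, seed: int) -> None:
    cols = ["query_name", "matched_name", "domain", "kingdom", "phylum", "class",
            "order", "family", "genus", "species", "ott_id", "wikidata_qid"]
    lines = [f"# seed={seed}", "\t".join(cols)]
    for i, (sp, (order, family, genus)) in enumerate(sorted(DEFAULT_TAXA.items())):
        lines.append("\t".join([
            sp, sp, "Eukaryota", "Archaeplastida", "Streptophyta", "Magnoliopsida",
            order, family, genus, sp, str(100000 + i), f"Q{900000 + i}",
        ]))
    path.write_text("\n".join(lines) + "\n")


def _contaminant_spectra(polarity: str) -> list[Spectrum]:
    """Fixed instrument-background spectra (present in blanks and samples)."""
    out = []
    for k, prec in enumerate((371.1012, 445.1200, 519.1388)):
        mzs = [50.0 + 13.7 * i + 2.3 * k for i in range(12)]
        peaks = tuple(Peak(round(m, 4), 1e4 + 500.0 * i) for i, m in enumerate(mzs))
        out.append(Spectrum(feature_id=900 + k, precursor_mz=prec, rt=15.0 + 7.0 * k,
                            polarity=polarity, peaks=peaks))
    return out


def _jitter_spectrum(
    s_peaks, precursor: float, rt: float, fid: int, polarity: str,
    rng: np.random.Generator, design: FixtureDesign,
) -> Spectrum:
    peaks = tuple(
        Peak(
            round(p.mz + float(rng.uniform(-design.mz_jitter, design.mz_jitter)), 5),
            round(p.intensity * float(rng.uniform(1 - design.intensity_jitter,
                                                  1 + design.intensity_jitter)), 2),
        )
        for p in s_peaks
    )
    return Spectrum(feature_id=fid, precursor_mz=precursor, rt=rt,
                    polarity=polarity, peaks=peaks)


def generate_sample_set(
    design: FixtureDesign,
    library: list[LibraryEntry],
    out_dir: str | Path,
) -> dict:
    """Emit the full synthetic study into ``out_dir`` and return the
    ground-truth ledger (also written as ``ground_truth.json``).

    Layout: ``msdata/`` (per-sample MGF + quant CSV, both polarities),
    ``library/`` (structure table + reference MGF), ``externals/`` (per-sample
    SIRIUS/CANOPUS TSVs), ``metadata.tsv``, ``taxonomy.tsv``,
    ``bioactivity.tsv``, ``chembl.tsv``, ``ground_truth.json``.
    """
    rng = np.random.default_rng(design.seed + 1)
    out = Path(out_dir)
    (out / "msdata").mkdir(parents=True, exist_ok=True)
    (out / "externals").mkdir(exist_ok=True)
    write_library_files(library, out / "library", design.seed)
    _write_taxonomy_tsv(out / "taxonomy.tsv", design.seed)

    species = list(DEFAULT_TAXA)
    active_species = [sp for sp in species if DEFAULT_TAXA[sp][1] == ACTIVE_FAMILY]
    # spread samples over species, guaranteeing >=3 active-family samples
    sample_species = {}
    for i in range(design.n_samples):
        sid = f"S{i + 1:02d}"
        if i < 3:
            sample_species[sid] = active_species[i % len(active_species)]
        else:
            rest = [sp for sp in species if sp not in active_species]
            sample_species[sid] = rest[(i - 3) % len(rest)]
    sample_ids = sorted(sample_species)
    blank_ids = [f"B{i + 1:02d}" for i in range(design.n_blanks)]

    by_species: dict[str, list[LibraryEntry]] = {sp: [] for sp in species}
    for e in library:
        for t in e.taxa:
            by_species[t].append(e)
    shared_entry = next(e for e in library if len({DEFAULT_TAXA[t][2] for t in e.taxa}) > 1)

    rt_of = {e.structure_id: 60.0 + 37.0 * k for k, e in enumerate(library)}
    contaminants = _contaminant_spectra("PI")

    ledger: dict = {
        "seed": design.seed,
        "design": asdict(design),
        "active_class": ACTIVE_CLASS,
        "active_group": [s for s in sample_ids if sample_species[s] in active_species],
        "samples": {},
        "cross_polarity_pairs": [],
        "sirius_true": [],
        "sirius_false": [],
        "contaminant_words": sorted(
            {w for c in contaminants
             for w in to_spectral_document(filter_relative_intensity(c)).words}
        ),
    }

    meta_lines = [f"# seed={design.seed}",
                  "\t".join(["sample_id", "sample_type", "source_id", "source_taxon",
                             "filename_pi", "filename_ni"])]
    bio_lines = [f"# seed={design.seed}", "\t".join(["sample_id", "assay", "percent_inhibition"])]

    shared_occurrences = []
    pair_budget = design.n_cross_polarity_pairs

    for si, sid in enumerate(sample_ids):
        sp_name = sample_species[sid]
        entries = sorted(by_species[sp_name], key=lambda e: e.structure_id)
        pi_features: list[Feature] = []
        ni_features: list[Feature] = []
        planted_pi: dict[int, str] = {}
        planted_ni: dict[int, str] = {}
        sirius_rows = []
        canopus_rows = []
        fid = 0
        ni_fid = 0
        for e in entries:
            fid += 1
            mh = adduct_mz(e.formula, "[M+H]+")
            rt = rt_of[e.structure_id]
            if e.structure_id == shared_entry.structure_id:
                # exact copy: co-detected shared compound across taxa
                spec = Spectrum(feature_id=fid, precursor_mz=mh, rt=rt,
                                polarity="PI", peaks=e.peaks)
                shared_occurrences.append([sid, fid])
            else:
                prec = mh + float(rng.uniform(-design.precursor_jitter,
                                              design.precursor_jitter))
                spec = _jitter_spectrum(e.peaks, round(prec, 5), rt, fid, "PI", rng, design)
            pi_features.append(Feature(fid, spec.precursor_mz, rt, float(rng.uniform(1e5, 1e7)),
                                       spec))
            planted_pi[fid] = e.structure_id

            # external annotations: 70 % true SIRIUS rows (confident scores),
            # 15 % wrong-structure rows failing the gates
            u = rng.uniform()
            if u < 0.70:
                sirius_rows.append((fid, e.inchikey2d, round(float(rng.uniform(0.55, 0.95)), 3),
                                    round(float(rng.uniform(0.85, 0.99)), 3), "[M+H]+"))
                ledger["sirius_true"].append([sid, fid])
            elif u < 0.85:
                # wrong structure from the same family, so class/group
                # structure remains as planted
                other = library[(library.index(e) + 6) % len(library)]
                sirius_rows.append((fid, other.inchikey2d, 0.3,
                                    round(float(rng.uniform(0.2, 0.6)), 3), "[M+H]+"))
                ledger["sirius_false"].append([sid, fid])
            canopus_rows.append((fid, e.npc_class, round(float(rng.uniform(0.6, 0.99)), 3)))

            if pair_budget > 0 and any(r[0] == fid for r in sirius_rows[-1:]):
                # plant the deprotonated twin in NI at the same RT
                ni_fid += 1
                ni_mz = spec.precursor_mz - 2 * PROTON_MASS
                ni_spec = _jitter_spectrum(e.peaks, round(ni_mz, 6), rt, ni_fid, "NI",
                                           rng, design)
                ni_spec = Spectrum(feature_id=ni_fid, precursor_mz=ni_mz, rt=rt,
                                   polarity="NI", peaks=ni_spec.peaks)
                ni_features.append(Feature(ni_fid, ni_mz, rt,
                                           float(rng.uniform(1e5, 1e7)), ni_spec))
                planted_ni[ni_fid] = e.structure_id
                ledger["cross_polarity_pairs"].append([sid, fid, ni_fid])
                pair_budget -= 1

        # one background contaminant feature per sample (exact blank copy)
        cont = contaminants[si % len(contaminants)]
        fid += 1
        pi_features.append(Feature(fid, cont.precursor_mz, cont.rt, 5e4,
                                   Spectrum(feature_id=fid, precursor_mz=cont.precursor_mz,
                                            rt=cont.rt, polarity="PI", peaks=cont.peaks)))
        contaminant_fids = [fid]

        fl_pi = FeatureList(sample_id=sid, polarity="PI", features=pi_features)
        write_mgf(fl_pi, out / "msdata" / f"{sid}_PI.mgf", header_comment=f"seed={design.seed}")
        write_quant_csv(fl_pi, out / "msdata" / f"{sid}_PI_quant.csv",
                        header_comment=f"seed={design.seed}")
        ni_name = ""
        if ni_features:
            fl_ni = FeatureList(sample_id=sid, polarity="NI", features=ni_features)
            write_mgf(fl_ni, out / "msdata" / f"{sid}_NI.mgf",
                      header_comment=f"seed={design.seed}")
            write_quant_csv(fl_ni, out / "msdata" / f"{sid}_NI_quant.csv",
                            header_comment=f"seed={design.seed}")
            ni_name = f"{sid}_NI.mgf"

        meta_lines.append("\t".join([sid, "sample", f"SRC{si + 1:03d}", sp_name,
                                     f"{sid}_PI.mgf", ni_name]))

        s_cols = ["feature_id", "inchikey2d", "cosmic", "zodiac", "adduct"]
        s_lines = [f"# seed={design.seed}", "\t".join(s_cols)]
        for row in sirius_rows:
            s_lines.append("\t".join(str(x) for x in row))
        (out / "externals" / f"{sid}_sirius.tsv").write_text("\n".join(s_lines) + "\n")
        c_cols = ["feature_id", "npc_class", "class_probability"]
        c_lines = [f"# seed={design.seed}", "\t".join(c_cols)]
        for row in canopus_rows:
            c_lines.append("\t".join(str(x) for x in row))
        (out / "externals" / f"{sid}_canopus.tsv").write_text("\n".join(c_lines) + "\n")

        ledger["samples"][sid] = {
            "species": sp_name,
            "PI": {str(k): v for k, v in planted_pi.items()},
            "NI": {str(k): v for k, v in planted_ni.items()},
            "contaminant_features": contaminant_fids,
        }

        # bioactivity: the active family is strongly inhibiting and clean;
        # one decoy sample is active but cytotoxic
        if sp_name in active_species:
            inhib = round(float(rng.uniform(82, 95)), 1)
            cyto = round(float(rng.uniform(5, 15)), 1)
        elif sid == "S07":
            inhib, cyto = 88.0, 75.0
        else:
            inhib = round(float(rng.uniform(5, 35)), 1)
            cyto = round(float(rng.uniform(5, 30)), 1)
        bio_lines.append("\t".join([sid, design.assay, str(inhib)]))
        bio_lines.append("\t".join([sid, design.cytotox_assay, str(cyto)]))

    # blanks: background spectra only
    for bi, bid in enumerate(blank_ids):
        feats = []
        for k, c in enumerate(contaminants, start=1):
            feats.append(Feature(k, c.precursor_mz, c.rt, 1e5,
                                 Spectrum(feature_id=k, precursor_mz=c.precursor_mz,
                                          rt=c.rt, polarity="PI", peaks=c.peaks)))
        fl = FeatureList(sample_id=bid, polarity="PI", features=feats)
        write_mgf(fl, out / "msdata" / f"{bid}_PI.mgf", header_comment=f"seed={design.seed}")
        write_quant_csv(fl, out / "msdata" / f"{bid}_PI_quant.csv",
                        header_comment=f"seed={design.seed}")
        meta_lines.append("\t".join([bid, "blank", f"BLK{bi + 1:03d}", "",
                                     f"{bid}_PI.mgf", ""]))

    (out / "metadata.tsv").write_text("\n".join(meta_lines) + "\n")
    (out / "bioactivity.tsv").write_text("\n".join(bio_lines) + "\n")

    shared_doc = to_spectral_document(
        filter_relative_intensity(
            Spectrum(feature_id=1, precursor_mz=adduct_mz(shared_entry.formula, "[M+H]+"),
                     rt=0.0, polarity="PI", peaks=shared_entry.peaks)
        )
    )
    ledger["shared_compound"] = {
        "structure_id": shared_entry.structure_id,
        "inchikey2d": shared_entry.inchikey2d,
        "occurrences": shared_occurrences,
        "word_count": len(shared_doc.words),
    }

    # ChEMBL-style activity table: two NP-like active-class structures with
    # target activity, one NP-unlike row (filtered on ingest), decoy targets
    active_structures = [e for e in library if e.npc_class == ACTIVE_CLASS]
    target = "Trypanosoma cruzi"
    ch_cols = ["inchikey2d", "target", "activity_type", "activity_value", "np_likeness"]
    ch_lines = [f"# seed={design.seed}", "\t".join(ch_cols)]
    expected_chembl = []
    for e in active_structures[:2]:
        ch_lines.append("\t".join([e.inchikey2d, target, "IC50", "1.2", "1.5"]))
        expected_chembl.append(e.inchikey2d)
    ch_lines.append("\t".join([active_structures[2].inchikey2d, target, "IC50", "0.8", "-2.0"]))
    ch_lines.append("\t".join([library[1].inchikey2d, "Leishmania donovani", "IC50",
                               "3.3", "1.1"]))
    (out / "chembl.tsv").write_text("\n".join(ch_lines) + "\n")
    ledger["chembl"] = {
        "target": target,
        "expected_structures": sorted(expected_chembl),
        "np_unlike_structure": active_structures[2].inchikey2d,
    }
    ledger["bioactivity_thresholds"] = {
        "assay": design.assay,
        "active_min_inhibition": design.active_min_inhibition,
        "cytotox_assay": design.cytotox_assay,
        "cytotox_max": design.cytotox_max,
    }

    (out / "ground_truth.json").write_text(json.dumps(ledger, indent=2, sort_keys=True) + "\n")
    return ledger
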