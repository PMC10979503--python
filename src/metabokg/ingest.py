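"""Parse and validate sample metadata and per-sample MS exports.

Feature finding itself happens upstream (MZmine-style exports are ingested,
never computed): each LC-MS feature arrives as one MGF block (its MS² spectrum,
keyed by feature id, precursor m/z and retention time) plus one row of a
quantification CSV (feature id, m/z, RT, area). Samples are organized in a
sample-wise directory architecture so that every downstream product of one
sample lives next to its inputs and new samples can be added incrementally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyteomics import mgf as _mgf

from metabokg.errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("QC", "blank", "sample")
POLARITIES = ("PI", "NI")

#: metadata columns that must be present (plus at least one filename column)
REQUIRED_METADATA_COLUMNS = ("sample_id", "sample_type", "source_id", "source_taxon")
FILENAME_COLUMNS = ("filename_pi", "filename_ni", "filename")


@dataclass(frozen=True)
class Peak:
    """One fragment peak: m/z in Da (> 0), intensity in arbitrary units (>= 0)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An MS² spectrum attached to one LC-MS feature.

    Peaks are stored in ascending m/z order; retention time is seconds.
    """

    feature_id: int
    precursor_mz: float
    rt: float
    polarity: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if self.feature_id < 1:
            raise ValidationError(f"feature_id must be >= 1, got {self.feature_id}")
        if not self.precursor_mz > 0:
            raise ValidationError("precursor_mz must be positive")
        if self.polarity not in POLARITIES:
            raise ValidationError(f"polarity must be one of {POLARITIES}")
        ordered = tuple(sorted(self.peaks, key=lambda p: (p.mz, p.intensity)))
        object.__setattr__(self, "peaks", ordered)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]


@dataclass(frozen=True)
class Feature:
    """One aligned (MGF x quant-table) LC-MS feature."""

    feature_id: int
    mz: float
    rt: float
    area: float
    spectrum: Spectrum


@dataclass
class FeatureList:
    """All features of one (sample, polarity) analysis, joined on feature id."""

    sample_id: str
    polarity: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate feature ids in {self.sample_id}/{self.polarity}")
        for f in self.features:
            if abs(f.mz - f.spectrum.precursor_mz) > 1e-4:
                raise ValidationError(
                    f"feature {f.feature_id}: quant m/z {f.mz} disagrees with "
                    f"spectrum precursor {f.spectrum.precursor_mz} by more than 1e-4 Da"
                )
        self.features.sort(key=lambda f: f.feature_id)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass(frozen=True)
class SampleRecord:
    """Minimal sufficient sample metadata: id, type, source id, source taxon, filenames."""

    sample_id: str
    sample_type: str
    source_id: str
    source_taxon: str
    filenames: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.sample_type == "sample" and not self.source_taxon.strip():
            raise ValidationError(f"sample {self.sample_id}: source_taxon required")


def _normalize_sample_type(raw: str) -> str:
    """Case-normalize the sample type; taxa are never normalized here."""
    t = raw.strip()
    for lit in SAMPLE_TYPES:
        if t.lower() == lit.lower():
            return lit
    raise ValidationError(f"unknown sample_type {raw!r}; expected one of {SAMPLE_TYPES}")


def parse_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the run metadata TSV into one :class:`SampleRecord` per row.

    The table must carry sample_id, sample_type, source_id, source_taxon and at
    least one filename column (filename_pi / filename_ni / filename). Sample
    types are case-normalized to the QC/blank/sample literals; rows with any
    other type are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"metadata table missing required column {col!r}")
    fname_cols = [c for c in FILENAME_COLUMNS if c in df.columns]
    if not fname_cols:
        raise SchemaError(
            f"metadata table needs at least one filename column among {FILENAME_COLUMNS}"
        )
    records = []
    for _, row in df.iterrows():
        filenames = {}
        if row.get("filename_pi", ""):
            filenames["PI"] = row["filename_pi"]
        if row.get("filename_ni", ""):
            filenames["NI"] = row["filename_ni"]
        if not filenames and row.get("filename", ""):
            filenames["PI"] = row["filename"]
        records.append(
            SampleRecord(
                sample_id=row["sample_id"].strip(),
                sample_type=_normalize_sample_type(row["sample_type"]),
                source_id=row["source_id"].strip(),
                source_taxon=row["source_taxon"].strip(),
                filenames=filenames,
            )
        )
    ids = [r.sample_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate sample_id values: {dupes}")
    return records


def _spectrum_from_mgf_block(block: dict, polarity: str, rt_unit: str, index: int) -> Spectrum:
    params = block.get("params", {})
    try:
        fid = params.get("feature_id", params.get("scans"))
        feature_id = int(fid)
        pepmass = params["pepmass"]
        precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
        # RTINMINUTES is self-describing; the rt_unit flag covers exports that
        # write minute values under the generic RTINSECONDS key.
        if "rtinminutes" in params:
            rt = float(params["rtinminutes"]) * 60.0
        elif "rtinseconds" in params:
            rt = float(params["rtinseconds"]) * (60.0 if rt_unit == "min" else 1.0)
        else:
            raise KeyError("rtinseconds")
        peaks = tuple(
            Peak(float(m), float(i))
            for m, i in zip(block["m/z array"], block["intensity array"])
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"unparseable MGF block at scan index {index}: {exc}") from exc
    return Spectrum(
        feature_id=feature_id, precursor_mz=precursor, rt=rt, polarity=polarity, peaks=peaks
    )


def read_mgf(path: str | Path, polarity: str, rt_unit: str = "s") -> list[Spectrum]:
    """Read an MGF file into spectra (keys PEPMASS, RTINSECONDS/RTINMINUTES,
    FEATURE_ID or SCANS)."""
    spectra = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for index, block in enumerate(reader):
            spectra.append(_spectrum_from_mgf_block(block, polarity, rt_unit, index))
    return spectra


def read_feature_bundle(
    mgf_path: str | Path,
    quant_path: str | Path,
    sample_id: str,
    polarity: str,
    rt_unit: str = "s",
) -> FeatureList:
    """Join an MGF of MS² scans with its quantification CSV into a FeatureList.

    Features present in only one of the two files are dropped with a logged
    warning (only features with an associated MS² scan are kept); an empty
    intersection is an error. RTs may be given in minutes (``rt_unit='min'``
    applies to the quant table; MGF RTINSECONDS/RTINMINUTES keys are
    self-describing) and are stored in seconds.
    """
    spectra = {s.feature_id: s for s in read_mgf(mgf_path, polarity, rt_unit)}
    quant = pd.read_csv(quant_path, comment="#")
    for col in ("feature_id", "mz", "rt", "area"):
        if col not in quant.columns:
            raise SchemaError(f"quantification table missing column {col!r}")
    rt_scale = 60.0 if rt_unit == "min" else 1.0

    features = []
    quant_ids = set()
    for _, row in quant.iterrows():
        fid = int(row["feature_id"])
        quant_ids.add(fid)
        if fid not in spectra:
            logger.warning("feature %s in quant table of %s/%s has no MS2 scan; dropped",
                           fid, sample_id, polarity)
            continue
        features.append(
            Feature(
                feature_id=fid,
                mz=float(row["mz"]),
                rt=float(row["rt"]) * rt_scale,
                area=float(row["area"]),
                spectrum=spectra[fid],
            )
        )
    for fid in sorted(set(spectra) - quant_ids):
        logger.warning("MGF scan %s of %s/%s has no quant row; dropped", fid, sample_id, polarity)
    if not features:
        raise ValidationError(
            f"no feature id shared between {mgf_path} and {quant_path}"
        )
    return FeatureList(sample_id=sample_id, polarity=polarity, features=features)


# ---------------------------------------------------------------------------
# writing (round-trip + sample-wise layout)

def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(x))


def write_mgf(features: Iterable[Feature] | FeatureList, path: str | Path,
              header_comment: str | None = None) -> None:
    """Write features back to MGF, byte-deterministically (sorted by feature id)."""
    feats = sorted(features, key=lambda f: f.feature_id)
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    for f in feats:
        s = f.spectrum
        lines.append("BEGIN IONS")
        lines.append(f"FEATURE_ID={s.feature_id}")
        lines.append(f"PEPMASS={_fmt(s.precursor_mz)}")
        lines.append(f"RTINSECONDS={_fmt(s.rt)}")
        lines.append(f"SCANS={s.feature_id}")
        for p in s.peaks:
            lines.append(f"{_fmt(p.mz)} {_fmt(p.intensity)}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_quant_csv(fl: FeatureList, path: str | Path,
                    header_comment: str | None = None) -> None:
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("feature_id,mz,rt,area")
    for f in sorted(fl.features, key=lambda x: x.feature_id):
        lines.append(f"{f.feature_id},{_fmt(f.mz)},{_fmt(f.rt)},{_fmt(f.area)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_feature_bundle(fl: FeatureList, mgf_path: str | Path, quant_path: str | Path) -> None:
    """Inverse of :func:`read_feature_bundle` (round-trip safe)."""
    write_mgf(fl, mgf_path)
    write_quant_csv(fl, quant_path)


def _write_if_changed(path: Path, writer, overwrite: bool) -> None:
    """Write via ``writer(tmp_path)``; refuse to clobber differing foreign content."""
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    new = tmp.read_bytes()
    if path.exists():
        old = path.read_bytes()
        if old == new:
            tmp.unlink()
            return
        if not overwrite:
            tmp.unlink()
            raise ValidationError(
                f"{path} exists with different content; pass overwrite=True to replace"
            )
    tmp.replace(path)


def layout_sample_directories(
    records: Iterable[SampleRecord],
    bundles: Mapping[tuple[str, str], FeatureList],
    root: str | Path,
    overwrite: bool = False,
) -> list[Path]:
    """Materialize the sample-wise directory architecture under ``root``.

    One directory per sample_id, holding a ``metadata.tsv`` row and one
    subdirectory per polarity with the MGF + quant CSV. Re-running on the same
    inputs is a byte-identical no-op; adding a sample touches only its own
    directory; collision with differing foreign files raises unless
    ``overwrite`` is set.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    created = []
    for rec in records:
        sdir = root / rec.sample_id
        sdir.mkdir(exist_ok=True)
        meta_cols = ["sample_id", "sample_type", "source_id", "source_taxon",
                     "filename_pi", "filename_ni"]
        meta_row = [rec.sample_id, rec.sample_type, rec.source_id, rec.source_taxon,
                    rec.filenames.get("PI", ""), rec.filenames.get("NI", "")]
        _write_if_changed(
            sdir / "metadata.tsv",
            lambda p, row=meta_row: Path(p).write_text(
                "\t".join(meta_cols) + "\n" + "\t".join(row) + "\n"
            ),
            overwrite,
        )
        for pol in POLARITIES:
            fl = bundles.get((rec.sample_id, pol))
            if fl is None:
                continue
            pdir = sdir / pol.lower()
            pdir.mkdir(exist_ok=True)
            _write_if_changed(pdir / f"{rec.sample_id}_{pol}.mgf",
                              lambda p, fl=fl: write_mgf(fl, p), overwrite)
            _write_if_changed(pdir / f"{rec.sample_id}_{pol}_quant.csv",
                              lambda p, fl=fl: write_quant_csv(fl, p), overwrite)
        created.append(sdir)
    return created


def load_sample_directory(sdir: str | Path) -> tuple[SampleRecord, dict[str, FeatureList]]:
    """Read back one sample directory written by :func:`layout_sample_directories`."""
    sdir = Path(sdir)
    rec = parse_sample_metadata(sdir / "metadata.tsv")[0]
    bundles = {}
    for pol in POLARITIES:
        mgf_path = sdir / pol.lower() / f"{rec.sample_id}_{pol}.mgf"
        quant_path = sdir / pol.lower() / f"{rec.sample_id}_{pol}_quant.csv"
        if mgf_path.exists() and quant_path.exists():
            bundles[pol] = read_feature_bundle(mgf_path, quant_path, rec.sample_id, pol)
    return rec, bundles
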