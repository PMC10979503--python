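"""Taxon resolution against a local lineage table and taxonomic distances.

Sample source organisms are resolved to full lineages (domain .. species) so
that annotation candidates can be reranked by how closely their reported
producing organisms match the sample's organism. Resolution is pluggable: the
default resolver is an in-memory table loaded from TSV (a local stand-in for
the Open Tree of Life service); a remote adapter can implement the same
``resolve`` signature. Unresolved names are a value, never an error, and are
never fabricated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from metabokg.errors import SchemaError, ValidationError

#: canonical rank order, shallowest first; index+1 is the rank's depth score
RANKS = ("domain", "kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonRecord:
    """A resolved taxon: queried name, matched canonical name, its lineage and
    external identifiers (OTT id, Wikidata QID) when known."""

    query_name: str
    matched_name: str
    lineage: Mapping[str, str]  # rank -> name, ranks in RANKS order
    external_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.lineage) - set(RANKS)
        if unknown:
            raise ValidationError(f"unknown ranks in lineage: {sorted(unknown)}")
        if self.lineage.get("species") and not self.lineage.get("genus"):
            raise ValidationError("species given without genus")
        # store in canonical rank order
        ordered = {r: self.lineage[r] for r in RANKS if self.lineage.get(r)}
        object.__setattr__(self, "lineage", ordered)


def canonicalize_name(name: str) -> str:
    """Trim, collapse whitespace and strip authority strings after the binomial.

    'Waltheria   indica L.' -> 'Waltheria indica'. Single-word names (genus or
    higher queries) pass through after whitespace normalization.
    """
    words = name.strip().split()
    if len(words) >= 2:
        # keep genus + epithet; epithet must be lowercase latin (authority
        # strings start with an uppercase letter, '(' or contain a period)
        epithet = words[1]
        if re.fullmatch(r"[a-z][a-z\-]+", epithet):
            return f"{words[0]} {epithet}"
        return words[0]
    return " ".join(words)


class TaxonomyTable:
    """Lineage lookup keyed by canonical name.

    Built from a TSV with columns query_name, matched_name, the eight canonical
    ranks, and optional ott_id / wikidata_qid columns.
    """

    def __init__(self, records: list[TaxonRecord]):
        self._by_name: dict[str, TaxonRecord] = {}
        for rec in records:
            key = canonicalize_name(rec.matched_name)
            if key in self._by_name:
                raise ValidationError(f"duplicate taxonomy key {key!r}")
            self._by_name[key] = rec

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
        required = {"matched_name"} | set(RANKS)
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"taxonomy table missing columns {sorted(missing)}")
        records = []
        for _, row in df.iterrows():
            lineage = {r: row[r].strip() for r in RANKS if row[r].strip()}
            ext = {}
            if row.get("ott_id", "").strip():
                ext["ott"] = row["ott_id"].strip()
            if row.get("wikidata_qid", "").strip():
                ext["wikidata"] = row["wikidata_qid"].strip()
            records.append(
                TaxonRecord(
                    query_name=row.get("query_name", row["matched_name"]).strip(),
                    matched_name=row["matched_name"].strip(),
                    lineage=lineage,
                    external_ids=ext,
                )
            )
        return cls(records)

    def resolve(self, name: str) -> Optional[TaxonRecord]:
        rec = self._by_name.get(canonicalize_name(name))
        if rec is None:
            return None
        if rec.query_name == name:
            return rec
        return TaxonRecord(
            query_name=name,
            matched_name=rec.matched_name,
            lineage=rec.lineage,
            external_ids=rec.external_ids,
        )

    def __len__(self) -> int:
        return len(self._by_name)

    def records(self) -> list[TaxonRecord]:
        return list(self._by_name.values())


def resolve_taxon(name: str, table: TaxonomyTable) -> Optional[TaxonRecord]:
    """Exact match after canonicalization; ``None`` marks an unresolved name."""
    return table.resolve(name)


def shared_rank_depth(a: TaxonRecord, b: TaxonRecord) -> tuple[int, Optional[str]]:
    """Count contiguous shared ranks from domain downward.

    Returns ``(depth, deepest_shared_rank)`` with depth in 0..8; identical
    fully specified lineages give ``(8, 'species')``, different domains give
    ``(0, None)``. Symmetric in its arguments; a lineage truncated at rank r
    caps the depth at r's index.
    """
    if a is None or b is None:
        raise ValidationError("shared_rank_depth requires two resolved taxa; "
                              "skip reweighting for unresolved samples")
    depth = 0
    deepest = None
    for rank in RANKS:
        na, nb = a.lineage.get(rank), b.lineage.get(rank)
        if na and nb and na == nb:
            depth += 1
            deepest = rank
        else:
            break
    return depth, deepest
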