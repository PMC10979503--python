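"""MEMO: alignment-free sample fingerprints over document words.

A sample's fingerprint counts, for every two-decimal peak/loss word, the number
of its feature documents containing that word (a word counts once per feature).
Documents from spectra with fewer than ``min_peaks`` peaks are discarded, and
every word observed in any blank sample is removed from all columns, so the
matrix reflects sample chemistry rather than instrument background — without
any cross-sample feature alignment.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd
from scipy.spatial import distance as _ssd

from metabokg.errors import ParameterError, ValidationError
from metabokg.spectral import SpectralDocument

_METRICS = ("braycurtis", "jaccard", "cosine")


def build_memo_matrix(
    docs: Mapping[str, Iterable[SpectralDocument]],
    blanks: Iterable[str] = (),
    min_peaks: int = 10,
) -> pd.DataFrame:
    """Aggregate documents into the sample x word count matrix.

    ``docs`` maps sample_id -> documents of that sample (all polarities);
    ``blanks`` are sample ids whose words define the background to subtract.
    Blank rows are excluded from the output. Raises if ``docs`` is empty or a
    blank id has no documents entry.
    """
    if not docs:
        raise ValidationError("no documents supplied")
    blanks = set(blanks)
    missing = blanks - set(docs)
    if missing:
        raise ValidationError(f"blank sample(s) {sorted(missing)} missing from docs")

    counts: dict[str, Counter] = {}
    for sample_id, sample_docs in docs.items():
        c: Counter = Counter()
        for d in sample_docs:
            if d.n_peaks < min_peaks:
                continue
            c.update(set(d.words))  # once per feature document
        counts[sample_id] = c

    blank_words: set[str] = set()
    for b in blanks:
        blank_words.update(counts[b].keys())

    rows = {
        sid: {w: n for w, n in c.items() if w not in blank_words}
        for sid, c in counts.items()
        if sid not in blanks
    }
    columns = sorted({w for r in rows.values() for w in r})
    matrix = pd.DataFrame(
        [[rows[sid].get(w, 0) for w in columns] for sid in sorted(rows)],
        index=sorted(rows),
        columns=columns,
        dtype=int,
    )
    matrix.index.name = "sample_id"
    return matrix


def remove_blank_words(matrix: pd.DataFrame, blank_words: Iterable[str]) -> pd.DataFrame:
    """Drop background columns from an existing matrix (idempotent)."""
    drop = [c for c in matrix.columns if c in set(blank_words)]
    return matrix.drop(columns=drop)


def memo_distance(matrix: pd.DataFrame, metric: str = "braycurtis") -> pd.DataFrame:
    """Pairwise sample distances on the fingerprint matrix.

    Bray-Curtis (default) and cosine act on counts; Jaccard on
    presence/absence. Square, symmetric, zero diagonal.
    """
    if metric not in _METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if len(matrix) < 2:
        raise ValidationError("need at least two samples")
    values = matrix.to_numpy(dtype=float)
    if metric == "jaccard":
        values = values > 0
    dm = _ssd.squareform(_ssd.pdist(values, metric=metric))
    return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)
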