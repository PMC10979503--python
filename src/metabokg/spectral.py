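"""Spectral preprocessing, modified cosine, per-sample molecular networks and
peak/loss documents.

The modified cosine allows a fragment of one spectrum to match a fragment of
the other either directly (|Δm/z| ≤ tol) or shifted by the precursor-mass
difference, on a one-to-one peak assignment. The variant pinned here selects
assigned pairs greedily by descending intensity product (ties: smaller |Δm/z|,
then lower m/z) and normalizes by the Euclidean intensity norms of the full
peak lists, so scores are reproducible across platforms and bounded by the
optimal-assignment score.

Documents are the multiset of two-decimal ``peak@X.XX`` / ``loss@X.XX`` words
of a spectrum (losses restricted to 10–200 Da from the precursor); they power
the MEMO fingerprints and the cross-sample shared-word queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import networkx as nx

from metabokg.errors import ParameterError, ValidationError
from metabokg.ingest import FeatureList, Peak, Spectrum


@dataclass(frozen=True)
class MNParams:
    """Molecular-network construction parameters.

    Defaults: 0.01 Da fragment tolerance, 0.7 modified-cosine edge cutoff,
    top_n 15, max_links 10, no minimum matched-peak count.
    """

    fragment_tol: float = 0.01
    score_cutoff: float = 0.7
    top_n: int = 15
    max_links: int = 10
    min_matched_peaks: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.score_cutoff <= 1):
            raise ParameterError("score_cutoff must be in (0, 1]")
        if not (self.top_n >= self.max_links >= 1):
            raise ParameterError("need top_n >= max_links >= 1")
        if self.fragment_tol <= 0:
            raise ParameterError("fragment_tol must be positive")


@dataclass(frozen=True)
class ScorePair:
    """A modified-cosine score with its matched-peak count."""

    score: float
    n_matched: int

    def __post_init__(self) -> None:
        if self.n_matched == 0 and self.score != 0.0:
            raise ValidationError("zero matched peaks implies zero score")


@dataclass
class MolecularNetwork:
    """Undirected per-sample similarity network over feature ids."""

    nodes: list[int]
    edges: list[tuple[int, int, ScorePair]]
    components: list[frozenset[int]]
    params: MNParams

    def as_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, j, sp in self.edges:
            g.add_edge(i, j, score=sp.score, n_matched=sp.n_matched)
        return g

    def component_of(self) -> dict[int, int]:
        """Map feature id -> component index (components sorted by min member)."""
        return {n: k for k, comp in enumerate(self.components) for n in comp}


@dataclass(frozen=True)
class SpectralDocument:
    """Two-decimal peak/loss words of one spectrum.

    Words rounded to the same two decimals collapse to a single occurrence;
    ``n_peaks`` keeps the source spectrum's peak count for the MEMO minimum-
    peak filter.
    """

    feature_id: int
    peak_words: tuple[str, ...]
    loss_words: tuple[str, ...]
    n_peaks: int

    @property
    def words(self) -> tuple[str, ...]:
        return self.peak_words + self.loss_words


def filter_relative_intensity(s: Spectrum, lo: float = 0.01, hi: float = 1.0) -> Spectrum:
    """Normalize to the base peak and keep peaks with relative intensity in
    [lo, hi] (boundaries inclusive)."""
    if not s.peaks:
        raise ValidationError("cannot filter an empty spectrum")
    base = max(p.intensity for p in s.peaks)
    if base <= 0:
        raise ValidationError("all-zero intensities")
    kept = tuple(
        Peak(p.mz, p.intensity / base)
        for p in s.peaks
        if lo <= p.intensity / base <= hi
    )
    return Spectrum(
        feature_id=s.feature_id,
        precursor_mz=s.precursor_mz,
        rt=s.rt,
        polarity=s.polarity,
        peaks=kept,
    )


def compute_neutral_losses(
    s: Spectrum, min_loss: float = 10.0, max_loss: float = 200.0
) -> list[tuple[float, float]]:
    """Neutral losses precursor − fragment within [min_loss, max_loss] Da,
    intensities inherited from the fragment peaks."""
    out = []
    for p in s.peaks:
        loss = s.precursor_mz - p.mz
        if min_loss <= loss <= max_loss:
            out.append((loss, p.intensity))
    return out


def _round2(x: float) -> str:
    """Two-decimal string, half rounded away from zero on the decimal
    representation (cross-implementation stable, unlike float banker's
    rounding)."""
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def to_spectral_document(s: Spectrum) -> SpectralDocument:
    """Translate a (preprocessed) spectrum into its two-decimal document."""
    peak_words = sorted({f"peak@{_round2(p.mz)}" for p in s.peaks})
    loss_words = sorted({f"loss@{_round2(mz)}" for mz, _ in compute_neutral_losses(s)})
    return SpectralDocument(
        feature_id=s.feature_id,
        peak_words=tuple(peak_words),
        loss_words=tuple(loss_words),
        n_peaks=len(s.peaks),
    )


def _greedy_assignment(
    peaks_a: list[Peak], peaks_b: list[Peak], tol: float, shift: float
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one assignment over direct/shifted candidate pairs.

    Candidates ordered by descending intensity product, ties by smaller
    matched |Δm/z| then lower m/z (a's peak, then b's). Returns
    (index_a, index_b, intensity_product) triples.
    """
    candidates = []
    for i, p in enumerate(peaks_a):
        for j, q in enumerate(peaks_b):
            d = p.mz - q.mz
            direct = abs(d)
            shifted = abs(d - shift)
            if direct <= tol or shifted <= tol:
                delta = min(direct, shifted)
                candidates.append((p.intensity * q.intensity, delta, p.mz, q.mz, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    assigned = []
    for prod, _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        assigned.append((i, j, prod))
    return assigned


def _cosine_from_assignment(
    peaks_a: list[Peak], peaks_b: list[Peak], assigned: list[tuple[int, int, float]]
) -> ScorePair:
    if not assigned:
        return ScorePair(0.0, 0)
    norm_a = math.sqrt(sum(p.intensity ** 2 for p in peaks_a))
    norm_b = math.sqrt(sum(p.intensity ** 2 for p in peaks_b))
    if norm_a == 0 or norm_b == 0:
        return ScorePair(0.0, 0)
    score = sum(prod for _, _, prod in assigned) / (norm_a * norm_b)
    return ScorePair(min(score, 1.0), len(assigned))


def modified_cosine(a: Spectrum, b: Spectrum, tol: float = 0.01) -> ScorePair:
    """Modified cosine: direct or precursor-shift fragment matches on a greedy
    one-to-one assignment; score in [0, 1], symmetric, invariant to uniform
    intensity scaling."""
    if tol <= 0:
        raise ParameterError("tolerance must be positive")
    if not a.peaks or not b.peaks:
        raise ValidationError("both spectra need at least one peak")
    shift = a.precursor_mz - b.precursor_mz
    assigned = _greedy_assignment(list(a.peaks), list(b.peaks), tol, shift)
    return _cosine_from_assignment(list(a.peaks), list(b.peaks), assigned)


def cosine_zero_shift(a: Spectrum, b: Spectrum, tol: float = 0.01) -> ScorePair:
    """Direct-match cosine (no precursor shift): the identity-search variant
    used for spectral-library matching."""
    if tol <= 0:
        raise ParameterError("tolerance must be positive")
    if not a.peaks or not b.peaks:
        return ScorePair(0.0, 0)
    assigned = _greedy_assignment(list(a.peaks), list(b.peaks), tol, shift=0.0)
    return _cosine_from_assignment(list(a.peaks), list(b.peaks), assigned)


def build_molecular_network(fl: FeatureList, params: MNParams | None = None) -> MolecularNetwork:
    """Per-sample molecular network.

    All pairwise modified cosines are computed; candidate edges need
    score ≥ cutoff and n_matched ≥ min_matched_peaks; an edge survives only if
    each endpoint ranks the other within its top_n neighbors, then each node
    keeps at most max_links incident edges (kept by both endpoints). Edge
    ordering for top_n/max_links: higher score, more matched peaks, then
    lexicographic (i, j) — deterministic by construction.
    """
    params = params or MNParams()
    feats = sorted(fl.features, key=lambda f: f.feature_id)
    if not feats:
        raise ValidationError("feature list is empty")
    ids = [f.feature_id for f in feats]
    spectra = {f.feature_id: f.spectrum for f in feats}

    candidate: dict[tuple[int, int], ScorePair] = {}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            sp = modified_cosine(spectra[i], spectra[j], params.fragment_tol)
            if sp.score >= params.score_cutoff and sp.n_matched >= params.min_matched_peaks:
                candidate[(i, j)] = sp

    def edge_key(pair: tuple[int, int]) -> tuple:
        sp = candidate[pair]
        return (-sp.score, -sp.n_matched, pair)

    neighbors: dict[int, list[tuple[int, int]]] = {i: [] for i in ids}
    for (i, j) in candidate:
        neighbors[i].append((i, j))
        neighbors[j].append((i, j))

    # mutual top_n rule
    topn: dict[int, set[tuple[int, int]]] = {}
    for n, inc in neighbors.items():
        topn[n] = set(sorted(inc, key=edge_key)[: params.top_n])
    surviving = [e for e in candidate if all(e in topn[v] for v in e)]

    # max_links per node, edge kept only if retained by both endpoints
    incident: dict[int, list[tuple[int, int]]] = {i: [] for i in ids}
    for e in surviving:
        incident[e[0]].append(e)
        incident[e[1]].append(e)
    kept_per_node = {
        n: set(sorted(inc, key=edge_key)[: params.max_links]) for n, inc in incident.items()
    }
    final = sorted(e for e in surviving if all(e in kept_per_node[v] for v in e))

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(final)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )
    return MolecularNetwork(
        nodes=ids,
        edges=[(i, j, candidate[(i, j)]) for i, j in final],
        components=components,
        params=params,
    )


# ---------------------------------------------------------------------------
# exports

def export_edge_csv(net: MolecularNetwork, path: str | Path) -> None:
    lines = ["source,target,score,n_matched"]
    for i, j, sp in net.edges:
        lines.append(f"{i},{j},{sp.score!r},{sp.n_matched}")
    Path(path).write_text("\n".join(lines) + "\n")


def export_graphml(net: MolecularNetwork, path: str | Path) -> None:
    nx.write_graphml(net.as_networkx(), str(path))


def export_documents(docs: list[SpectralDocument], path: str | Path) -> None:
    """One line per feature: ``feature_id<TAB>word word ...``."""
    lines = [f"{d.feature_id}\t{' '.join(d.words)}" for d in docs]
    Path(path).write_text("\n".join(lines) + "\n")


def documents_for_feature_list(
    fl: FeatureList, lo: float = 0.01, hi: float = 1.0
) -> list[SpectralDocument]:
    """Intensity-filter every spectrum of an analysis and build its document."""
    return [to_spectral_document(filter_relative_intensity(f.spectrum, lo, hi)) for f in fl]
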