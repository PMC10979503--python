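# Methods

## Scope and data model

`metabokg` operates strictly per sample: every extract is processed in
isolation (feature lists, molecular network, spectral documents, annotations)
and only the resulting RDF graphs are combined. This makes a campaign
incrementally extensible — adding an extract never requires reprocessing or
re-aligning the others — at the cost of not producing a cross-sample aligned
feature table. Cross-sample structure emerges instead from shared graph nodes:
taxa, chemical structures (2D InChIKeys), and two-decimal spectral words.

The unit of processing is the LC-MS feature: a chromatographic peak with
*m/z*, retention time (stored in seconds), area, and exactly one MS² spectrum.
Feature finding itself is upstream; the package ingests MGF + CSV exports and
joins them on feature id (inner join — only features with an MS² scan are
usable downstream, so unmatched rows are dropped with a warning rather than
an error).

## Modified cosine

Two spectra are compared by a cosine over a one-to-one fragment assignment in
which a fragment pair may match directly (|Δm/z| ≤ tol) or shifted by the
precursor-mass difference (|Δm/z − Δprecursor| ≤ tol); the shift term lets
analogs differing by one substituent still align their common fragments.
Since the exact assignment strategy differs between implementations, this
package pins one reproducible variant:

* raw intensities (no m/z weighting, intensity power 1);
* candidate pairs sorted by descending intensity product, ties broken by
  smaller matched |Δm/z|, then lower m/z — greedy selection under the
  one-to-one constraint;
* normalization by the Euclidean intensity norms of the *full* peak lists, so
  the score is in [0, 1], symmetric, and invariant to uniform intensity
  scaling.

The greedy score is bounded above by the maximum-weight assignment; the test
suite checks this bound against an exhaustive matching oracle on small
spectra, and cross-checks scores against matchms' implementation on fixtures
where the optimal assignment is unique. Greedy selection can in principle be
sub-optimal, but at typical fragment densities the two coincide (observed on
the majority of random pairs at ≤ 6 peaks).

Molecular networks use the standard feature-based-networking pruning: edges
require score ≥ 0.7 (fragment tolerance 0.01 Da), both endpoints must rank
each other within their top 15 neighbors, and each node then keeps at most
its 10 best incident edges (an edge survives only if both endpoints keep it).
Edge ordering for pruning is (score desc, matched peaks desc, node-id pair),
making the edge list byte-deterministic. `min_matched_peaks` defaults to 0
for networking; the library-matching threshold of 6 applies only to
annotation.

## Spectral documents and MEMO

Before document generation, intensities are normalized to the base peak and
peaks with relative intensity in [0.01, 1] are kept (both boundaries
inclusive — "between" read inclusively). Words are `peak@X.XX` for each
fragment and `loss@X.XX` for each neutral loss (precursor − fragment) in
[10, 200] Da, rounded to two decimals with half-away-from-zero rounding
applied to the decimal representation (`Decimal(repr(x))`), not float
banker's rounding — this keeps documents stable across implementations.
Duplicate words after rounding collapse to a single occurrence per feature;
the alternative (intensity-weighted multiplicity) is deliberately not used so
documents are insensitive to peak-list densification.

The MEMO matrix counts, per sample, the number of feature documents
containing each word; documents from spectra with fewer than 10 peaks are
discarded, and any word occurring in any blank sample is removed from all
columns. Blanks are pooled globally (a per-batch grouping can be emulated by
building matrices per batch). Distances: Bray–Curtis by default (standard for
count fingerprints), Jaccard on presence/absence, cosine on counts — via
scipy. Because fingerprints are per-sample, adding a sample without a new
blank changes only its own row.

## Annotation cascade

1. **MS² library search.** Candidate library entries are gated by parent mass
   (±0.01 Da against the entry's [M+H]⁺ or [M−H]⁻ m/z by polarity), scored
   with a *zero-shift* cosine — the library entry is a spectrum of the
   candidate itself, so precursor-shifted matches would be spurious — and
   kept if score ≥ 0.2 with ≥ 6 matched fragments.
2. **MS1 fallback.** Features without an MS² hit are matched on parent mass
   only (±10 ppm) against the adduct m/z of structures reported in the
   sample's species; such candidates carry spectral score 0.
3. **Taxonomic reranking.** Each candidate's taxonomic score is the deepest
   rank shared between the sample's organism and any organism the structure
   is reported from, on the points scale domain = 1, kingdom = 2, …,
   genus = 7, species = 8. The confidence filter's "taxonomic score ≥ 6"
   therefore means family-or-deeper. The combined score is
   `(spectral + taxo/8) · boost`: the 1/8 weight makes the maximal taxonomic
   contribution equal to the maximal spectral contribution. This points
   scale and weight are package conventions; only the ≥ 6 gate is fixed by
   the downstream filter.
4. **Chemical-consistency reweighting.** Within each network component of
   ≥ 2 features, the modal NPClassifier class of the current rank-1
   candidates defines a consensus; candidates of that class get a
   multiplicative boost 1 + α (α = 0.5). A modal tie applies no boost
   (conservative). Candidates are re-ranked with deterministic tie-breaking
   (final score desc, spectral desc, structure id), so the rank-1 set never
   depends on input order.

External SIRIUS/CSI:FingerID and CANOPUS results are ingested, never
computed. The confident-annotation set is the union of SIRIUS structures with
COSMIC > 0.5 **and** ZODIAC > 0.8 (both strict) and rank-1 ISDB candidates
with taxonomic score ≥ 6 (inclusive) — mirroring the wording "above"
vs "≥" per gate.

## Mass arithmetic

Monoisotopic masses come from pyteomics' NIST table (supported elements
C, H, N, O, P, S, F, Cl, Br, I, Na, K); adduct m/z is
`(mass(M) + mass(Δ) − z·mₑ)/|z|` with the electron mass included — omitting
it shifts [M+H]⁺ by ~1.1 ppm at m/z 500, enough to miss sub-ppm agreement
with measured high-resolution values. The calculated [M+H]⁺ of C₃₀H₄₀O₅,
C₃₀H₄₀O₄ and C₃₀H₃₈O₆ (481.2949, 465.2999, 495.2741) agree with the measured
481.2950 / 465.3002 / 495.2754 within their reported errors (0.33, 0.69,
2.69 ppm), and [M+H]⁺ − [M−H]⁻ equals exactly two proton masses.

## Knowledge graph

Each processing step's parameters are serialized canonically (sorted-key
JSON) and digested with MD5 — a standard 128-bit hash matching the 32-hex
provenance suffix convention — into the IRI of the produced node, so
identical parameters yield identical IRIs across runs, platforms, and key
orderings. Literals carry explicit XSD datatypes (doubles with `repr`
lexical forms, which round-trip floats exactly). Turtle serialization is a
custom deterministic writer (prefix block + triples sorted by subject,
predicate, object, rendered via rdflib's namespace manager): two
serializations of equal graphs are byte-identical and serialize → parse →
serialize is a fixed point; parsing uses rdflib. The campaign graph is the
set union of per-sample graphs — shared taxa, structures and word nodes
deduplicate by IRI, and merging never alters existing triples.

Queries run on an in-memory index distilled from the graph (pure functions:
identical graph → identical rows, with a stated sort key per query). The
fragment-presence query runs on spectra rather than the graph because the
two-decimal word nodes deliberately do not store intensities, and the query
needs the ≥ 50 % relative-intensity condition. Bioactivity thresholds
(minimum inhibition, maximum cytotoxicity) are mandatory parameters: the
package records percent inhibition and refuses to presume an activity cutoff.

## Synthetic study design

The reference design is 10 extracts + 2 blanks over 6 species in 3 plant
families (Malvaceae, Celastraceae, Solanaceae), 30 library structures, seed
42. Structures carry CHNO formulas drawn so all [M+H]⁺ masses are ≥ 0.05 Da
apart (the parent-mass gate then isolates a single true candidate); each
structure is "reported" in 1–2 species of one family, and its chemical class
is the family's signature class, so the quinone-methide class exists only in
the three Celastraceae extracts (the planted "active" group, which also
receives high inhibition / low cytotoxicity values, next to one
active-but-cytotoxic decoy sample). Sample spectra are copies of the library
spectra with ≤ 0.005 Da fragment jitter, ≤ 0.003 Da precursor jitter and
± 20 % intensity jitter — inside the 0.01 Da matching tolerance, emulating
instrument error. One structure reported across two genera is planted as an
*exact* spectral copy in several samples (co-detected compound), four PI
features get NI twins at exactly −2 proton masses and identical retention
time, and fixed background spectra appear in both blanks and samples.
Retention times are unique per structure (37 s spacing), so cross-polarity
windows (±3 s) cannot produce accidental pairs.

What the generator does **not** emulate: real fragmentation chemistry (peaks
are uniform random), isotope patterns, co-elution and chimeric spectra,
retention-time drift between samples, and realistic class-structure
correlation. Passing end-to-end tests therefore demonstrates that the
pipeline's bookkeeping, thresholds, arithmetic and graph semantics are
correct under controlled noise — not that annotation would reach the same
recovery on real data, where spectral ambiguity dominates.

## Numerical and degenerate-input choices

* Rounding of document words: half away from zero on the decimal string.
* All-zero-intensity spectra are rejected at preprocessing; empty libraries
  yield empty candidate lists (not errors); unresolved taxa are values, and
  reweighting with an unresolved sample taxon leaves all taxonomic scores 0.
* Seeds: a single `numpy` generator per fixture run; the study seed is
  embedded in every emitted file header.
* Problem sizes: the default study (10 samples, ~9 features each, 30
  structures) processes end-to-end in about two seconds on one CPU; the
  property suites use 200 random spectrum pairs at ≤ 6 peaks where the
  exhaustive assignment oracle is exact.

## Known limitations

* The greedy assignment is not guaranteed optimal; scores are reproducible
  but can differ from assignment-optimal implementations on pathological
  tie structures.
* Taxon resolution is exact-match after canonicalization against a local
  lineage table; no fuzzy matching or synonymy. A remote resolver can be
  plugged in via the same interface.
* The RDF schema is a reconstruction of the sample-centric data model's named
  links; predicate naming may differ from other implementations of the same
  idea, so graphs are interoperable at the level of structure, not vocabulary.
* SPARQL rendering of the queries is not implemented; queries run on the
  in-memory index only.
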