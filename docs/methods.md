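# Methods

This note documents the models and procedures implemented in `dggetax`,
the choices made where the design was genuinely open, and what the
synthetic data does and does not establish.

## Global alignment and percent similarity (`seqcore`)

Queries are compared to references by minimum-penalty global alignment
(Needleman–Wunsch over a three-state Gotoh recursion, numba-compiled).
The cost model charges `mismatch_cost` per substitution column
(default 1), `match_cost` for identities (default 0), and
`gap_open_cost + L · gap_extend_cost` for a gap run of length `L`
(defaults 1 and 1, so a single-base indel costs 2). Two conventions
deserve note:

* **Gap-run arithmetic.** "Penalty 1 to open and 1 to extend" is
  ambiguous about whether a length-L run costs `1 + L` or `L`. We adopt
  the standard affine convention `open + L · extend`; both penalties
  are independently configurable, so the other reading is one parameter
  away.
* **Terminal gaps are charged.** The point of using global rather than
  local alignment is that a fragment is *not* a free match to a
  full-length reference; similarity of a half-length fragment to its
  exact source is ~50%, not 100%. Callers comparing fragments should
  trim references (or use the `fragment_window` of the clone generator)
  to comparable coordinates.
* **Similarity denominator.** `S = 100 · identities / alignment
  columns` (gap columns included), penalizing indels symmetrically.
  A `denominator="shorter"` option divides by the shorter ungapped
  length instead; it is not the default.
* **Ambiguity.** `N` never counts as an identity and always costs a
  mismatch — a conservative choice that can only lower similarity.
* **Determinism.** Co-optimal alignments are resolved by a fixed
  traceback preference (substitution column, then gap in the reference
  row, then gap in the query row), so outputs are reproducible. Ties in
  batch rankings break lexicographically by reference id.

Optimality is verified three ways in the tests: literal enumeration of
every alignment (tiny strings), an independent top-down exhaustive
search (all pairs up to length 9), and `Bio.Align.PairwiseAligner`
with the equivalent score model (longer pairs).

## Threshold-ladder consensus classification (`taxclass`)

All similarities are computed once per query; the ladder
99, 98.5, 98, 97.5, 97, 96, 95, 94, 93, 92, 91, 90, 85, 80 is walked
from the top and the **first** non-empty hit set (inclusive boundary,
`S ≥ t`) resolves the query; lower steps are not revisited. The
consensus is the longest common prefix of the retained hits' lineages
along domain > phylum > class > order > family > genus > species,
computed over hits (a multiset), not unique taxa; partial reference
lineages cap the consensus at their own depth. Conflict at phylum
leaves only "Bacteria"; no hit at 80% leaves the query unassigned, with
no lineage guessed.

Consequences worth knowing: because the ladder stops at the first
non-empty step, a query whose single nearest reference is retrievable
at some step always receives that reference's full lineage depth — the
consensus only shallows when the resolving bin contains conflicting
references. With wide bins at the bottom of the ladder (90 → 85 → 80)
this happens readily for highly diverged queries.

## Environment-neighbor counting (`envneighbors`)

A database record is a valid neighbor when its similarity **strictly**
exceeds the threshold (default 95%) — deliberately different from the
classifier's inclusive boundary; each rule follows its own stated
wording, and the distinction is observable (a record at exactly 95.0 is
excluded). Keyword flags are case-insensitive plain-substring matches
over the whole annotation: "uranium" or "radionuclide" raises the
uranium flag (pooling is configurable), "iron" the iron flag. No
stemming or word boundaries are applied; note that the substring
"iron" occurs inside common words such as "environment", so real-world
annotations should be screened with that pitfall in mind (the synthetic
annotations avoid such words, keeping generator truth exact). Zero
counts are rendered as "-" only at the output boundary; internally they
are integers.

## Fingerprint ordination (`fingerprint`)

* **Normalization.** Each lane is scaled so its band intensities sum to
  exactly 100, making lanes relative-abundance profiles and removing
  loading differences between gel lanes. All-zero lanes are rejected by
  name.
* **PCA.** Covariance PCA on band-centered intensities (backed by
  scikit-learn's exact SVD solver). Bands are *not* scaled to unit
  variance: after lane normalization, intensity differences between
  bands are signal. Correlation-based and presence/absence variants are
  available behind flags. Component signs are arbitrary in PCA; we fix
  each component so its largest-magnitude loading is positive, making
  scores, loadings and band rankings reproducible. Trailing components
  with numerically zero variance are dropped and the variance fractions
  renormalized to sum to 100. A rank-0 (all-lanes-identical) table is
  an error.
* **Confidence ellipses.** Per group with ≥ 3 lanes, the ellipse is the
  population-coverage ellipse: sample mean and covariance of the
  (PC1, PC2) scores, semi-axes `sqrt(eigval · χ²₂(coverage))` with
  coverage 0.90 by default. This encloses ~90% of the group's *samples*
  under a Gaussian model (verified by Monte Carlo to ±1 point), rather
  than a standard-error ellipse of the mean — appropriate because the
  published figures' ellipses enclose individual sample points.
  Collinear scores yield a flagged degenerate minor axis.
* **Discriminant bands.** The `n` bands with the greatest *signed*
  loadings on a chosen axis (default PC1, n = 6), ties broken by band
  id. Signed, not absolute: with the sign convention above, the
  positive direction of PC1 is the one carrying the dominant
  group-specific bands, and selection by greatest value mirrors
  excising the bands on one side of the axis.

## Synthetic data (`synthetic_data`)

The generators emulate the study inputs with exact ground truth:

* **Reference taxonomy** — an ancestral 550-nt sequence (the length of
  a typical V3–V5 16S fragment) evolved down a systematic tree
  (3 phyla × 2 classes × 1 order × 2 families × 2 genera × 2
  references = 48 references by default). Per-rank divergence rates
  (0.20, 0.12, 0.08, 0.05, 0.018, 0.008 for phylum … genus, reference)
  decrease with depth, so intra-genus similarity > intra-family >
  intra-phylum by construction, and sibling genera sit close enough
  (~95–96% to a same-family genus) that highly diverged queries reach
  consensus conflicts inside the ladder's wide bottom bins.
  Substitutions are Jukes–Cantor-like (uniform over the three
  alternative bases, no transition/transversion bias) — sufficient to
  exercise similarity thresholds, easy to calibrate.
* **Clone libraries** — 144 clones by default (a band-sequencing
  campaign's scale), each a seeded mutated copy (substitutions, and
  optionally single-base indels) of a sampled reference, optionally
  truncated to a fragment window before mutation. Truth tables record
  source, lineage, and realized substitution/indel counts; the realized
  substitution fraction is binomially calibrated against the requested
  rate.
* **Annotated database** — mutated relatives of the references (uniform
  divergence in [0, 0.15] by default) with free-text annotations;
  uranium/iron keywords are planted independently with probability 0.3
  each.
* **Band tables** — 6 uranium + 6 control lanes, 28 shared + 6 + 6
  group-specific bands (≈ 40 bands per lane, within the 25–40 a soil
  community typically shows). Intensities are per-band log-normal base
  levels times multiplicative log-normal noise (CV 0.35, set so PC1
  carries roughly 40–50% of the variance with clear group separation,
  the regime reported for real uranium/control gels); drop-out (5%)
  zeroes individual bands.

What the synthetic data does **not** emulate: real 16S evolution
(rate heterogeneity, chimeras, PCR bias), gel-migration physics and
band co-migration, database annotation noise, or the actual Silva/EMBL
content. Passing tests therefore demonstrate that the algorithms are
implemented correctly and behave as designed under controlled
conditions — not that the published community-level numbers are
recovered, which would require the unpublished gel tables and a
2011-era database snapshot.

## Problem sizes and numerics

Default test and acceptance workloads use the 48-reference database,
200-clone recovery runs, 60-record annotated databases, 12-lane band
tables and 10,000-point ellipse simulations — sizes chosen to give
tight statistical checks (binomial error on a 200-clone recovery rate
is ~1.5%) while keeping a full run in the order of a minute. Alignment
DP uses float64 costs with an absolute tie tolerance of 1e-9;
normalization is exact to < 1e-9 per lane; PCA agreement with the
eigendecomposition oracle is asserted at 1e-8; ellipse coverage at ±1
percentage point.

## Known limitations

* The percent-similarity engine is O(len(query) · len(ref)) per pair
  with no heuristic prefilter; it is meant for hundreds of queries
  against curated reference sets, not database-scale search.
* The classifier reports no confidence measure (no bootstrap); the
  resolving threshold itself is the only quality signal.
* Whether the original analysis recomputed consensus at every ladder
  step or only the first non-empty one is ambiguous; the first-nonempty
  reading is implemented.
* Keyword flags are annotation-text only; they know nothing about
  sequence provenance or study metadata.
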