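# Methods

## The identification problem

A barcode library is a set of aligned COI sequences in a fixed 658-column
frame, each labelled with species, genus and order. Identification is
simulated leave-one-out: each record in turn is the query, all remaining
records are the reference database, and the query is scored under a
criterion. Only the outcome `correct` counts toward the proportion of
correct matches; `ambiguous` (distance ties spanning species), `incorrect`
and `no_id` all count against. Queries for which no pairwise distance is
defined are dropped from the denominator and reported as such.

The library rules mirror standard curation: records need ≥ 550 determined
bases; open-nomenclature names (`sp.`, `cf.`, `nr.`, `aff.`, digits-only
epithets — a configurable regex list, since any such rule is open-ended)
can be excluded; and a "dataset A" library keeps species with ≥ 2 records
(every query has a conspecific match available) while "dataset B" keeps
species with ≥ 3 (required by ASB, which needs two conspecifics per query).

## K2P distances

`d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)` over the columns where both sequences
hold an unambiguous A/C/G/T (pairwise deletion — the natural choice with
ragged 550–658 bp records, and the convention of the classical
identification tools). Design points:

- **Undefined, never clamped.** A pair is NaN when fewer than `min_sites`
  columns are comparable (default 100) or a log argument is ≤ 0
  (saturation). Undefined pairs are excluded from every summary; they are
  never silently zero or capped.
- **Percentiles** interpolate linearly between order statistics (the
  dominant convention). The BCM threshold is the 95th percentile of all
  defined intraspecific pairwise distances.
- **Summary conventions.** The intraspecific band is `[0, 95th percentile]`
  (its lower bound is structurally 0, and the upper bound must coincide
  with the BCM threshold construction); the congeneric interspecific band
  is the central `[2.5th, 97.5th]` of per-species-pair means (one mean per
  unordered pair of distinct congeneric species). The overlap fraction
  pools both classes and counts values strictly inside (inter lower bound,
  intra upper bound). Raw congeneric sequence-pair distances and per-class
  overlap fractions are also exposed, since "overlap" can be read per class
  or pooled.

The matrix is computed by one-hot matrix products (exact integer counts in
float32), so a 1,000-record library takes well under a second; a scalar
`k2p` is kept as the elementwise reference path.

## Identification criteria

- **BM**: ties at the minimum distance (exact after a 1e-10 guard — K2P on
  identical discrete inputs is bit-identical, so genuine ties are exact)
  are `correct` only if all tied matches are conspecific, `ambiguous` if
  they span species including the query's, `incorrect` otherwise.
- **BCM**: identical to BM below the threshold; at or above it, `no_id`
  ("below" is strict). Note a structural consequence: because the threshold
  is an in-library 95th percentile, BCM censors a few percent of queries
  even when the barcoding gap is perfect, so BCM ≤ BM always — matching the
  small BM/BCM gap seen in real benchmarks.
- **ASB**: `correct` iff the worst conspecific distance is strictly below
  the best other-species distance; a tie there is `ambiguous`; any other
  failure is `no_id`. Conspecifics with undefined distance to the query
  cannot be ranked and are excluded from the requirement.
- **NJT**: neighbor joining (Saitou–Nei) on the K2P matrix; Q-criterion
  ties within 1e-10 are broken by a seeded uniform draw, so trees are
  reproducible. A species is correctly identified when its member set is
  exactly one side of some edge bipartition of the unrooted tree — the
  rooting-invariant reading of "forms a monospecific clade" (a rooted
  reading would depend on arbitrary rooting of NJ output). Singleton
  species are trivially monospecific (a leaf edge); identical sequences
  stay separate leaves so denominators are unchanged. NJ is O(n³); a
  per-order mode builds one tree per order, and records involved in
  undefined pairs are pruned greedily (most-undefined first) before tree
  building and leave the denominator.

## Experiments

**Criterion × order replicates.** Outcomes are computed once over the full
library; each order's records are then randomly split into 3 groups (one
per criterion) × 3 sub-groups, and each sub-group's proportion correct
under its group's criterion is one replicate. This yields a balanced
criterion × order × 3 table without changing the reference database per
cell (re-evaluating inside cells would alter what "the library" is, which
the replicated-design idea does not require). Cell sizes differ by ≤ 1.

**Mini-barcodes.** MB1/MB2/MB3 are columns 1–220, 221–439, 440–658
(1-based, closed). Shorter fragments are center-trimmed, the extra column
removed at the 3' end when the excess is odd. Distances, the BCM threshold
and (for NJT) the trees are recomputed per fragment; the minimum
compared-site rule scales as `min(100, frame_width // 2)` so 55- and 22-bp
fragments remain evaluable while grossly under-covered pairs are still
excluded. The full-barcode point enters each fragment's series at x = 658.

**Taxon coverage.** Species (not records) are sampled without replacement;
all records of a sampled species are kept; everything — distances,
threshold, evaluation — is recomputed inside the subsample, so queries
never see sequences outside it. The full-library point is appended at the
total species count.

## Statistics

- **ANOVA**: balanced two-way mixed model, criterion fixed, order random;
  F(criterion) = MS(Cr)/MS(Cr×Or), F(order) and F(interaction) against the
  residual; with 3 × 6 × 3 observations the df are (2, 5, 10, 36), total
  53. Sums of squares partition exactly. Mean squares at floating-point
  dust (constant data) yield NaN F rather than noise ratios.
- **Cochran's C** = max cell variance / sum of cell variances; the critical
  value comes from the F-relation `C* = [1 + (k-1)/F_{α/k}(ν, (k-1)ν)]⁻¹`
  rather than digitized tables.
- **SNK**: means ranked, spans of size p tested against
  `q(α, p, df) · sqrt(MS_err/n)` from the studentized range, spans inside
  accepted homogeneous spans never re-tested. For the criterion main effect
  the error term is MS(Cr×Or) with n = orders × replicates per criterion;
  within-interaction comparisons use the residual MS with n = replicates.
- **Decay fits**: `y0 + a·exp(-x/t)` by Levenberg–Marquardt with
  multi-start over t ∈ {25, 50, 100, 200}, y0 starting at max(y) and a at
  the shortest-fragment offset; best RSS with t > 0 wins; no sign
  constraint on a (both signs occur in practice). Noiseless model data are
  recovered to machine precision (RSS < 1e-12). Curves are compared by the
  extra-sum-of-squares F-test; families of such tests are
  Benjamini–Hochberg corrected.
- **Coverage regression**: OLS with intercept via statsmodels; a constant
  response (a criterion perfect at every size) returns slope 0 and R² 0
  instead of a degenerate fit.

## The synthetic generator

Star phylogenies at four levels under the Kimura 1980 substitution model
(exact per-site transition probabilities, not a Poisson approximation, so
expectations are exact at any distance; the rate matrix is scaled so branch
length is expected substitutions/site, and at those probabilities the
plug-in K2P of a parent/child pair equals the branch length identically).
Branches: root → order ancestors `d_order/2`; order → genus ancestors
`d_genus/2`; genus → species ancestors `(d_inter − d_intra)/2` (clamped at
0); species → individuals `d_intra/2`. Paths add, so the *measured*
expectations sit on the dials: conspecific individuals at `d_intra`,
congeneric individuals at `d_inter` — which is what makes the overlap of
the two measured distributions directly controllable. The upper levels are
kept on finite branches deliberately: fully independent random ancestors
would sit at the K2P saturation boundary (E[Q] = 0.5), voiding about half
of all between-genus distances and with them any NJ tree.

Ragged ends are a uniform-length (550–658) contiguous block at a uniform
offset; columns outside it are 'N' ('-' is reserved for true indels, never
generated). No indels, no rate heterogeneity across sites, no coalescent
within species, no non-star topology — so the generator reproduces the
*distance structure* the criteria consume, not sequence evolution at large.
Passing tests on synthetic libraries therefore demonstrate correctness of
the pipeline's arithmetic and decision rules under controlled divergences;
they do not by themselves certify performance on real libraries, where
intraspecific divergence varies across species, species are not
equidistant, and label noise exists.

Defaults (the package's study conditions, chosen once): 6 orders × 10
genera × 3 species × 3 individuals (540 records, 180 species — dataset-B
qualified), 658 columns, `d_intra = 0.02`, `d_inter = 0.10`,
`d_genus = d_order = 0.20`, `kappa = 3`. These sit inside the ranges
reported for dense insect COI libraries (intraspecific 95% bound of a few
percent, congeneric distances centered near 10%, transition/transversion
ratios of 2–6, deep divergences around 20%). Because divergences are
single-valued the two distributions are tight and the defaults show a clear
barcoding gap; the heavy-overlap regime is obtained by bringing the dials
together (e.g. 0.05 vs 0.06), which the acceptance script runs as a second
condition. Problem sizes throughout (a few hundred records per library,
three coverage sizes, 20-seed trend checks) are the package's own
desk-scale choices: large enough for the Monte-Carlo tolerances used, small
enough that the whole suite runs in minutes on one core.

## Known limitations

- K2P saturation and the minimum-site rule mean very short fragments (22
  bp) drop some pairs; NJT prunes affected records, slightly shrinking its
  denominators there.
- The SNK relation string is only a total order when homogeneous subsets do
  not overlap; overlapping subsets are reported as subsets.
- The ANOVA is exactly the balanced fixed × random × replicates design —
  no general unbalanced or higher-way support.
- The CLI consumes pre-aligned input; multiple alignment and sequence
  retrieval are out of scope.
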