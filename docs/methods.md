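# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions a maintainer needs.

## Data model

A `PeakTable` is a features × samples matrix of integrated peak areas with
aligned metadata.  Two conventions matter throughout:

* **Missing ≠ zero.**  A missing area (empty cell, NaN) means the peak was
  not detected or not integrated; zero is a legal measured value.  Each
  statistic states its policy: presence counting treats zero as absent,
  blank-filter means treat missing as 0, pooled CVs ignore missing values,
  total-standardization renders missing as a 0 contribution.
* **Retention time is stored in seconds; feature IDs render minutes.**
  Co-elution windows are second-scale, while the `I<mz>R<rt>` naming
  convention prints minutes (4 decimals for m/z, 1 for minutes).  The
  rounding inside IDs is round-half-even — the ID convention itself does
  not pin down a rounding rule, so the platform default was adopted and is
  documented rather than guessed.

Sample roles partition the columns: `sample` (biological), `pooled`
(repeated injections of a mixture of all samples — pure instrument
variance), `blank` / `medium_blank` (matrix blanks).  Exactly one of
volume filtered (environmental) or biovolume (culture) normalizes each
biological sample.

## QC filters

Four per-feature filters, run in order (CV → replicate → presence →
blank), each recomputable from the input table:

| filter | statistic | fails when | boundary |
|---|---|---|---|
| pooled CV | sd(ddof=1)/mean over pooled injections | CV > 0.30 | strict `>`: CV = 0.30 passes |
| replicate | mean within-replicate-group CV | > CV over all samples | strict `>` |
| presence | fraction of samples with nonzero, non-missing area | < 0.50 | "at least half" is inclusive |
| blank | mean sample area vs mean blank area | mean < 3 × blank mean | ≥ 3× passes; zero blank always passes |

The replicate filter uses CV rather than variance so that it is scale-free
("more variable within replicates than across the whole set" is otherwise
dominated by abundant features).  The presence filter counts sample
columns individually, not stations; with replicates this weights stations
by replication, which matches how the table is actually assembled.
Spiked internal-standard rows are exempt from removal — they are held at
constant level by construction, so the blank comparison is meaningless
for them, and B-MIS needs them downstream; their flags are still reported.

All filters are idempotent and invariant to permuting columns within a
role.

## Dereplication

One analyte can appear as several mass features.  The search flags a
candidate pair (parent, satellite) when three conditions hold:

1. the m/z offset matches a known mass difference within a ppm tolerance
   (default 5 ppm, Orbitrap-class accuracy — the window size is a design
   default, not a measured property): ¹³C +1.003355, ¹⁵N +0.997035,
   ³⁴S +1.995796; [M+Na]⁺−[M+H]⁺ +21.981944, NH₄ +17.026549, K +37.955882
   (positive mode); [M+Cl]⁻−[M−H]⁻ +35.976678 (negative mode); and
   (m + 1.007276)/2 for the doubly charged companion of a feature at m;
2. the two features co-elute: |ΔRT| ≤ 3 s (reversed phase) or 6 s (HILIC),
   interpreted as an absolute gap bound;
3. the satellite's mean area is strictly below the parent's (isotopologue
   and adduct intensity scales with the parent).  A stricter
   natural-abundance plausibility check is deliberately not imposed:
   "smaller than parent" is the assumption the area model supports.

The offsets live in data tables (`ISOTOPE_OFFSETS`, `ADDUCT_OFFSETS`), not
in code.  When two parents explain the same satellite, the larger-area
parent wins.  Removal is transitive — a chain A←B←C keeps only A — and a
cycle in the satellite→parent graph is an error, never silently broken.
No feature is ever removed for merely *having* satellites.

## Normalization

**B-MIS** (best-matched internal standard).  For every feature, each
accepted internal standard is tried as a normalizer: candidate area =
raw area × mean(IS over pooled injections)/IS in that injection.
Candidates are scored by pooled CV only (pooled injections isolate
instrument variance); the winner is applied to all columns, but only if it
improves the pooled CV by at least 40% relative to no normalization —
otherwise the feature keeps raw areas.  The 40% cut-off follows the
published B-MIS protocol; this study's own cut-off is not stated, so the
protocol default is used and exposed as a parameter.  A standard with a
zero or missing area anywhere is excluded (its normalization would divide
by zero).  Because the no-normalization baseline always competes, the
chosen pooled CV can never exceed the baseline.

Cultures are *not* B-MIS-normalized: different growth media and analysis
batches put them in incomparable matrices.  The culture path is biovolume
normalization → log₁₀ → division by the per-feature maximum across
organisms, so only order-of-magnitude differences register.  Features
never observed in a dataset come back all-missing and flow into the
explicit `not_observed` pseudo-mode instead of being dropped — "never
seen in culture" is itself an informative category.  A feature whose
largest area is ≤ 1 has no usable dynamic range on a log₁₀ scale and is
likewise returned as missing (with a warning); the generator keeps
per-biovolume abundances well above 1, and real instrument areas are
orders of magnitude larger.

Environmental tables are standardized per feature to fractions of that
feature's total area across biological samples; rows sum to 1 and the
result is invariant to any per-feature rescaling, which is exactly why
response factors are not needed before pattern analysis.

## Mode discovery

k-medoids on Euclidean distances between standardized feature patterns
(fractions for environmental sets, log-max values with missing rendered 0
for cultures).  `KMedoids` implements exact PAM: greedy BUILD, then
steepest-descent SWAP (apply the single best improving swap until none
exists; the objective is non-increasing and ties break to the lowest
index, so the fit is deterministic).  Steepest descent can stop in a
swap-local optimum even on 8-point instances — R's reference
implementation shows identical behavior — so by default the solver reruns
SWAP from 9 additional seeded random medoid sets and keeps the best
solution (`n_init=10`; `n_init=1` is classical PAM).  `CLARA` repeats PAM
on random subsamples of size 40 + 2k (the classical default), each
augmented with the incumbent medoids, assigns all points to the nearest
medoid, and keeps the draw with the lowest total dissimilarity.

k is selected at the *smallest* local maximum of average silhouette width
over k ∈ [2, k_max] (endpoints compared one-sided); if the curve has no
local maximum the argmax is returned with a warning.  Silhouettes of
singleton clusters are 0 (scikit-learn's convention, adopted knowingly).
Modes are labeled a, b, c, … by decreasing size.

Sample-level structure uses nonmetric MDS (Kruskal stress-1, best of
several random starts; wraps scikit-learn's nonmetric MDS) and ANOSIM,
R = (mean between-group rank − mean within-group rank)/(M/2) with
M = n(n−1)/2, with a seeded permutation p-value or full enumeration of
distinct label arrangements for n ≤ 10.

## Mode-overlap enrichment and metaclusters

For partitions of the same feature universe from two datasets, the
observed statistic is the shared-member count for every mode pair.  The
null permutes one partition's label vector uniformly (mode sizes
preserved; the pairwise-overlap null is identical whichever side is
permuted) and recounts all pairs each draw;
p = (1 + #{draws ≥ observed}) / (1 + n_perm) with n_perm = 1000 by
default.  The +1 correction means p is never exactly 0, and with discrete
overlap counts the test is slightly *conservative* (achieved type-I rate
just at or below nominal α — never anticonservative, so reported edges are
not inflated).  No multiple-testing correction is applied across mode
pairs by default, matching the raw p < 0.05 edge rule; a
Benjamini–Hochberg option would be a caller-side addition on the edge
table.  Whether the `not_observed` pseudo-mode participates in the
universe is a flag (default: it does — compounds absent from cultures but
structured in the environment are a real category).

Modes with ≥ 10 members become network nodes; cross-dataset pairs with
p < α become edges.  A metacluster is a connected component containing a
culture-dataset mode (the root; components with several culture modes
yield one metacluster per root).  A compound is a member iff it belongs
to the root mode and to ≥ 2 environmental modes of the component.  The
rooted-component rule is an explicit automation of what is otherwise a
hand-drawn grouping; compound sets are automatically disjoint across
roots because each compound has exactly one culture label.

## Quantification

`Concentration = (Area / RF) · (Vol_reconst / Vol_filtered) · (1 / RF_ratio)`,
with RF the mean area-per-concentration over bracketing standard
injections (the before/after combination rule is a package choice), the
reconstitution volume defaulting to 400 µL, RF_ratio the matrix/water
response ratio measured once on a representative matrix and shared across
batches (overridable per batch), and a per-sample dilution factor applied
multiplicatively (internal standards are added at the dilution step, so
dilution enters after the volume ratio).  Compounds calibrated only in a
later batch transfer through a structurally matched standard:
RF_relative = RF_analyte/RF_matched, estimated RF in an earlier batch =
RF_relative × that batch's matched RF — an algebraic identity, so the
round trip is exact.  Carbon/nitrogen equivalents multiply by the
formula's element counts (formulas parsed with pyteomics); intracellular
concentration = moles / (biovolume × 10⁻¹⁵ L µm⁻³), reported in mM.
DMSP is flagged unreliable (unstable in methanol-based extraction) and
excluded from carbon-fraction sums by default.

## The synthetic generator

The generator plants exactly the structures the pipeline claims to
recover, at the study's scale by default (313 features; 21 species in 5
taxon groups: 52 core + 123 group-specific + 138 rare features; 36
transect samples):

* abundances are multiplicative log-normal throughout (peak areas are
  positive and heteroscedastic); the per-feature base level has median
  10³ units per µm³ biovolume so culture log₁₀ values are positive;
* environmental truth: abundance = biomass × Σ_g w(station, g) × mean
  group signature, with named gradient shapes for the weights (monotone,
  peaked, flat, depth-like, and five equally spaced latitude "bands");
  the rare block, absent from all cultures, is fed by an optional extra
  source column so the `not_observed` pathway is exercisable;
* instrument artifacts: every injection's areas are multiplied by a drift
  factor f ~ lognormal(0, drift_sigma); pooled columns are the mean of
  the sample columns *before* drift; blanks carry 10% of the per-feature
  median sample area (the matrix blank is a second in-series filter, so
  it carries real matrix signal) plus contaminant-only features at a
  constant level everywhere — detectable *only* by the blank comparison;
  internal standards share f exactly (B-MIS best case) or carry
  independent variation of the same magnitude (the no-matching-IS case);
* satellites are appended at the exact mass offsets with configurable
  per-kind rates, areas a fixed fraction (0.2) of the parent, and uniform
  m/z (ppm) and RT jitter;
* planted concentrations generate areas by the exact forward model of the
  concentration equation, so the quantification round trip is a pure
  inversion test.

**Benchmark geometry.** The mode-recovery benchmark plants five taxon
groups whose weights are Gaussian latitude bands at equally spaced
centers (x = 0.1 … 0.9, width 0.12).  Mixtures of monotone + peaked +
flat shapes were rejected at design time: those patterns nest into
super-clusters, so the silhouette curve acquires an early local maximum
(k = 3) and the geometry simply does not contain five well-separated
modes.  Banded community types are mutually near-equidistant and the
silhouette curve rises monotonically to its k = 5 maximum.  The
dereplication benchmark spaces parents 20 s apart so that only a parent
and its own satellites co-elute; with the offset table's pairwise
differences all larger than the 5 ppm window (and equal-area satellites
blocked by the strict area rule), precision does not depend on the seed.

**What passing these checks shows — and does not.**  The generator's
noise is i.i.d. multiplicative and its drift purely per-injection; real
LC-MS data add retention-time drift, saturation, ionization suppression
that varies by co-eluting matrix, peak-shape pathologies, and
compositional correlations between features.  Recovery at
noise_sigma = 0.1 demonstrates that the implementations are correct and
calibrated, not that real transect data contain five modes or that B-MIS
removes all non-biological variance in the field.  Conversely the exact
oracles (hypergeometric tail, exhaustive medoid search, full ANOSIM
enumeration, algebraic round trips) validate the statistics themselves
independently of any generative assumption.

## Problem sizes and numerics

Validation experiments run at: 10,000 permutations for the overlap toy
(vs the exact hypergeometric tail, 2 Monte Carlo SE agreement); 200 null
replicates × 1,000 permutations for type-I calibration; 25 random 8-point
instances for PAM optimality; 313 × 36 with 20 fresh seeds for mode
recovery; ~160 planted satellites per run for dereplication; the full
313-feature table for B-MIS and QC recovery; 20,000 permutations against
full enumeration for ANOSIM.  The whole set completes in well under a
minute of CPU apart from the mode-recovery sweep (~10 s) and the null
calibration (~3 s).

Ties break deterministically everywhere (lowest index in PAM, largest
parent area in dereplication, first-found in equal-CV B-MIS choices);
permutation tests take explicit seeds; CV requires ≥ 2 observations and a
positive mean, and degenerate inputs (zero volumes, empty groups, cyclic
annotations, mixed polarities) raise typed errors naming the offenders
rather than propagating NaN.
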