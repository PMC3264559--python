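# Methods

## The paired decomposition

Given a tumor matrix `D1` (M1 probes × N patients) and a patient-matched
normal matrix `D2` (M2 × N), both complete and of full column rank, the
package computes the exact simultaneous factorization

    D1 = U1 Σ1 V,   D2 = U2 Σ2 V

where `V` is the shared N × N probelet matrix (rows `v_nᵀ`, each scaled to
unit Euclidean norm), `U1`, `U2` have orthonormal columns (arraylets) and
`Σ1`, `Σ2` are non-negative diagonal weights.  The ratio `σ1_n/σ2_n` is
the n-th generalized singular value of the pair.

Numerics.  The stacked matrix `[D1; D2]` is reduced by a thin QR; the
cosine–sine structure of the stacked orthonormal factor `[Q1; Q2]` is
obtained from the SVD `Q1 = P C Wᵀ`, after which `Q2 W` has orthogonal
columns with norms `S = sqrt(I − C²)`.  The probelet rows are the rows of
`Wᵀ R`, and the weights are the cosines/sines times the row norms.  This
route is backward-stable for tall matrices (M ≫ N) and never forms a Gram
matrix.  Reconstruction `D_i = Σ_n σ_{i,n} u_{i,n} v_nᵀ` is exact to
machine precision by construction.  The equivalent N × N generalized
symmetric-definite eigenproblem `D1ᵀD1 x = λ D2ᵀD2 x` is used only as an
independent test oracle: its eigenvalues are the squared weight ratios,
and its eigenvectors are the **dual** basis of the probelets — the
probelets themselves solve the eigenproblem on the inverse Grams.  (These
coincide only when the probelets are orthogonal, e.g. in the SVD limit of
an orthonormal `D2`.)

Conventions, chosen here because the decomposition leaves them free:

* **Sign.**  Each probelet is oriented so its median entry is
  non-negative (largest-magnitude entry positive when the median is
  exactly zero); the paired arraylets flip together, leaving the
  reconstruction unchanged.  With a cohort that is mostly high-weight,
  this orients the leading probelet so the high class is positive, which
  the positive classification cutoff assumes.
* **Order.**  Components are reported in decreasing angular distance
  `θ_n = arctan(σ1_n/σ2_n) − π/4` (ties broken by decreasing `σ1`):
  tumor-exclusive first, normal-exclusive last.
* **Rank tolerance.**  A dataset whose smallest singular value falls
  below 1e-10 of its largest is rejected as rank deficient, naming the
  offending dataset.

Interpretive scalars: weight fractions `p_n = σ_n²/Σσ_k²` per dataset;
generalized normalized Shannon entropy `−(1/log N) Σ p_n log p_n` in
[0, 1] (0 = one component carries everything, 1 = flat spectrum); angular
distance in [−π/4, +π/4] with the conventions `σ2 = 0 → +π/4`,
`σ1 = 0 → −π/4`.

## Preprocessing

Order of stages (the narrative of the underlying protocol lists them
without fully fixing the order; the order below is this package's
choice): QC-select arrays (pass fraction strictly above 0.90) → per-tissue
probe filtering (valid in ≥ 99% of that tissue's arrays; tissues filtered
independently, so probe sets differ) → per-profile autosomal-median
centering (X included in the shift, excluded from the median) → per-tissue
SVD imputation → per-patient replicate medians → patient-matched assembly
on the sorted intersection of patient ids.  Imputation precedes the
replicate medians; centering precedes imputation so the zero
initialization of missing cells is unbiased.

Imputation iterates a truncated rank-k SVD reconstruction over the
missing cells (observed cells never change), initialized at zero, until
the relative change of the imputed values drops below `tol` (default
1e-6, default rank 5, cap 100 iterations).  Non-convergence returns the
current completion with a warning flag rather than failing: with ~0.2%
missing data the fixed point is reached in a handful of iterations, and a
conservative cap should not abort a whole pipeline run.  The contraction
slows when a large fraction of a single column is missing (a regime the
tests cover explicitly but real arrays do not reach).

## Enrichment

For a probelet, the `K` patients with the largest (or smallest) entries
are tested for over-representation in each categorical annotation label
with the exact hypergeometric upper tail, computed by integer summation
(`math.comb` + `Fraction`) so the returned double is the correctly
rounded exact value.  `K` defaults per label to that label's population
count — the one choice that lets a perfectly aligned annotation reach
complete overlap — and is overridable per call.  P-values are reported
unadjusted; a Bonferroni column rides along for the reader and never
gates anything.  Rank-sum (Mann-Whitney-Wilcoxon) comparisons use exact
enumeration of all group assignments up to a combined n of 12 (valid
under ties) and the tie-corrected normal approximation above that.

## Segmentation

A deliberately simple, self-contained stand-in for circular binary
segmentation: within each chromosome, the split maximizing the pooled
two-sample |t| is accepted when its permutation p-value (shuffling the
chromosome's values, re-maximizing; default 1000 permutations, at least
100 enforced) falls below `alpha` = 0.01, and the halves are recursed
with at least `min_width` = 3 probes per side.  A noiseless step yields
an infinite statistic and is split exactly; the permutation calibration
makes the false-split rate on pure noise ≈ alpha.  Each segment reports
the p-value of the split that delimited it.  The splitter sits behind a
single function so a full circular implementation can be substituted.
Segments are exported in BED convention (0-based, half-open) from the
1-based inclusive internal coordinates.

## Copy-number calls

All rules share one per-profile spread estimate: the RMS deviation of the
autosomal chromosome-unit means about the autosomal genomic mean, after
excluding the configured outlying units (default chromosome 7, arm 9p,
chromosome 10); a chromosome with an excluded arm is evaluated arm by
arm.  "SD of the mean chromosome number" is interpreted as this
across-unit spread, not a probe-level SD.  Calls (strict inequalities):
female gender when the normal profile's X mean exceeds the genomic mean
by more than twice the unexcluded SD (per-patient, as the rule is
phrased); chromosome-unit gain/loss beyond twice the robust SD; segment
gain/loss beyond twice the robust SD from the genomic mean, or beyond one
SD from the chromosome mean when that deviation shares the sign of the
genomic-mean deviation.

## Survival classification

Probelet scores split three ways around a cutoff `c` (default 0.02):
`> c` high, `|score| ≤ c` low, `< −c` unclassified — boundaries fall to
"low", and the comparators are configurable because the printed rules
leave the boundary direction ambiguous.  Cutoffs carry across cohorts by
the Euclidean-norm ratio of the scores over shared patients (0.02 →
0.017 at a norm ratio of 0.85), and across score types to the
correlation scale (default 0.15 for profile–arraylet Pearson
correlation, requiring observed values on ≥ 97.5% of the reference
arraylet's probes).  Pearson is used rather than cosine similarity: on
centered profiles the two are near-identical, and Pearson is the field's
default reading of "correlation".  Ages dichotomize at 50 years (> 50
older).  Kaplan-Meier, log-rank and Cox proportional-hazards machinery is
delegated to lifelines; Cox fits use Efron tie handling (the common
default), and the tests cross-check the coefficient against an
independent hand-written Efron partial-likelihood search.

## Synthetic cohorts

The generator emulates exactly the structure the decomposition is meant
to separate, at the reference study's stated scales where it states them:

* toy genome of six autosomes (400 probes each, arms split 40/60) plus X,
  labelled 1, 7, 9, 10, 17, 19 so the calling rules apply verbatim;
  tumor and normal probe grids are disjoint (probe-independent);
* tumor-exclusive global pattern: chr7 +0.45, chr10 −0.45, 9p −0.30,
  three focal gains (on 1p, 17q, 19q); per-patient weight bimodal —
  ~90% of patients near 1 (SD 0.10), ~10% near 0 (SD 0.02);
* gender-common X amplification (+0.4) in both tissues for a ~50% female
  cohort;
* normal-exclusive artifacts: three batches, each a fixed random probe
  offset vector of SD 0.15, chromosome-invariant by construction;
* i.i.d. Gaussian probe noise (SD 0.10), ~1.45 arrays per patient, 2% of
  arrays planted as QC failures, 0.2% missing entries;
* survival: exponential with a 13-month median in the high class, hazard
  ratio 2.3 between classes, independent exponential censoring tuned to
  ~30%.

Alteration levels and the noise SD are not stated by the reference
analysis and were fixed once at magnitudes typical of centered log2 aCGH
data.  What the simulator does **not** model: GC/wave artifacts,
probe-level correlation along the genome, allele-specific copy number,
non-proportional hazards.  Recovery of the planted structure therefore
demonstrates the pipeline's correctness under its own model assumptions,
not its robustness to every artifact of real arrays.

## Problem sizes and tolerances

Tests and the acceptance script run the simulator at its default 200
patients (20 seeds for seed-averaged recovery), random decomposition
oracles at 12×6 / 11×6 over 20 seeds, segmentation calibration on
120-probe chromosomes over 100 seeds, and exhaustive enrichment
enumeration up to a population of 12 — sizes at which every oracle is
exact or cheap while the statistical properties (recovery correlation
> 0.99, classification accuracy ~1.0, false-split rate ≈ alpha, Cox
log-HR within sampling error of the planted value) are stable.
Reconstruction and orthonormality are asserted at 1e-10, the
eigenvalue oracle at 1e-8, imputation at 1e-6 relative RMSE, exact
statistics at 1e-12.  At noise SD half the step height the change-point
location estimate itself carries an O(1)-probe error, so noisy
breakpoint "recovery" is scored within a 3-probe window.

## Known limitations

* The segmentation is binary, not circular, and does not reproduce the
  published CBS pruning or hybrid p-values; segment boundaries on real
  data may differ near closely spaced change points.
* The decomposition requires complete, full-column-rank matrices; cohorts
  with duplicate or constant patient columns must be cleaned upstream.
* Normal-arraylet orthonormality degrades (error ~ machine-eps/σ2) for
  components that are almost perfectly tumor-exclusive; with any noise
  floor in the normal dataset this is far below the 1e-8 contract.
* Correlation classification assumes the reference arraylet and the new
  profiles share a probe universe; it does not re-map probes between
  array designs.
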