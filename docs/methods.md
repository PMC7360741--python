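# Methods

`tmadissect` analyzes hyperplexed immunofluorescence tissue-microarray (TMA)
data at single-cell resolution: per-patient tables of segmented cells with
coordinates, QC metadata, an E-cadherin-based epithelial/stromal call, and
log2-scale intensities for a panel of biomarkers (55 by default).  The
package (i) virtually dissects each spot into epithelial, stromal, and
epithelial–stromal boundary domains, (ii) summarizes each domain as a fixed
feature vector of thresholded mean intensities and pairwise Kendall rank
correlations, (iii) fits a recurrence-guided, stability-selected penalized
Cox model per domain and combines the domains multiplicatively into a 5-year
recurrence-risk score, and (iv) infers recurrence-specific differential
biomarker networks from per-patient partial correlations.

## Preprocessing and QC

Cells are retained if their segmented area is **strictly greater than 10
pixels** (at x20) and their per-round DAPI-overlap quality index is **at
least 0.9** (inclusive); when several per-round quality columns are present
they are collapsed to the per-cell minimum, since a cell failing any imaging
round is unreliable throughout.  Raw intensities are transformed once as
`log2(x + 1)` (a flag guards against double transformation).  Slide-to-slide
variability is removed by a per-biomarker median normalization: each slide's
intensities are shifted additively (on log2 scale) so that every slide's
median equals the pooled grand median.  The shift is rank-preserving, so all
Kendall correlations downstream are invariant to it; whether the original
protocol normalized globally or per biomarker is not documented, and the
per-biomarker variant was chosen as the safer default.  Exposure-time
harmonization is assumed done upstream.

## Spatial dissection

Compartments come directly from E-cadherin labeling: positive cells are
epithelial, the rest stromal.  The boundary domain uses a three-step circle
tessellation: circle centers are laid on a square lattice (spacing =
diameter/10, i.e. 5 µm at the default 50 µm diameter) over each spot's
bounding box; a circle is retained iff it contains at least one positive and
one negative cell (centroid within the radius, inclusive); the boundary
domain is the union of retained discs.  For a dense straight interface this
union converges to a band two diameters (100 µm) wide as the lattice spacing
shrinks; at 5 µm spacing and a 2 µm cell grid the measured extent is 95 µm —
one spacing step of discretization on each relevant edge.  The epithelial
and stromal domains keep their band cells: the boundary domain overlaps both
compartments rather than partitioning them.  Cell extent is ignored (only
centroids are available); coordinates are continuous µm.

## Feature engine

For a panel of P markers each domain yields `P + P(P-1)/2` features (1540
when P = 55): per-marker mean intensities followed by tie-corrected Kendall
tau-b for every unordered pair.  "Expression" is defined conservatively: per
biomarker and per spot, a nearest-rank 85th-percentile threshold is computed
from the whole spot's cell-intensity distribution (the smallest value with
at least 85% of values at or below it), and only intensities *strictly
above* it count.  Means average the expressing cells of the domain;
correlations use the domain cells expressing *both* markers of the pair, and
are missing when fewer than three such cells exist or either vector is
constant.  Anchoring the threshold to the spot rather than to the domain
keeps the expression calls consistent across a spot's three domains.  Mean
features likewise use only above-threshold cells; computing them over all
cells is a one-line switch (`percentile=0`).

For modeling, feature columns missing in more than 20% of patients are
dropped and the remainder median-imputed; penalized regression needs
complete columns, and imputation at the cohort median is neutral for
standardized coefficients.

## Prognostic model

The partial likelihood is the plain Breslow form
`L(β) = Π_k exp(f_{i_k}'β) / Σ_{i∈R_k} exp(f_i'β)`, with `R_k` the risk set
at event time `t_k`.  Model construction per domain is a two-step procedure:

1. **Selection.** L1-penalized (LASSO) Cox regression on column-standardized
   features.  The penalty weight λ* minimizes 10-fold cross-validated
   partial-likelihood deviance along the path.  Selection is then repeated
   on stratified bootstrap resamples (500 by default), each refitting the
   path down to λ*; a feature survives only if selected in ≥ 90% of
   resamples.  λ* is tuned once on the full data rather than within every
   resample: the per-resample frequencies are statistically
   indistinguishable between the two variants while the fixed-λ* form costs
   an order of magnitude less.
2. **Sign stability and refit.** Surviving features are refit per bootstrap
   under an L2 (ridge) penalty at a CV-chosen weight; a feature is kept only
   if its coefficient sign matches the full-data ridge refit in ≥ 90% of
   resamples.  Final coefficients come from a ridge refit on the full data
   restricted to the final features, so they are conditioned only on the
   selected set, not on the original 1540-dimensional search space.

Bootstrap resamples are stratified by recurrence year within the 5-year
horizon (plus a no-recurrence stratum), preserving the per-year event
counts — a form of risk-set sampling that keeps the screens stable under
outcome imbalance; single-patient year strata are merged with the following
year.  Resamples whose fit fails are excluded from the frequency
denominator.  Ties use the Breslow approximation throughout; Efron
correction and intermediate elastic-net mixing are deliberately out of
scope.  The two stability screens draw independent seeded resample streams.

The three domain models combine multiplicatively: the overall score is
`exp(Σ_s f_s'β_s)` over S = {epithelial, stromal, epi-stromal}; a domain
with an empty final feature set contributes a constant factor of 1.
Comparison models share the identical learning procedure: the *null* model
runs the same pipeline on the undissected spot's 1540 features, the
*intensity* model on the undissected mean intensities alone, and the
*clinical* model is an unpenalized Cox fit on age, gender, and one-hot TNM
stage; "+clinical" variants combine score columns through a small Cox fit on
the training scores.

A Schoenfeld-style residual-trend utility is provided for
proportional-hazards diagnostics; it reports per-feature correlations of
residuals with event time and is not used as a gate.

## Evaluation

Train/test pairs are disjoint ~50/50 splits stratified by recurrence year,
so each side preserves the cohort's per-year recurrence proportions to
within one patient (out-of-bag resampling is the obvious alternative; the
50/50 split was chosen for strictly independent test sets and is switchable
in code).  The binary 5-year outcome is positive for an event within the
horizon and negative for event-free follow-up past it; patients censored
event-free before the horizon are masked out of binary ROC analysis but
retained for Cox fitting, Kaplan–Meier curves, and time-dependent AUC, so no
information is discarded overall.  ROC/AUC is empirical (AUC equals the
Mann–Whitney concordance); the operating point maximizes Youden's
J = sens + spec − 1 with ties resolved toward higher specificity; likelihood
ratios are LR+ = sens/(1−spec) and LR− = (1−sens)/spec with infinity
sentinels at the boundaries.  Time-dependent AUC(t) is the cumulative-case /
dynamic-control estimator with inverse-probability-of-censoring weights from
the Kaplan–Meier censoring distribution, evaluated yearly at t = 1..5 and
masked where no cases or no controls exist.  The six-model comparison
harness refits every model per split and emits the per-split AUC table;
post-hoc significance testing on those distributions is left to external
tools.

## Partial-correlation networks

Per patient and domain, a correlation matrix **C** over the N biomarkers
named by the domain's final features is filled with the already-computed
Kendall taus (missing pairs set to 0) and nudged to positive definiteness by
the smallest shrinkage `(1−δ)C + δI` on a δ-grid of step 0.01 reaching a
minimum-eigenvalue floor of 1e−6.  The Kendall-based matrix is inverted
directly — no sine transform to a Pearson equivalent — and partial
correlations follow from the precision matrix as
`ρ_ij = −P_ij/√(P_ii P_jj)`.  For each pair, per-patient partials are split
by outcome, histogrammed on [−1, 1] (40 equal-width bins by default, with a
1e−12 pseudocount), and compared by the Jensen–Shannon divergence in bits
(symmetric, bounded by 1).  The resulting information-distance matrix,
thresholded at its nearest-rank 99th percentile (strictly greater), defines
the domain's differential network; biomarkers without surviving edges remain
as isolated nodes, since a selected expression feature carries no pairwise
relationship.  Bin count matters at small cohort sizes: with ~30 patients
per group, 40-bin histograms have a substantial finite-sample JSD floor
(~0.5 bits between identical distributions), which the 99th-percentile
threshold tolerates only when true separations are large; coarser binning
lowers the floor and is exposed as `network_bins`.

## Synthetic cohorts

The generator emulates the assumed data structure so every stage is testable
without patient data: one 0.6 mm spot per patient with a central epithelial
blob (radius 180 µm) and surrounding stroma; log2-scale intensities composed
of per-marker baselines (uniform 4–9, matching the displayed dynamic range),
patient random intercepts (sd 0.4), compartment-specific latent factors
(3 factors, loading sd 0.25) that induce the background tau structure,
planted patient-varying signals, per-slide offsets (sd 0.3), and unit cell
noise; cell size and quality drawn so roughly 5% of cells fail QC.  Planted
mean features shift a marker in one domain's cells by a patient-level
normal deviate; planted correlation features add a shared per-cell factor to
a marker pair within one domain with patient-varying loading.  Outcomes
follow a proportional-hazards mechanism: each patient's true planted feature
values (computed with the same thresholding rules, on the clean pre-noise
intensities and geometric domain definitions) are standardized across the
cohort and dotted with β*; event times are exponential with rate
`h0·exp(η)`; censoring is uniform on (0, 1.5 × horizon); `h0` is calibrated
by closed-form bisection so the expected observed 5-year recurrence fraction
hits the target — 0.15 by default, the cohort composition the tool is
designed around (65 recurrences in 432 patients).  Times are quantized to
days.  An `exact_events` mode bisects `h0` against the realized event count
(monotone given fixed draws) so the 432-patient preset reproduces exactly 65
in-horizon recurrences.  A feature-level generator (iid standard-normal
features, planted coefficients of alternating sign) supports model-level
recovery studies at the full 1540-feature dimension without paying for
cell-level simulation.

What the generator does *not* emulate: realistic cell morphology and
density gradients, spatially autocorrelated intensity fields, immune-cell
subpopulations, marker-specific dynamic ranges and detection floors, and
informative censoring.  Passing tests therefore demonstrate correctness of
the algorithms and recoverability of planted structure under the stated
noise model — not clinical performance on real cohorts.

## Problem sizes and statistical power

Tests and the acceptance checks run at desk scale by design: cohorts of
40–432 patients, panels of 4–55 markers, 150–500 cells per compartment,
10–100 stability bootstraps, and 2–50 evaluation splits, with every
stochastic step seeded.  One power property is worth stating explicitly:
with ~60 observed events (the 0.15 recurrence fraction at n = 400), the 90%
stability screen retains only a subset of planted effects of hazard ratio 2
per SD — per-bootstrap selection frequencies for such effects span roughly
0.4–1.0 — while keeping false positives at or near zero among ~1530 noise
features.  The screen trades recall for precision exactly as stability
selection is designed to; recovering weaker effects requires more events or
a lower stability threshold.

## Numerical choices

Nearest-rank percentiles everywhere a threshold is taken (expression
threshold, network threshold), with "above" strict.  Features are
standardized (mean 0, sd 1; constant columns left unscaled) before
penalization, and coefficients are reported on the standardized scale with
the transform stored.  The log partial likelihood subtracts the maximum
linear predictor before exponentiation.  Histograms clip values to [−1, 1]
before binning.  Kendall tau is tau-b (tie-corrected), missing below n = 3
or for constant input rather than raised.  All randomness flows from
`numpy.random.default_rng` seeded by the run configuration; child seeds are
drawn below 2^31.
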