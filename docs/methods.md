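# Methods

`metabfuse` implements a two-platform plasma metabolomics workflow: unbinned
¹H-NMR spectral fingerprinting and LC-MS metabolite intensities are
preprocessed separately, fused as z-scored blocks, and modelled with OPLS
regression against the study factors; model validity is assessed by response
permutation, important variables (VIP > 1) feed a pathway
over-representation and topology analysis, and a univariate screen links
selected variables to clinical covariates. Because the workflow is meant to
be testable without any cohort data, a synthetic paired-platform generator
with known ground truth is a first-class part of the package.

## Synthetic data model

**Spectra.** Each metabolite is a mixture of 1–4 Lorentzian lines
`h / (1 + ((δ − δ₀)/w)²)` with centres in 0.2–10 ppm (kept out of the
reference window 6.45–6.58 ppm), apex heights 0.3–1.0 and half-widths
0.001–0.006 ppm — solution-state ¹H linewidths at high field. A sample's
spectrum is the concentration-weighted sum of its metabolite signatures on a
0–12 ppm grid at 0.0005 ppm (24 001 points), plus:

* a fumarate-analogue reference singlet at 6.5 ppm (equal amount per tube),
* nuisance residual-water (~4.9 ppm, broad) and methanol (3.335 ppm)
  signals that lie inside the exclusion windows by construction,
* a per-sample global shift drawn from U(−jitter, +jitter), default
  0.005 ppm, modelling field drift (per-peak jitter is out of scope:
  alignment downstream is global, via the reference singlet),
* additive white Gaussian baseline noise, default SD 0.01 in units of a
  unit-concentration, unit-height peak apex. That is an apex
  signal-to-noise around 100, typical of plasma CPMG spectra; at much
  higher SNR the 2×-noise retention rule stops doing any work and
  Lorentzian skirt points flood the variable list.

**Concentrations.** log-concentration = metabolite baseline (U(−0.5, 0.5))
+ factor level × log-fold effect + N(0, σ), with σ = 0.3 by default and
planted effects of 1.0 log-unit. Unaffected metabolites therefore have
equal arm means in expectation, and all concentrations are positive.

**Designs.** The mouse-style design is 2 diets × 2 times-on-diet with
n = 8/arm by default (the source study does not print its group sizes; 8 is
a config default, not a claim); the human-style design is a 23-vs-23
binary case–control cohort. Factor codings are 0/1 per arm.

**MS run.** Intensities are concentration × drift(injection order) ×
lognormal technical noise (default CV 10%; multiplicative because MS
intensities are positive and CVs are scale-free). Drift shapes are linear
or exponential, parameterized by the sensitivity at the end of the run
relative to the start. The run opens with a pooled-QC injection and adds
one after every five analytical samples; the QC composition is the mean of
all study-sample concentrations (pooled-plasma analogue). Study samples
are injected in seeded randomized order — standard practice, and necessary:
with arm-ordered injection the residual drift left after correction is
confounded with the group factor, which visibly distorts the permutation
null. A worst-case ordered run is available with `randomize_order=False`.

**What the generator does not emulate.** J-coupling multiplets and
phase/baseline artefacts (spectra are generated phased), correlated
(apodized) noise, chromatographic peak shapes, adducts and in-source
fragments, non-MCAR missingness, batch-to-batch structure beyond a single
run. Tests passing on this generator therefore certify the pipeline's
*algorithmic* behaviour — alignment, filtering, fusion, model selection,
calibration — not its robustness to every artefact of real spectra.

## NMR processing

Fixed stage order: common grid → alignment → exclusion → total-area
normalization → peak detection → noise thresholding.

* **Alignment** shifts each spectrum by an integer number of grid points so
  the tallest point in the 6.3–6.7 ppm search window lands on the grid
  point nearest 6.5 ppm; vacated edge points are zero-filled; ties break
  toward the smaller shift. Sub-point alignment is pointless at a
  0.0005 ppm grid where the default jitter spans 10 points.
* **Exclusion windows** are closed intervals, removed before any
  summation, so no variable can ever sit inside one: residual water
  (mouse 4.65–5.16, human 4.55–5.16 ppm), methanol 3.32–3.35 ppm, the
  reference singlet 6.45–6.58 ppm, and citrate 2.47–2.68 ppm in human
  plasma only.
* **Normalization** divides by the sum of retained intensities (the
  retained total area), making spectra comparable across dilution.
* **Peak detection** takes strict local maxima of the pointwise sum of all
  normalized spectra — unbinned fingerprinting; plateaus yield no peak;
  endpoints never do. No prominence filter is applied by default.
* **Noise** is the ddof = 1 standard deviation of the signal-free
  0–0.2 ppm region, estimated per sample. The retention rule discards a
  peak variable iff strictly more than 50% of samples lie below 2× their
  own noise level. Per-sample (rather than pooled) noise is the stricter,
  self-calibrating reading of an ambiguous convention; both the factor and
  the fraction are config keys.

Phasing and baseline correction are out of scope; real-data users must
supply phased spectra (CSV `ppm,intensity`, optionally JCAMP-DX via their
own reader).

## MS drift correction (QC-RLSC)

Per metabolite, a degree-1 LOESS (span 0.75, both configurable; a
hand-written degree-0 kernel mean exists for completeness) is fitted to QC
intensity versus injection order, evaluated at QC orders, linearly
interpolated to every injection and linearly extrapolated at the run edges
using the edge QC slopes (flat extrapolation under-corrects the tail of a
drifting run). The curve is normalized by the median of its QC fitted
values and divided out of every injection, so a drift-free run is left
untouched and corrected intensities keep the original scale. Metabolites
with fewer than 3 QC points or a non-positive fitted curve are flagged and
passed through uncorrected. QC CV (100·SD/mean over QC injections) is
reported before and after correction. Missing intensities survive
correction untouched and are floor-imputed (half the per-metabolite
minimum) only when a feature table is assembled.

## Fusion and OPLS

Blocks are z-scored independently (per-variable mean 0, SD 1, ddof = 1;
zero-variance variables dropped with a warning) and concatenated
column-wise over the shared sample set. Scaling is done once on the full
table before cross-validation — the convention of the commercial
chemometrics workflow this mirrors; a leakage-safe per-fold variant would
re-scale inside each training fold and is deliberately not the default so
that reported Q² matches that convention.

**OPLS.** For responses Y (one column per factor), Y-orthogonal components
are extracted iteratively: with V an orthonormal basis of span(XᵀY), the
candidate loading p of the leading PLS component is stripped to
w_o ∝ p − V(Vᵀp); then t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o) and X is deflated
by t_o p_oᵀ. After the requested number of orthogonal components, an
ordinary NIPALS PLS with one component per response column is fitted to the
filtered X. The NIPALS inner loop is solved at its exact fixed point — the
first left singular vector of XᵀY — because the power iteration converges
arbitrarily slowly when the two leading singular values nearly tie, which
permuted responses routinely produce. R²Y = 1 − SS_res/SS_tot on training
data; predictions for new samples first remove the stored orthogonal
components, then apply the PLS regression coefficients.

**Cross-validation.** Venetian-blind folds (sample index mod K, K = 7 by
default) on the fixed sample order, deterministic; if a training fold would
hold a constant response column the assignment is re-stratified by response
rank. Q² = 1 − PRESS/SS_tot. The orthogonal-component count is grown while
each additional component improves Q² by more than 0.01.

**VIP.** Over predictive components only (the selection-relevant part):
VIP_j² = p·Σ_a SSY_a w_{ja}²/Σ_a SSY_a with unit-norm weight vectors, so
mean(VIP²) = 1 exactly — asserted as an invariant. The VIP > 1 convention
selects variables for downstream analysis.

**Permutation validation.** For each response column separately, the
column is permuted (others fixed), the model refitted with the same
orthogonal-component count and folds, and the *permuted column's* R² and
Q² recorded against |corr| with the original column; intercepts come from
an ordinary least-squares line through the permuted points plus the
unpermuted point at |corr| = 1. Scoring the permuted column (not the joint
Y) is essential for multi-response models: the intact column otherwise
keeps the joint Q² high for every permutation and the intercept says
nothing. A valid model shows negative Q² intercepts and an unpermuted Q²
above every permuted one. Degenerate permutations are kept as drawn.

## The fusion-benefit experiment

The package's headline property — fusing complementary blocks predicts the
group factor better than either platform alone — is evaluated on a
dedicated experiment (`experiments.fusion_experiment`): 2 arms × 12
samples, 30 metabolites, 6 responders at 1.0 log-unit over σ = 0.3, split
3 NMR-only / 3 MS-only. Panels are complementary by design: unaffected
metabolites alternate between platforms, with two measured by both.
Duplicating every metabolite across both platforms instead measures
redundancy, and the identical noise-column pairs' spurious correlations add
coherently in the fused weight vector, eroding the benefit. The NMR block
enters at the metabolite level (what a perfect spectral pipeline recovers);
the MS block passes through the simulated injection run and QC-LOESS
correction. All three models are compared at equal complexity (the plain
predictive component, no orthogonal components): this generator plants no
structured Y-orthogonal variation, so per-block automatic selection only
adds selection noise to the comparison. With 50 seeds the fused model wins
in ≈92–98% of replicates. Note that fusing the full unbinned spectral
table (10³ variables) with a 27-variable MS panel lets the wider block
dominate the concatenated model — a real limitation of unweighted
concatenation that block-scaling variants address; the end-to-end pipeline
reports all three Q² values so the effect is visible rather than hidden.

## Pathway analysis

VIP > 1 variables are mapped to metabolites: variables annotated to more
than one candidate metabolite are dropped (an overlapped signal cannot be
attributed), and among unique-candidate variables sharing a metabolite the
highest-VIP one represents it. Enrichment is the right-tail hypergeometric
probability with the pathway library's metabolite roster as the universe
(a `universe="measured"` override restricts to the measured panel).
Impact is the share of a pathway's betweenness-centrality mass carried by
hit nodes, on the undirected pathway graph; graphs with zero total
centrality fall back to uniform node mass, so an isolated single-node
pathway scores 1 when hit. FDR is Benjamini–Hochberg. The shipped pathway
library is a synthetic toy (five chain-graph pathways over M01–M30) in the
package's JSON format; real KEGG/SMPDB content is not distributed. A
quantitative enrichment mode (per-pathway mean |z| with a label-permutation
null) was considered and not implemented: the hypergeometric ORA is the
primary, unambiguous reading, and two half-calibrated tests are worse than
one tested one.

## Univariate screen and correlations

Two-sample t-tests are equal-variance by default (Welch behind a flag);
the diet screen takes the union of variables with p < α (default 0.05) at
either time point. Mann–Whitney uses exact enumeration when the pooled
sample is ≤ 12 and tie-free, otherwise the tie-corrected normal
approximation. The clinical screen computes pairwise-complete Pearson
correlations (≥ 3 pairs; constant vectors flagged NaN) with two-sided
p-values from the t transform on n − 2 degrees of freedom, and performs
*no* multiplicity correction by design — it is an exploratory screen and
every report of it says so. The 2×2 χ² is Pearson's without Yates
correction (flag available).

## Numerical and reproducibility choices

* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from the run seed via `numpy.random.SeedSequence`, so a
  rerun is byte-identical.
* Deterministic sign convention for PLS weights (largest-magnitude element
  positive); alignment ties break toward the smaller shift with a warning.
* Degenerate inputs fail loudly: empty universes, rank-deficient Y,
  all-constant tables, zero spectral area, too-few QC points (flagged, not
  fatal, per the correction contract).
* Experiment sizes used by the test and acceptance suites — 50 fusion
  replicates, 100 permutations, 20 null seeds, 20 drifting runs of 40
  injections — are the package's chosen desk-scale study conditions; they
  complete in well under a minute each on one core.

## Known limitations

* The OPLS implementation follows the published NIPALS formulation;
  numerical agreement with proprietary implementations (different
  deflation or scaling details) is not a goal.
* Unweighted concatenation lets a much wider block dominate fusion (see
  above); no block-scaling mode is currently exposed.
* The NMR variable list from unbinned peak picking is resolution- and
  noise-dependent; on very clean spectra the 2×-noise rule retains many
  peak-skirt points.
* Pathway impact uses undirected toy graphs; directed reaction topology
  and compound-identifier translation are out of scope.
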