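# Methods

`synfac` implements an information-resolved analysis of case-control
resting-state BOLD cohorts: pairwise regional dynamics are decomposed
into synergistic and redundant components, patient-specific synergy
*reductions* are factorized into latent dysfunction patterns with a
topic model, and the factors are related to clinical scores, regional
gene expression, and microcircuit parameters inferred from a dynamic
mean-field model.  Every stage is exercised against a fully synthetic
cohort with planted ground truth, so the statistical machinery can be
validated without any imaging data.

## Integrated information decomposition (Gaussian, MMI)

For each unordered pair of regions the joint past
`(X1_t, X2_t)` and joint future `(X1_{t+tau}, X2_{t+tau})` are treated
as a four-dimensional Gaussian vector (fMRI band-passed signals are well
approximated by Gaussian linear processes at this resolution).  The
time-delayed mutual information (TDMI) between past and future is split
into sixteen atoms indexed by a pair of partial-information nodes —
Redundancy, Unique(1), Unique(2), Synergy — one node for how information
is carried in the past, one for the future.  Redundancy between source
collections uses the minimum-mutual-information (MMI) functional, under
which the double redundancy of a node pair is the minimum of the
single-source lagged MIs.  All sixteen cumulative (down-set) values are
closed-form Gaussian MIs or minima thereof, and the atoms follow from
one fixed 16 x 16 linear solve; an explicit Moebius-inversion oracle is
kept in the test suite as an independent derivation of the same
quantities.

Choices and caveats:

* **Lag.** `tau` = 1 sample (one TR).  For TR ~ 2 s this is the
  standard single-step time scale; it is configurable.
* **Units.** Nats (natural logarithm) throughout.
* **Z-scoring.** Each regional series is standardized before covariance
  estimation.  Gaussian MI is scale-invariant, so this only stabilizes
  the numerics.
* **Negative atoms.** Marginal MIs are clamped at zero, but atoms are
  reported as solved; MMI legitimately yields negative mixed atoms.
* **MMI idiosyncrasy.** For two *independent* autocorrelated channels,
  MMI assigns `Red->Red = 0` but `Syn->Syn = 2*min(auto-MI)` (both
  single channels predict the joint future equally well, which MMI
  counts as past-redundant information that appears jointly in the
  future, compensated by negative `Un->Syn`/`Syn->Un` atoms).  The
  analytic solution for this case is derived by hand in the test suite
  and the implementation reproduces it exactly.  Consequently the
  persistent synergy of a pair in a linear network is dominated by the
  regions' temporal predictability (min auto-MI), a fact that shapes the
  design of the synthetic generator (below).
* **Carried-forward atoms.** Only the persistent synergy (`Syn->Syn`)
  and persistent redundancy (`Red->Red`) matrices feed the rest of the
  pipeline; functional connectivity is the plain Pearson matrix.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture.  Controls share one stable VAR(1) law `x_{t+1} = A x_t + eps`;
patients attenuate couplings along K planted factors with
Dirichlet-distributed mixing.

* **Parcellation.** `n_cortical` regions split contiguously into the
  seven canonical resting-state networks plus `n_subcortical` SUB
  regions (default 100 + 15); coordinates live on two hemispheric
  spheres in arbitrary mm.
* **Coupling geometry.** Self-memory 0.25; each factor owns a
  contiguous region block wired as a signed cycle with |coupling| 0.35;
  a sparse (4%) weak background; off-diagonal couplings are uniformly
  shrunk (3% steps) until the spectral radius is below 0.95 (and below
  0.97 after any patient-specific attenuation).  The cycle geometry
  keeps every region's local structure identical, so the response to
  attenuation is homogeneous within a block — chosen once, at design
  time, so that the planted dysfunction is identifiable at the default
  cohort size.
* **Patient mechanism.** For patient loadings `l` (Dirichlet,
  concentration 0.35 — a cohort with both near-pure and mixed
  presentations), every within-block pair (i, j) of factor k has its
  couplings multiplied by `1 - effect * l_k` (default effect 0.6; the
  magnitude of the dysfunction is not empirically constrained, the
  default gives comfortable recovery at n = 60/60 and T = 240).
* **Planted truth.** Because MMI synergy responds to attenuation at the
  *region* level (losing coupled drive lowers a region's auto-MI and
  hence the synergy of every pair containing it), the dysfunction
  profile of a pure-factor patient is a smooth nonlinear transform of
  the attenuation weights, not the weights themselves.  `PlantedTruth`
  therefore stores both: the mechanism (`attenuation_weights`) and the
  recovery target (`factor_patterns`) — the analytically expected
  document-space reduction profile of a pure-factor patient, computed
  from the VAR law via the discrete Lyapunov equation, expressed in
  units of a nominal estimator noise sd `1.4 / sqrt(T)` (calibrated
  once against the generator's own law) and passed through the
  expectation of the document rule `w = max(0, -z)` with the uniform
  noise floor subtracted.
* **Clinical scores.** PANSS subscales are linear in the loadings
  (factor 1 -> positive, factor 3 -> negative and general, factor 2
  uncoupled) plus Gaussian noise sized for a true correlation near 0.3,
  affinely mapped into [7, 49]/[7, 49]/[16, 112]; item scores are
  subscale/n_items plus noise clipped to [1, 7].  Only the correlation
  structure matters downstream.
* **Sites.** Balanced round-robin within each group; sites differ only
  by a small additive measurement-noise level (0, 0.15, 0.3 sd), i.e.
  a scanner effect that attenuates correlations slightly.  Demographics
  are independent of the loadings.
* **Gene expression.** Planted genes equal a z-scored factor map plus
  noise, half negated so both tails of the gene-factor ranking are
  populated; the rest are spatially smooth noise fields.
* **Structural maps.** Distance-decaying lognormal connectome
  thresholded to a density (unit maximum), plus smooth z-scored myelin
  and gradient proxies.

What the generator does **not** emulate: hemodynamic filtering in the
cohort series (the dynamics stage has its own forward model),
missing data, motion artefacts, age/diagnosis interactions, or any
spatial correlation between the factor blocks and the network labels.
Passing recovery tests therefore demonstrates the statistical machinery
under the stated generative assumptions, not performance on real fMRI.

## Group statistics

Confounds (age, gender, motion, site; dummy-coded) are regressed out of
each pair's values across subjects, then a pooled-variance two-sample t
(contrast NC - SCZ) is computed per pair.  Degrees of freedom are not
reduced for the residualization step; with cohort sizes in the tens and
a handful of covariates the calibration error is negligible (verified
by the null-calibration test) but it is a documented simplification.
Regional profiles are diagonal-excluded row means of the t matrix;
network summaries are grouped means/dispersions (block means for
matrices); multiple testing uses Benjamini-Hochberg.  Dispersion
differences between groups are compared with a two-sample t-test on
squared deviations from each group's own mean rather than an F-test.

## Spatial-autocorrelation (SA) permutation test

Surrogates for map-to-map correlation tests preserve spatial
autocorrelation by variogram matching: permute the map, smooth with
k-nearest-neighbour exponential-decay kernels (k in
{0.1, 0.2, 0.3, 0.4, 0.55, 0.7} of N — the upper entries matter for
very smooth maps, whose best kernel otherwise saturates the grid cap
and leaves the test liberal), pick the kernel whose binned
semivariogram best regresses onto the original's (least squares over 40
equal-count bins), and rank-remap the smoothed map to the original
value multiset.  The residual size of the test on independent smooth
map pairs is about 6-7% at a nominal 5% — slightly liberal, a known
property of this family of approximate spatial nulls, and far below the
~40% of a naive permutation test on the same pairs.
The final rank-remapping makes the exchangeability argument exact on
the value distribution, and makes the affine rescaling step of the
variogram fit irrelevant (it is monotone), so only the kernel selection
uses the regression.  `sa_corr_test` surrogates its *first* argument
and holds the second fixed; the test is two-sided on |r| with the
add-one permutation p-value.  Euclidean distances on parcellation
coordinates stand in for geodesic distances.

## Latent factors

Patient synergy matrices are z-scored per entry against the control
distribution (Bessel-corrected control sd), positive z reset to zero,
reductions vectorized over the strict lower triangle in canonical order
((1,0), (2,0), (2,1), ...), and discretized as `round(scale * w)` with
scale 10 (a z of -1.7 becomes 17 counts) — the standard adaptation of
topic models to continuous brain measures.  Inference is batch
variational EM for the smoothed LDA (symmetric priors alpha = 100/K,
eta = 0.01), deterministic per seed, with the evidence lower bound
tracked every iteration; a collapsed Gibbs sampler is available for
small corpora.  Factor order is arbitrary, so models are compared after
Hungarian matching on pattern correlations.  K is selected by
split-half stability (mean matched pattern correlation over repeated
half-splits), a declared substitute for an unspecified criterion.
Among repeated random restarts the model with the highest final bound
is the "final estimate" reported alongside run distributions.

## Associations

Representational similarity uses absolute differences (scalars),
Euclidean distances (vectors), or 0/1 mismatch (categoricals) as
subject dissimilarities, compared via Kendall tau-b on strict lower
triangles (tie-corrected, because categorical RDMs are tie-heavy).
Factor-loading RDMs from repeated LDA runs give a tau distribution per
characteristic, located against the single raw-z tau with a one-sample
t-test.  Clinical correlations residualize covariates from both sides
within site, report per-site and pooled ("overall") Pearson r with
Fisher-z 95% CIs, and apply FDR-BH across the factor x scale family.
The GLM `Y ~ 1 + p1 + p2` leaves the third loading implicit (the
simplex absorbs it into the intercept) and tests contrasts `H beta = 0`
via the standard general linear hypothesis.

## Transcriptomics

Factor maps are regional sums of pattern mass over incident pairs.
Per-gene Pearson correlations with a factor map rank the genes; the top
and bottom `n` form the risk set (ties broken by gene id).  Regional
co-expression is Spearman correlation between region profiles across
risk genes, Fisher z-transformed (duplicated regions are capped just
below |rho| = 1; the diagonal is zeroed).  The scalar summary used
against factor maps is the diagonal-excluded row mean ("co-expression
strength"); a first-principal-axis alternative was considered and
rejected for interpretability — the row mean is the field's common
"hubness" summary.  The virtual knockout rebuilds the co-expression
without each gene; `GCI = r_all - r_without`, so positive GCI means the
gene supports the map correlation.  Note that a gene loading both map
tails symmetrically induces co-expression proportional to `z_i * z_j`,
whose row mean cancels for centred maps; detectable single-gene drivers
load one tail (this shapes the synthetic driver constructions in the
tests).

## Dynamic mean-field model

The reduced Wong-Wang gating equation with Balloon-Windkessel
hemodynamics; regional recurrent strength W, input I and noise sigma
are linear in the myelin and gradient maps (nine coefficients) plus a
global coupling G.  Kinetic constants: a = 270 nC^-1, b = 108 Hz,
d = 0.154 s, tau_s = 0.1 s, gamma = 0.641, J = 0.2609 nA; hemodynamic
constants are the standard Balloon-Windkessel set (kappa 0.65,
gamma 0.41, tau 0.98 s, alpha 0.32, rho 0.34, V0 0.02).  Numerics:
Euler-Maruyama at dt = 10 ms with S clipped to [0, 1]; the firing-rate
transfer evaluates its removable singularity at `a x = b` as 1/d; the
hemodynamic states (time constants ~1 s) are integrated on a 50 ms
grid; BOLD is decimated to TR = 2 s after a 20-60 s burn-in (the
burn-in must cover the hemodynamic transient, which otherwise inflates
all correlations).  FCD is the correlation matrix of sliding-window FC
vectors (window/stride configurable).  The fit cost is
`(1 - r(FC upper triangles)) + KS(FCD entry distributions)`.

Fitting uses an in-house (mu/mu_w, lambda) CMA-ES (rank-one plus
rank-mu covariance update, cumulative step-size adaptation) over the
ten parameters mapped to the unit box, with box projection, a small
uniform pre-screen to avoid starting on the flat plateaus of silent or
saturated dynamics, and common random numbers: all candidate
simulations in one fit reuse a single noise seed, which makes the
objective deterministic and low-variance.  Group-level fits use k-fold
cross-validation over subjects with mean training FC/FCD; the reported
parameters come from the fold with the lowest validation cost.  The
self-recovery checks use 30 cortical regions and 120 s simulations
(90 s analysed), sizes at which the optimizer reliably reaches a
near-zero-cost optimum within 64 generations.

Model-behaviour note: the gating dynamics are bistable; reproducible
coupling-driven FC requires an active-but-unsaturated operating point
and a sparse connectome (few strong partners per region), which is how
the synthetic structural connectome's default density (0.1) was chosen.

## Problem sizes and runtimes

Default test-suite scales: recovery cohort 60/60 subjects, 50 regions,
240 time points; null calibrations 200 replicate mini-cohorts
(15/15 subjects, 12 regions); SA calibration 1000 smooth map pairs with
99 surrogates each; mean-field self-recovery 20 restarts x 64
generations at 30 regions.  These sizes keep the full suite and the
reproduction script each within tens of minutes on one CPU while
leaving comfortable margins on every threshold.

## Known limitations

* Degrees of freedom are not propagated through the two-stage
  residualize-then-test procedure.
* Euclidean, not geodesic, distances for SA surrogates.
* The MMI redundancy functional's independent-channel synergy artifact
  (above) means "persistent synergy" in linear networks tracks regional
  predictability more than cross-coupling per se.
* The collapsed Gibbs backend is a reference implementation for small
  corpora, not performance-tuned.
* No harmonization beyond covariate regression; no mixed-effects site
  modelling.
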