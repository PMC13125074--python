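# Methods

## Problem setting

Functional network connectivity (FNC) summarizes an fMRI session as the
pairwise correlation structure among intrinsic connectivity networks
(ICNs).  With the 53-ICN decomposition used throughout, a static FNC (sFNC)
matrix is 53×53 and its strict upper triangle vectorizes to
V = C(C−1)/2 = 1378 features.  Dynamic FNC (dFNC) repeats the estimate in
tapered sliding windows, giving a sequence of windowed matrices per
subject.  The package learns a two-dimensional latent manifold of these
vectors with a variational autoencoder (VAE), then uses the decoder to
*interpolate* connectivity: between diagnostic groups on a latent grid, and
between dynamic brain states along latent trajectories.

## FNC construction (`fnc_data`)

Time courses are postprocessed per component: linear detrend, OLS
residualization on (detrended) motion regressors, despiking by clipping
samples beyond 4 median absolute deviations from the component median, and
a zero-phase 5th-order Butterworth low-pass at 0.15 Hz.  The MAD threshold
is a package choice — despiking rules vary across toolboxes — and is
configurable.

sFNC is the plain Pearson correlation of the full time courses.  dFNC uses
a tapered window: a rectangle of `width_tr` TRs (20 by default; 26 suits
slower-TR acquisitions) convolved with a Gaussian of σ = 3 TRs truncated at
±3σ, the central `width_tr` samples kept and normalized to sum to one.
Window count follows floor((T − width)/step), the convention that yields
137 windows for a 157-timepoint scan at width 20, step 1.  Within each
window the estimator is the taper-weighted correlation; an L1-penalized
(graphical lasso) covariance estimate rescaled to a correlation is
available behind a flag, with the penalty a configuration value since no
canonical choice exists.  A penalty of exactly zero is the unpenalized MLE
and is served by the weighted-correlation path directly.

## The VAE (`vae`)

Encoder and decoder are MLPs (default 1378→256→64→(2,2) and its mirror,
ReLU hidden activations, linear outputs).  The encoder's second head
produces log σ² for numerical stability, initialized near σ ≈ 0.1 so early
epochs are not dominated by reparameterization noise.  The per-sample
objective is

    L(x) = (1/V) Σ_i (x_i − x̂_i)² − (β/2) Σ_j (1 + log σ_j² − μ_j² − σ_j²)

with z = μ + σ ⊙ ε, ε ~ N(0, I).  The function `vae_loss` evaluates the
β = 1 form exactly.  **Training uses β = 1/V by default** (configurable via
`TrainConfig.kl_weight`): with a per-edge-averaged reconstruction term a
full-weight KL outweighs it by a factor of V on correlation-scale data and
collapses the posterior onto the prior, leaving an uninformative latent
space.  β = 1/V restores the classic summed-ELBO balance (sum of squared
errors plus KL, i.e. a fixed-variance Gaussian likelihood).  The evaluation
studies sharpen the posterior further (β = 0.2/V), which behaves like a
slightly reduced assumed likelihood noise; the choice was made by pilot
reconstruction performance, in the same spirit as an architecture search.

Optimization is Adam at 0.001 with a reduce-on-plateau scheduler (×0.1
after 10 stale epochs), early stopping after 20 stale epochs, at most 1000
epochs, batch size 16 for sFNC (512 suits large windowed sets).  All
randomness — weight initialization, shuffling, ε draws — derives from one
integer seed; identical seed and data give bitwise-identical training on
fixed hardware and thread settings.  Implementation is plain NumPy with
hand-written backpropagation.

The identifiable VAE (iVAE) conditions the latent prior on a one-hot
auxiliary label (here: diagnosis).  Over one-hot inputs the prior network
is exactly a per-label table of (mean, log-variance) pairs, learned
jointly.  With the tables frozen at (0, 0) the objective reduces to the
plain VAE, which is asserted in tests to 1e−10.

## PPCA baseline (`ppca`)

Tipping–Bishop probabilistic PCA fit by EM, with the per-sample
log-likelihood evaluated through the matrix-determinant lemma and asserted
non-decreasing.  At the fixed point the loadings span the top-q eigenspace
of the *maximum-likelihood* (1/N) sample covariance and σ² equals the mean
trailing eigenvalue — the closed-form oracle the tests compare against.
When σ² reaches numerical precision (noiseless data) a measurable
log-likelihood decrease can appear; the fit then keeps the previous iterate
and reports convergence.  Reconstruction decodes the posterior-mean latent.

## Static interpolation (`static_interp`)

Grid half-width r is the 80th percentile of |latent coordinates| pooled
over samples and both dimensions (one scalar, hence a square grid).  The
side is chosen as ⌈√N_train⌉ — 15 for 225 training subjects — and nodes are
evenly spaced over [−r, r]².  Latent dim 1 maps to x (rightward), dim 2 to
y (upward); row 0 of exported layouts is the top of the display.  Originals
are placed by minimizing total Euclidean distance between latent positions
and nodes — a rectangular linear sum assignment solved by the
Jonker–Volgenant algorithm (`scipy.optimize.linear_sum_assignment`), with
inputs pre-sorted by subject id so tie resolution is reproducible.

Region statistics partition the 15×15 grid into upper 7 rows / lower 8,
left 7 columns / right 8, and upper triangle including the diagonal vs
lower excluding it; group comparisons use the Mann–Whitney U test, reported
two-sided and both one-sided.  Trajectories are linear in latent space;
at each point M = 50 draws z = point + s·ε are decoded, with the draw
noise s defaulting to the mean posterior σ of the groups involved and the ε
sequence shared across points so per-edge Wilcoxon signed-rank tests are
paired; Bonferroni correction runs over the V edges.  Display-only
transforms (lower-triangle mean removal, ×2 difference scaling) never touch
stored data.

## Dynamic states (`dynamic_states`)

k-means (k-means++ init, 50 restarts, fixed seed) clusters pooled latent
features of both groups.  The number of states is searched over 2–9 and
selected by an elbow criterion on the mean sample-to-centroid L2 distance,
operationalized as the k with the largest discrete second difference of the
curve.  A warning flags curves without a real elbow: no positive curvature,
or a mean post-bend slope exceeding 0.2 of the pre-bend slope (single-
Gaussian null data sits near 0.3, well-separated planted clusters near
0.05).

Dwell time for group g and state α is the number of windows assigned to α
divided by the number of g-subjects with at least one window there
(membership = ≥1 window; the natural reading of "subjects in that state").
Transition mass N_{α→β} counts consecutive-window moves per subject,
normalized by T−1 and averaged over the group's subjects, so each group's
matrix sums to one including self-moves.  The transition probability matrix
divides each off-diagonal row entry by the row's cross-state mass; the
diagonal is zero by convention and defined rows sum to one.  Rows with no
outgoing cross-state mass are NaN and flagged.

Group state differences are per-edge two-sample t-tests over member
windows (a subject-level variant first averages each subject's windows),
Bonferroni-corrected over edges.  Dwell-time group tests are per-state
two-sample t-tests on per-subject window counts among visitors,
Benjamini–Hochberg corrected over the k states.  Generated states are
matched to originals by maximizing summed Pearson similarity between
median state vectors (optimal assignment), after originals are relabeled
by ascending control-window fraction.

## Synthetic data (`synthetic`)

The generator emulates the statistical structure the framework assumes,
not the biophysics of BOLD.  Shipped prototypes (53×53, synthetic fixtures)
encode the targeted qualitative contrast: patients show reduced positive
connectivity within auditory, sensorimotor and visual domains and between
subcortical and cerebellar domains.  Prototype construction projects the
block design to the nearest correlation matrix (Higham alternating
projections via statsmodels) with a 5% identity shrink for eigenvalue
margin.

Per subject a severity s ∈ [0,1] is drawn — Beta(2,8) for controls,
Beta(8,2) for patients, overlapping tails emulating a continuum — and the
sample is the blend (1−s)·control + s·patient, optionally augmented by a
secondary latent factor, a severity×secondary interaction, extra
nonlinear-coefficient contrast terms, and an element-wise monotone warp.
Noise is added by drawing a Gaussian series of length L ≈ 1/sd² with the
target correlation and taking its empirical correlation, so every emitted
matrix is exactly a valid correlation matrix.  Dynamics follow per-group
first-order Markov chains over k state prototypes spanning sparse-to-dense
connectivity, with patients stickier in the sparsest state — the planted
dwell-time contrast.

The model-comparison dataset bends the continuum deliberately (tanh warp,
quadratic severity term, interaction) so the manifold is intrinsically 2-D
but spans more than two linear dimensions; a plain monotone blend of two
prototypes is a straight segment in data space that a two-component linear
model captures exactly, which would make the nonlinear-vs-linear question
vacuous.  Its edge noise (sd 0.02) keeps the manifold the dominant variance
component, mirroring the strong 2-D structure the method targets; the
generic continuum default is sd 0.05.

What passing these tests does *not* show: robustness to scanner/site
effects, head-motion artifacts, non-Gaussian edge noise, or ICA estimation
error — none of which the generator emulates.

## Evaluation studies (`studies`) and problem sizes

The acceptance studies run at desk scale, single CPU: assignment oracle on
1000 instances (N ≤ 6 vs brute force); PPCA oracle at N = 2000, V = 50;
elbow recovery on 10 draws of 1500 points from five 6σ-separated Gaussians;
transition recovery at 50 subjects × 150 windows on one pooled chain
(±0.05 tolerance; the conditional cross-state probabilities are the
noisiest estimates, so the cohort is not split);
dwell-contrast detection over 10 draws of 20+20 subjects × 100 windows;
null calibration over 100 simulations each; model comparison on 120+120
subjects (85/15 split) × 10 model seeds, VAE (256, 64) vs PPCA q = 2;
latent alignment on 100+100 subjects × 10 seeds with the lighter (128, 32)
encoder.  Null-calibration bounds use the binomial envelope of a perfectly
calibrated 5% test (≤10 flagged runs in 100).

## Numerical choices and degenerate inputs

Matrices must be symmetric within 1e−8; devectorized matrices get unit
diagonals.  Zero-variance components are an error naming the component;
zero-variance vectors in correlation metrics are flagged, never silently
dropped.  Posterior log-variances are clipped to ±15.  k-means with an
empty requested cluster is retried by sklearn's restarts.  Flat inertia
curves return the smallest k with a warning.  Wilcoxon edge tests with
fewer than 6 draws carry a low-power flag.  The σ → 0 taper limit is the
uniform window.

## Known limitations

The 2-D latent restriction is intrinsic to the design (grid display);
D = 3 is configurable but no grid pathway exists for it.  Sliding-window
correlation itself is a contested dFNC estimator and is implemented as
specified, not defended.  The iVAE prior is a per-label Gaussian, not a
mixture.  Training is CPU-oriented; very large windowed datasets will be
slow compared to GPU frameworks.
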