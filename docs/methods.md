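# Methods

This note documents the models, statistics and numerical choices behind
`popgate`, in the order the pipeline runs them.

## Task

Each trial has a pre-stimulus period (default 4 steps) and a stimulus
period (10 steps). Inputs are four channels: two stimulus features (A, B)
at levels ±1, shown only during the stimulus period with i.i.d. Gaussian
noise (σ = 1) added at every timestep, and two context cues coded (0, 1)
and on throughout the trial. The go level of both features is −1; context A
maps its go to response −1 (go-left), context B to +1 (go-right), mirroring
the location → go-left / pitch → go-right convention of the rodent task the
abstraction is based on (configurable via `TaskParams.go_sign`). The
irrelevant feature never affects the correct response, which gives no-go
(0) in half of the balanced conditions.

## Rank-one network and training

Units obey `τ ẋᵢ = −xᵢ + (1/N) mᵢ (n·φ(x)) + Σ_l u_l(t) Iᵢˡ + ηᵢ(t)` with
φ = tanh, τ = 100 ms, forward Euler at Δt = 20 ms, and white state noise of
SD 0.05. The readout is `z = (1/N) w·φ(x)` at the last timestep, and the
decision is the nearest of {−1, 0, +1} (an absolute-threshold alternative
is exposed; the two coincide for thresholds at ±0.5). All vectors are
initialised i.i.d. standard normal; training optimises only `m, n` and the
two contextual input vectors with Adam (learning rate 10⁻³, moment decays
0.9/0.999) on the squared error of the final-timestep readout, with fresh
balanced batches of 160 trials per step. Gradients are backpropagated
through the Euler unrolling analytically (verified against numerical
differentiation to machine precision); the trainer generalises to rank r
by making `m, n` matrices of shape (N, r).

The default budget is 320,000 trials (2,000 Adam steps). Steps-to-converge
depends on conventions the dynamics alone do not fix — most importantly the
1/N readout normalisation and the unit-variance initialisation — and under
ours, shorter budgets (e.g. 100–400 steps) leave the loss far from floor.
At 2,000 steps training reaches ≥ 98% accuracy in both contexts across
seeds, in about a minute of CPU.

## Latent reduction and mean field

Rank-one activity is confined to `x(t) = κ(t) m + Σ_l v_l(t) I_l` with
`v_l` the low-pass filtered inputs (they share the network time constant;
nothing in the model argues for a separate input constant).
`latent_project` recovers the coefficients by least squares and reports the
residual; for noiseless simulations the span explains > 99% of the state
variance and PCA finds at most 1 + 4 components.

With neurons grouped into populations whose loadings are jointly Gaussian,
the population average `E_p[a φ(x)]` is evaluated by Stein's lemma as
`μ_a ⟨φ(x)⟩_p + ⟨φ′(x)⟩_p Σ_c Cov_p(a, c) s_c`, where `s_c` are the current
drive coefficients. Both population averages ⟨φ⟩ and ⟨φ′⟩ are computed by
Monte-Carlo over the population's loading distribution (10,000 draws by
default, drawn once — common random numbers across timesteps). Two details
matter in practice:

* the `μ_a ⟨φ⟩` term is not optional: when the reduction is fed a finite
  network's *empirical* statistics, the per-population mean of `n` is
  O(sd(n)/√n_pop) rather than zero, and its product with the rates of a
  saturated population is a leading-order term;
* every constant input (the two-area bias term below) must enter through
  its own low-pass latent — a constant drive's state coefficient ramps with
  τ, it is not instantaneously 1.

Integration is explicit Euler at the network Δt, with self-consistent
gains re-evaluated every step. The mean-field is integrated without the
state noise term and compared against trial-averaged simulations.

**Validation metric.** Agreement with full networks is measured as the
relative L2 error of latent trajectories. For a *given* finite network the
reduction uses that network's empirical per-population moments, with its
actual neurons as the gain sample (`GaussianPopulations.empirical`); this
isolates the Gaussian-closure approximation from overlap sampling noise,
which scales as 1/√n_pop and otherwise dominates. Under this metric the
single-area reduction tracks N = 4000 networks within ~1–2% RMS, and the
two-area reduction tracks N = 2000/area networks within ~2% on the stacked
latent state (κ_A, κ_P, v_A→P, v_P→A), averaged over three network draws.
Per latent, κ_A, κ_P and the feedback latent are each below 5%; the
small-amplitude feedforward latent v_A→P sits around 5% because the ~3%
closure error of κ_A accumulates into its integral. Theoretical
(ensemble) statistics are used only for the scaling check that the
discrepancy shrinks with N.

## Three-population solution

The engineered solution has three equal populations with zero-mean
connectivity (m, n) and readout `w = γ m` (the output axis is exactly m):

* population A: `σ_nI_A = +β` (integrates stimulus A; its go level −1
  drives κ negative → go-left), `σ_nm = r > 0`;
* population B: `σ_nI_B = −β` (its go level drives κ positive → go-right),
  `σ_nm = r`;
* population 0: `σ_nm = −ρ` (negative feedback, stabilising the no-go
  state κ = 0).

The signed integration by population B makes κ itself carry the response
sign, which is what allows a single rank-one channel to transmit the
decision downstream; a sign-symmetric variant (both overlaps positive,
per-population readout signs) solves the single-area task equally well but
cannot communicate left/right through one scalar.

Gating is implemented through population-mean input shifts: in population
A, the preferred-context input I_xA and the preferred stimulus input I_A
both have mean μ_stim, so during context A the go level (−1) cancels the
contextual shift (working point near 0: high gain, strong integration)
while the no-go level (+1) doubles it (saturation — the stimulus is shut
out of the latent); the non-preferred context input I_xB has a large mean
μ_sup that saturates the whole population in context B. Population B
mirrors this; population 0 receives no net contextual shift. The
pre-stimulus signature follows: gating populations fire *less* (sit at a
smaller |x|, higher gain) in their preferred context.

The free magnitudes (β = 12, r = 2, ρ = 1, μ_stim = 1.5, μ_sup = 6.5,
γ = 3.5, residuals ν = 0.5, σ_ctx = 0.3) were fixed once by the coarse grid
search in `scripts/calibrate_three_pop.py`, selecting for task accuracy of
sampled networks (≥ 0.95 in both contexts at N = 1500), and are frozen as
`ThreePopParams` defaults. A purely covariance-based gating (correlated
stimulus/context loadings modulating the population variance) was tried
first and produces the right sign of gain modulation but ratios too weak
to reach criterion accuracy.

## Cluster-and-resample population inference

Neurons are clustered in the 6-D space of connectivity loadings
(m, n, I_A, I_B, I_xA, I_xB) with a full-covariance Bayesian Gaussian
mixture (10 restarts, best fit kept; a plain maximum-likelihood mixture is
available behind a flag). The Bayesian variant's weight prior shrinks
components the data do not support, which separates the population count
of trained networks more cleanly than the plain mixture, whose best k = 2
partitions occasionally look "comparable"; a fit that leaves components
empty is read as collapsing to fewer effective populations. Per-cluster
moments are stored over seven columns — the six loadings plus the readout
w — so that resampled networks preserve readout–connectivity correlations;
clustering itself never sees w. Resampling draws new neurons per cluster
(largest-remainder size allocation) from the cluster's multivariate
Gaussian, destroying single-neuron identity while keeping population-level
correlations.

"Comparable accuracy" for the minimal population count means a median over
10 resamples of at least 95% of the source network's accuracy. Because the
underlying question is existential/universal — does *some* k-population
summary reproduce the function, and does *no* smaller one — each k is
given the same search effort: the best of three clustering draws.
Trained rank-one networks fail at k = 1 (resampled accuracy ~50–75%) and
k = 2 (~90–94%) and pass from k = 3 (~95–98%). This population-count
result is a property of the solution regime: networks trained far past
convergence develop loading statistics whose single global Gaussian
already recovers ~93% accuracy, one reason the default training budget
stops at the point of reliable high accuracy rather than training
indefinitely.

## Two-area network

A1 and PFC are rank-one areas joined by rank-one blocks with the
across-area selection vectors aligned to the source output axes
(`n_A→P = m_A`, `n_P→A = m_P`), so each direction carries one scalar. A1 is
the three-population solution; its context vectors are not driven
externally but reconstructed from PFC feedback: a constant bias
`I_k = (I_ctxA + I_ctxB)/2` plus the fed-back context signal along
`I_x = (I_ctxA − I_ctxB)/2` yields net input I_ctxA or I_ctxB depending on
the sign of PFC's memory. PFC is a single population with bistable
self-overlap (σ_nm = 1.6 > 1) and a context-input overlap of 2; the context
cue (±1) is delivered only transiently (default: the pre-stimulus period,
8 steps in two-area simulations so the memory can charge before stimulus
onset). The behavioural response is read out from PFC along the
feedforward input direction.

Three scalars are calibrated deterministically at construction time from
short probe simulations: the feedback gain and offset (two-point
calibration, one per context attractor, so the fed-back signal is exactly
±1), and the readout. The readout adds a small `m_P` component and scalar
bias that cancel the context-dependent finite-size offset of the
projection, and is scaled under operating noise so go responses average
±2: the nearest-target rule penalises undershoot (misses at the ±0.5
boundary) but not overshoot, so aiming past ±1 moves the go noise tails
away from the boundary without endangering the (much less variable) no-go
responses. The feedforward loading SD is 1.5 — large enough for readout
signal-to-finite-size-noise, small enough that PFC stays in its linear
range so the communication is genuinely two-dimensional (larger values
create measurable nonlinear harmonic channels).

## Synthetic recordings

The generator emits Poisson spike counts in 50 ms bins (1 s pre-stimulus +
250 ms stimulus; negative-binomial emission available for over-dispersion
checks), 50 correct trials per condition by default, with trials arranged
in alternating context blocks. Neurons carry: a gamma-distributed baseline
(mean 8 Hz); a fractional pre-stimulus rate *reduction* in the preferred
context (mean 0.35) for the two gating populations and exactly zero for
population 0; signed tuning to both features (SD 1.2 Hz — strong but
imperfect population decoding); and a signed gating response (SD 8 Hz)
added only for the go level of the relevant feature in the neuron's
preferred context. The 'pfc' preset zeroes the sensory coefficients and
keeps the gating ones. Effect sizes were chosen once so that the planted
code sits in the regime the analyses assume (labelling recoverable from
~200 one-second trials per context; sensory decoding high but below
ceiling; selection responses dominating relevant-context decoders) and are
not revisited per analysis.

What the generator does *not* emulate: session and animal hierarchies,
heterogeneous trial counts (a fixed count per condition is used), error
trials, spike-time structure within bins, and correlated noise across
neurons (emission is conditionally independent). Passing tests therefore
show the estimators behave correctly when their assumptions hold, not that
real recordings satisfy those assumptions.

## Decoding and axes

Pseudo-populations: per fold, each neuron's trials of each condition are
split into disjoint halves (independently per neuron and fold) and 50
pseudo-trials per condition are resampled with replacement, half from each
side of the split — training and testing pseudo-trials never share a
source trial (sharing sources leaks trial noise and inflates accuracy well
above chance). Decoders are L2-regularised logistic regression (C = 1) on
stimulus-window-averaged counts; per-bin time courses are available, in
which case axis estimation uses weights averaged over the stimulus window.
Across-context decoding trains in one context and tests in the other, both
on their half of the pseudo-trials so within- and across-context scores
use equal trial counts. Default folds: 500 (analyses here typically use
15–100; fold count trades precision of the fold-mean against runtime and
does not bias the mean). Uncertainty: percentile bootstrap over folds,
1,000 resamples.

The sensory axis is the normalised irrelevant-context decoder; the
selection axis is the component of the relevant-context decoder orthogonal
to it (QR decomposition), flagged degenerate when the residual vanishes.
The angle null distribution shuffles the relevant weights across neurons.
The output axis is the normalised go-minus-no-go difference of mean
stimulus-window counts, restricted to a neuron subset.

## Population labelling and output gating

Labelling: two-sided Mann–Whitney on per-trial pre-stimulus mean rates
between contexts, Benjamini–Hochberg across neurons at α = 0.05;
significant neurons are labelled by the context where they fire *less*
(their preferred context), the rest are population 0. The implementation
is a vectorised normal-approximation with tie correction (checked against
scipy to 10 decimal places) so the permutation test stays cheap.

The output-gating ratio is |GO − NoGO| along the population's output axis
in the preferred context divided by the same separation in the other
context, averaged over the full 250 ms stimulus window; an exactly
vanishing denominator returns an infinite-ratio sentinel with a warning.
For population 0 the larger-separation context plays the preferred role
(the anti-conservative choice: population 0 still comes out
non-significant). The permutation null shuffles trial context labels per
neuron, re-runs the labelling on the permuted pre-stimulus rates,
reselects a matched-size population by the permuted modulation statistic,
and recomputes the ratio under the permuted labels;
p = (1 + #{null ≥ obs}) / (1 + n_perm), default 400 permutations
(resolution 0.0025). Labelling uses only pre-stimulus bins and ratios only
stimulus bins, enforced structurally by the window bookkeeping.

Single-neuron selectivity regresses stimulus-window counts on location,
pitch, decision and context jointly across contexts — the joint fit breaks
the within-context collinearity of decision with the relevant feature, and
the design rank is checked explicitly. Coefficients are tested at 0.05
with no within-neuron multiplicity correction; one significant weight =
pure, more = mixed. The drift control regresses counts on block number and
block identity and flags neurons whose apparent context effect is a
significant block-number trend without an identity term.

## Communication subspaces

Noise activity = stimulus-window time-averaged rates minus per-neuron
condition means, per context. Per fold (default 250; 100 in the shipped
analyses): random half-split, PCA to the top 10 components per area and
CCA fitted on the training half only (fitting on all trials leaks test
information), canonical-variate Pearson correlations evaluated on the
held-out half. The significant-dimension count is the number of *leading*
dimensions whose fold-wise 95% percentile interval excludes zero (a
permutation-across-trials null is the obvious alternative; the percentile
rule is the default because it needs no extra passes). The count is
sensitive to the number of retained PCs, so `pc_sweep` reports it for 5,
10 and 20. Canonical directions in neuron space (for angle and
per-population coefficient analyses) come from a fit on all trials;
subspace alignment is the smallest principal angle, arccos of the largest
singular value of the cross-Gram matrix of orthonormalised bases.

## Problem sizes in the shipped analyses

Trained networks: N = 512, 320k trials. Engineered single-area nets:
N = 1500 (4000 for mean-field checks). Two-area: 1500/area (2000/area for
mean-field checks), 1000 trials for CCA. Recordings: 130 neurons, 50
trials per condition. These sizes keep every analysis deterministic-seeded
and desk-scale while leaving all effects far from threshold.

## Known limitations

* The mean-field comparisons quantify the Gaussian closure for *given*
  networks; ensemble-statistics predictions carry additional O(1/√n_pop)
  overlap-sampling spread, quantified only as an ordering (error shrinks
  with N).
* The engineered constructions are calibrated objects: their frozen
  magnitudes are one point in a large feasible set, chosen for accuracy
  and interpretability, not fitted to data.
* The CCA dimensionality estimate inherits the known sensitivity to the
  PCA preprocessing dimension; conclusions should be read off the sweep,
  not a single setting.
* Spike-count analyses assume conditionally independent emission; shared
  trial-to-trial variability in real data would require the pseudo-trial
  machinery to be revisited.
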