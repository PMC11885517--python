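# Methods

## Generative task model

A trial is a sequence of azimuth locations (degrees, abstract 1-D; no
left/right semantics are used anywhere). The generative mean μ is drawn
uniformly in [−60°, 60°]; each sound's location is μ + ε with
ε ~ N(0, σ_exp²), σ_exp = 10°. With hazard H = 1/6 a sound is a
change-point: μ is resampled before the location is drawn. After each sound
the sequence terminates with probability 1/12 (that sound is the probe);
a probe is forced at the cap of 43 sounds, so sequence lengths are
geometric(1/12) truncated at 43 and span 1–43. The truncation rule is a
design choice — forcing the probe at the cap keeps every sequence usable
while leaving the sub-cap length law exactly geometric.

SAC (sounds after change-point) convention: the change-point sound itself
has SAC 1 — it is the first draw from the new mean. The first sound of a
sequence samples a fresh mean and is SAC 1. This convention is the only one
under which surprisal peaks at SAC 1 and prior uncertainty at SAC 2 (see
below), matching the behavioral literature on such tasks.

Sessions present each sequence twice, audio-only (A) and audio-visual (AV),
in a uniformly shuffled order conditioned on pair members never being
adjacent (rejection sampling on the shuffle; a single pair has no valid
arrangement and is rejected).

## Observer model

The observer performs exact Bayesian filtering on a discretized belief over
μ (grid −90°..90°, step 0.5°). A grid was chosen over a run-length
(changepoint-recursion) representation because the bounded-uniform reset
prior is non-conjugate with the Gaussian likelihood; on the grid the hazard
mixture is exact:

    prior_t(μ)  = (1 − H) · post_{t−1}(μ) + H · U(±60°)          (full prior)
    post_t(μ)   ∝ prior_t(μ) · N(x̃_t; μ, σ_exp² + σ_s²)

where x̃_t = x_t + η, η ~ N(0, σ_s²), is the noisy sensory observation
(`noisefree` mode uses x_t itself, for deterministic tests). The observer is
"near-optimal": it assumes the true H, σ_exp and mean bounds; only the
sensory noise σ_s differs by condition (fitted per subject for A; fixed at
1° for AV). The probe sound is auditory-only in both conditions, so the
probe observation uses the auditory σ_s by default (configurable).

Latent variables, per sound:

* **Prior uncertainty** PU_t = SD(post_{t−1}), the belief carried into
  sound t *before* hazard mixing. The alternative (after mixing) is one
  flag away (`pu_after_hazard`); the default reads "preceding posterior"
  literally. PU peaks at SAC 2 because the posterior formed *at* the
  change-point sound — carried into the next sound — is dominated by the
  reset component and therefore broad.
* **Surprisal** SU_t = −ln p(x̃_t) in nats, where p is the full prior over
  μ convolved with Gaussian observation noise. **Which** noise enters the
  convolution is a policy (`surprisal_obs_noise`): `"sensory"` (default,
  σ_s only), `"sensory+experimental"` (the full predictive
  √(σ_exp²+σ_s²)), or `"none"`. The default matters: only with at most
  sensory-noise convolution is mean SU larger in AV than A — the
  log-normalization term ½ln(2π·SD²) of the full predictive otherwise
  dominates and reverses the modality ordering. With `"none"` the A
  condition is pathological (sensory noise pushes observations outside the
  bounded prior support onto the density floor). Densities are floored at
  1e-300 before the log, so SU is always finite; observations outside the
  grid support are clamped (with a warning) only in the unconvolved policy.

At the probe the observer reports on the probe's *location* l (not μ):
p(l | x̃) ∝ Σ_μ prior(μ) N(l; μ, σ_exp²) N(x̃; l, σ_s²), a Gaussian mixture
whose components sit at μ + ρ(x̃ − μ) with ρ = σ_exp²/(σ_exp² + σ_s²). The
report is the posterior mean plus the central credible interval (default
80%) by linear interpolation of the grid CDF (mass at cell centers). With
observer parameters equal to the generative ones this interval is
calibrated: empirical coverage ≈ 80% (the tests check 2000 trials; grid
discretization and the ~0.1% of probe locations beyond ±90° leave the
coverage within a point of nominal).

Numerical notes: grid normalization is preserved to 1e-10 by every
operation; halving the grid step changes PU/SU by <0.5% plus a ≤0.03°
discretization floor; with H = 0 the recursion matches conjugate Gaussian
updating within 1%.

## Fitting

Response model: response = posterior-mean probe estimate + N(0, σ_m²)
motor noise (posterior mean rather than MAP; MAP coincides for the
unimodal probe posterior in practice). The marginal likelihood of a
response integrates over the sequence's unobserved sensory noise; this is
approximated with n Monte-Carlo draws of the full noise path, common random
numbers across parameter values (default n = 32). The optimizer is a
12-point log-spaced grid over σ_s ∈ [0.5, 40]° with σ_m ∈ [0.1, 30]°
profiled out by bounded 1-D search, then bounded scalar refinement of σ_s
between the neighbors of the grid optimum. Everything is deterministic
given the fit seed.

The Monte-Carlo mixture behaves like a kernel density in the response:
with few draws its narrow-bandwidth bias pulls σ_s down, most visibly when
motor noise dominates (small σ_s). The parameter-recovery experiments
therefore use 64 draws, which brings the median recovery error across
σ_s ∈ {5, 10, 20}° within ~15% at 300 trials; the default remains 32,
adequate at the A-condition scale (σ_s ≈ 10°, median error ~15–17%,
within the 25% recovery band).

## Behavioral metrics

Per trial: estimation error |x_resp − x_t|; response uncertainty (interval
width, degrees — for simulated observers the credible-interval width);
prior bias (x_resp − x_t)/(x_{t−1} − x_t). A zero denominator is a
degenerate record and is excluded, never zeroed. Summaries are per
condition × SAC 1–6, excluding single-sound trials; probes with SAC > 6 are
excluded by default (full range behind a flag). Latent summaries use
medians of within-subject z-scores; empty cells are reported with n = 0,
not imputed.

The prior-bias ratio is heavy-tailed — its denominator is the difference of
two nearby locations — so SAC-level contrasts are evaluated on medians with
multi-subject pooling; cell means at single-session scale are dominated by
a handful of near-zero denominators. The linear mixed-effects analysis used
on real data is deliberately not reimplemented (it targets unavailable
data); effect directions are validated on the summary tables instead.

## Synthetic EEG

Channels sit on a unit disk (sunflower layout) with Delaunay adjacency.
Each epoch (default −0.3..0.5 s at 250 Hz; the full −1..2 s span is a
parameter) is 1/f-power noise per channel plus a low-rank set of shared 1/f
sources (spatial channel correlations) plus white sensor noise. Implanted
components have a dipolar spatial map (Gaussian bumps of opposite sign),
a Gaussian temporal kernel, a DC carrier (ERP-like) or a random-phase
oscillation (induced; invisible in the evoked average), and per-epoch
amplitude base + β·z(latent), with latents z-scored within subject over the
included (non-first, non-probe) epochs — the same convention as the
regression. Epochs are baseline-corrected (−100..0 ms mean per channel and
epoch). Ground truth records each component's channel extent (|weight| ≥
half max), time extent (kernel ≥ half max) and datapoint signs.

What the generator does *not* emulate: volume conduction from dipole
physics, real ERP component families, artifacts (blinks, microsaccades,
line noise), non-stationary background. Passing recovery tests therefore
show the *statistical machinery* is correct under the assumed data model,
not that the pipeline is robust to real-world artifacts.

## Spectral analysis

Induced power: the across-epoch mean is subtracted per channel/time before
decomposition. Low band: 4–30 Hz at 1 Hz spacing, single Hanning taper,
fixed 300 ms window, 16 ms steps. High band: 40–100 Hz at 2 Hz spacing,
DPSS multitapers, window length linear 250 ms (40 Hz) → 100 ms (100 Hz),
taper count 3 → 1 (linear, rounded) with time-bandwidth NW = (K+1)/2.
Output times align to the sample nearest sound onset; only centers with
full window support are emitted (no zero-padding). Power is normalized per
taper energy × window length so a unit sinusoid yields comparable power
across the varying windows. Because the multitaper spectral window is flat
over its design half-bandwidth (≈ 8–10 Hz, wider than the 2 Hz bins), a
pure tone's argmax can land anywhere inside that bandwidth; tone-recovery
accuracy is therefore bandwidth-limited in the high band and exact-bin in
the low band. Baseline: relative change (p − m)/m against the per-epoch
0–500 ms mean (per-epoch rather than per-average baselining, reading the
"around each sound" convention strictly), computed on raw power.

## Mass-univariate regression and cluster inference

Included epochs: all sounds except firsts (no informative prior) and
probes (held out for the brain–behavior analysis). Both predictors (PU,
SU) enter one OLS design with intercept; EEG and predictors are z-scored
(population SD) — EEG per datapoint across included epochs, per subject
(the per-datapoint reading of the z-transform; a global per-subject scale
would only rescale betas uniformly). Collinearity |r| > 0.999 between
z(PU) and z(SU) is rejected.

Group inference: per-datapoint one-sample t across subjects (paired
contrasts via the difference maps, so sign flips realize condition swaps);
two-sided cluster-forming threshold at α = 0.001 on the t distribution
(df = n−1); suprathreshold datapoints of like sign are clustered by
adjacency (channel neighbors, ±1 time step, ±1 frequency bin; no adjacency
across the low/high bands); cluster mass = Σt; clusters spanning ≤ 5 ms
are dropped (at 250 Hz: one sample dropped, two kept). The null is the
distribution of the maximum |mass| over random sign-flip assignments
(identity counted via the +1 in p = (1 + #exceedances)/(n_perm + 1)), so
the smallest attainable p with 1000 permutations is 1/1001 ≈ 0.001. The
0.001 level acts as the cluster-*forming* threshold; cluster significance
is declared at permutation p < 0.05, so clusters at intermediate p-values
(e.g. 0.02) remain significant while the datapoint threshold stays
stringent. Family-wise error is
verified empirically: over 200 null datasets the rate of any cluster
p ≤ 0.05 stays ≤ 0.08. An independent cross-check against MNE's
spatio-temporal cluster test (same threshold) confirms the t-maps, cluster
partitions and masses.

## Brain–behavior link

For each significant cluster (defined on non-probe epochs — independence by
construction), probe-epoch activity is averaged over the cluster's
datapoints, giving one scalar per trial. Within subject, each behavioral
variable is regressed on that scalar (both z-scored, so the slope is a
correlation); group-level one-sample t-test of the slopes at α = 0.05,
uncorrected across cluster × variable pairs (a deliberate convention;
correction across the family is trivial to add downstream).
Subjects with degenerate variance are dropped with a warning. TFR clusters
are scored on the same band's TFR of the probe epochs with identical
parameters.

## Desk-scale configuration

Default simulated-study sizes — 8 subjects, 60 trial pairs, 32 channels,
epochs −0.3..0.5 s, 200 null datasets with 200 permutations each for the
error-rate experiment, 1000 permutations for cluster inference — keep the
full pipeline at minutes-scale on one CPU while preserving every analysis
window and threshold. All sizes are parameters; the full-scale
configuration (128 channels, −1..2 s, 150 pairs, 1000-permutation error
experiments) runs unchanged, just longer.

## Known limitations

* Some observer details admit alternatives (response-likelihood form,
  number of free parameters, whether hazard or a lapse rate should also be
  fitted); the recursion here is exact for the stated generative model,
  with σ_s (and σ_m) as the free parameters.
* The surprisal convolution policy is a genuine modelling fork (see above);
  the default is the one under which the modality orderings of the latents
  come out as the task's logic demands (tighter priors, larger surprisal).
* Prior-bias ratio statistics are intrinsically heavy-tailed; conclusions
  should rest on medians or trimmed statistics.
* The synthetic EEG validates machinery, not robustness to real artifacts.
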