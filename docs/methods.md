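# Methods

This note documents the models implemented in `netage`, the parameter choices
that matter, what the synthetic colony generator does and does not emulate,
and the numerical conventions pinned where several readings were possible.

## The network-age pipeline

### Affinity matrices

Eight interaction modes are aggregated per 24 h over the bees alive that day:

| mode | type | construction |
|---|---|---|
| `proximity_count` | symmetric | count of proximity events (tags < 2 cm for ≥ 3 consecutive same-side frames); counts rather than durations limit the weight of bees resting side by side |
| `trophallaxis_count` | symmetric | count of contacts passing the trophallaxis classifier |
| `distance_gaussian` | symmetric | exp(−d²/2γ²) of the mean pairwise distance d over co-visible frames, γ = max(D)/4 |
| `distance_max_minus` | symmetric | max(D) − d |
| `effect_{mean,cum}_{pos,neg}` | directed | per-contact change in the focal bee's mean (or cumulative) speed over 30 s windows before/after the event, positive and negative parts accumulated separately so all matrices stay nonnegative |

Interaction-effect records use only proximity events no longer than 60 s and
at least 5 s after the same pair's previous event. Multiple same-pair records
in a day are summed: summing preserves contact-count information consistently
with the count modes. Pairs that never interact (or are never co-visible)
receive affinity 0 and participate in the ranking as the lowest tie.

**Rank transform.** Off-diagonal affinities are replaced by dense ranks
(ties collapse to a single rank level) mapped affinely to [0, 1]; symmetric
matrices are ranked over unordered pairs so symmetry is preserved, and a
constant matrix maps to 0.5 (the midpoint asserts no order where none
exists). Dense ranking is pinned by the tie convention: {1, 1, 3} → {0, 0, 1}.

### Spectral embeddings

Symmetric modes: eigenvectors of the symmetrically degree-normalized
adjacency D^{−1/2} A D^{−1/2} (equivalently, the smallest nontrivial
eigenvectors of the symmetric normalized Laplacian), computed densely with
LAPACK, skipping the trivial leading vector and keeping the next 8. Directed
modes: SVD of D_r^{−1/2} A D_c^{−1/2}; left singular vectors embed rows,
right singular vectors embed columns, again skipping the trivial pair. With
4 symmetric and 4 directed modes this gives 12 coordinate sets × 8 dimensions
= 96 factors per bee-day.

Numerical conventions:

* A uniform ε = 10⁻⁸ · max(A) is added off-diagonal before normalization.
  This guarantees a connected graph (every alive bee receives coordinates —
  required because CCA needs complete rows) and, because ε scales with the
  matrix, the embedding is exactly invariant to a global rescaling of the
  affinities.
* Each eigenvector's sign is fixed by making its largest-magnitude entry
  positive; across days, signs are then aligned per mode and dimension by
  flipping day *t* whenever its Spearman correlation with the aligned day
  *t* − 1 over shared bees is negative (flips chain forward from the first
  day). Alignment happens per mode *before* concatenation.
* Eigenvalue crossings between days can permute dimensions; no
  dimension-matching is performed. This is a known limitation: the CCA step
  downstream pools all days and tolerates it in practice.

### CCA, scaling, orientation

Factors are pooled over all (bee, day) rows and z-scored per column (the
modes have incommensurate scales after concatenation; constant columns are
left at 0). Classic two-view CCA is computed by whitened SVD
(C_xx^{−1/2} C_xy C_yy^{−1/2} = U S Vᵀ, projection = C_xx^{−1/2} U), with a
relative ridge of 10⁻⁸·tr(C)/F for stability and a pseudo-inverse square
root on the descriptor side (the four fractions sum to one, so C_yy is rank
3). k = 3 canonical directions are kept; dimension 1 is network age. The PCA
variant takes principal directions of the same standardized factors;
targeted embeddings run the same CCA against a single scalar property.

Per day and dimension, values are affinely mapped so the 5th percentile → 0
and the 95th → 40 (linear-interpolation percentiles; values outside extend
linearly; a degenerate day maps to the midpoint 20). The sign of dimension 1
is then chosen so bees below the 5th percentile are biologically younger on
average than bees above the 95th; the flip is applied to the raw values and
the scaling recomputed (flip-then-rescale).

## Lifetime changepoint model

A bee is alive on days [e, e + l). Daily detection counts are normalized by
the bee's maximum; the observation per day is the indicator
(normalized count ≥ t), Bernoulli(p) while alive and Bernoulli(1 − p) after
death (the symmetric form is adopted for the post-death observation model).
Priors: l ~ N(35, 50) truncated to l > 0 — "35, 50" is read as mean and
standard deviation, the weakly-informative reading — p ~ Beta(5, 1),
t ~ Beta(25, 1). The reported death day is e + E[l | data].

Two backends:

* **grid** (default): the likelihood is piecewise constant in t (between
  adjacent observed count values) and in l (one-day cells), and p integrates
  analytically by Beta–Bernoulli conjugacy, so the posterior over l is an
  exact finite sum. Cells carry their exact truncated-normal prior mass and
  report their midpoints, matching the continuous-l convention of the
  sampler. Deterministic.
* **mcmc**: parallel-tempered blocked Gibbs (5 temperatures, geometric-ish
  ladder 1…0.08; 2000 tuning + 1000 kept sweeps). p | l, t is conjugate
  Beta; the block (l, t) | p samples l with t summed out exactly, then
  t | l, p; continuous values inside a chosen cell/piece come from inverting
  the prior CDF. Tempering matters: this posterior has well-separated minor
  modes (e.g. "died immediately; the high-count days are 1 − p failures"),
  and untempered chains lock into whichever mode they first touch. The two
  backends agree within 0.5 days on noisy synthetic bees.

Known limitation: for bees introduced long before the first observed day,
the model has a left-censoring plateau — every l that puts death before the
observation window explains the data equally well — which drags the
posterior mean down. Death-date evaluation therefore uses bees that emerge
inside the recording window; estimates for pre-window cohorts should be
treated as lower bounds.

Filtering before the model: detections below a confidence threshold are
dropped, ids observed before their introduction day are dropped, and ids
whose total detection counts fall below an Otsu threshold (between-class
variance maximization on a 256-bin histogram) are removed as erroneous tag
decodings.

## Task descriptor and movement metrics

Per bee and day, at most one detection per minute (the highest-confidence
one above 0.9 — the minute-sampling rule is not otherwise specified and a
deterministic choice aids reproducibility) is tested against the annotated
areas. Point-in-polygon uses the even-odd rule with boundary points counted
inside; overlapping annotations resolve by the priority exit > dance_floor >
brood > honey (configurable); areas are matched on comb side. Counts over
{brood, dance floor, honey, exit} are normalized to 1; samples outside every
area are ignored; bee-days with no in-area samples have no descriptor row.

Velocity is the distance between consecutive detections over elapsed time,
median-filtered with kernel 3 (endpoints use shrunken windows). Circadian
power fits a·sin(ωt) + b·cos(ωt) + c with ω = 2π/24 h by least squares over
3-day windows; P = 1 − SSE_sine/SSE_constant ∈ [0, 1] since the sine model
nests the constant one; peak time is the phase of the fitted maximum. Day
and night velocities average over 09:00–18:00 and 21:00–06:00 UTC. A
Lomb–Scargle periodogram is a useful independent check where available; the
fixed-frequency fit is the canonical implementation.

## Evaluation machinery

Task models regress the descriptor on a feature with a softmax link and
multinomial likelihood (jointly over the four areas) or a sigmoid link and
binomial likelihood (one area), each row weighted by its number of minute
samples — the descriptor rows are fractions, so the weighted fractional
likelihood stands in for the underlying counts. Scalar behavioral targets
use an identity link with Gaussian errors. Optimization is deterministic
L-BFGS from zero (the nonlinear variant — two fully connected layers, hidden
width 8, tanh — trains full batch from a fixed-seed initialization).
McFadden's pseudo-R² is 1 − ℓ₁/ℓ₀ on log-likelihoods against the
intercept-only null; "likelihood" is read as log-likelihood, the only
reading that keeps the statistic in its conventional range. Note that with
fractional outcomes a perfect fit attains the rows' entropy, not zero
log-likelihood, so pseudo-R² saturates below 1.

Bootstrap CIs resample (bee, day) rows with replacement (128 replicates,
percentile 95% CI of the paired score difference; a per-bee block bootstrap
is available for dependence-aware inference). The likelihood-ratio test uses
LR = 2(ℓ₁ − ℓ₀) against χ² with 4 df for the task model and 1 df for scalar
targets.

Future prediction fixes a 12-day training window, fits the CCA map and the
task model on those days only, and evaluates 1–11 days past the window;
per-day robust scaling of the evaluation day uses only that day's own
values, so nothing leaks backward. The persistence null carries the model's
prediction for the last training day forward to the same bees. A paired
binomial test counts rows where the model's squared error beats the null's.

Repeatability R = Var_p/(Var_i + Var_p) compares a bee's across-day variance
with the variance of daily mean network ages of an age-matched control group
(default span ± 1 day of biological age, configurable — the exact span is a
free choice). Trajectory clustering linearly inter-/extrapolates each bee's
daily series, then applies Ward agglomeration on Euclidean distances, cut at
k = 3. The per-day mode split uses exact 1-D 2-means (sorted-scan SSE
minimization — deterministic, and identical to k-means at its global
optimum); a separation score (between-cluster SS over total SS) flags days
that are actually bimodal, since 2-means always partitions.

## Synthetic colony generator

The generator emulates the statistical structure the pipeline assumes, with
full ground truth:

* **Development.** Each bee draws a cluster {early, late, none} (default
  probabilities 0.4/0.35/0.25) and a transition day (normal around 11 or 21
  days of age, sd 2 — values motivated by observed early/late developmental
  paths). The latent role ρ(b, t) follows a logistic curve in day-of-life
  with scale 2.5 days; "none" bees stay at ρ = 0. ρ is monotone by
  construction (reversions from forager-like to nurse-like roles are rare in
  real colonies and are left out by default).
* **Demography.** Staggered cohorts emerge from 4 weeks before recording
  through day 12 (so any focal day spans ages 0–6 weeks); lifespans are
  truncated-normal (mean 35, sd 15, ≥ 1 day).
* **Space.** Task mixtures over the four areas are fixed functions of ρ
  (nurses on brood, foragers on dance floor and exit, constant honey
  share). Positions follow a bounded walk: frames are assigned to areas in
  contiguous blocks drawn multinomially from the mixture, and each step
  moves toward a uniform target point inside the current (convex) area with
  step length v·min(Δt, 10 s) — bees move in short bouts, which keeps speed
  modulation visible at coarse frame spacing. Forager-like bees (ρ > 0.5)
  get a 24 h sinusoidal speed modulation peaking at 13:30 UTC.
* **Detection.** The camera images one comb side per frame (alternating);
  a bee is detected only on its side, with dropout (p = 0.8) and Beta(18, 1)
  confidences. After death (and before emergence) only false positives
  occur: Poisson(2/day), uniform over the comb, Beta(2, 5) confidences,
  flagged in a generator-only column. The generator emits 288 evenly spaced
  frames per day (one per 5 minutes) — enough for minute-sampled descriptors
  and velocity windows while keeping colony-scale runs tractable; the
  nominal 3 Hz rate remains the frame-grid constant for event detection in
  fine-grained runs.
* **Interactions.** Pairwise daily contact counts are Poisson with mean
  rate_max · exp(−(ρᵢ−ρⱼ)²/2σ²) (rate_max = 50 contacts/day for
  role-identical pairs, σ = 0.2 role units — strong but not degenerate role
  assortment); trophallaxis and the four directed effect modes draw at
  reduced rates from the same kernel, and mean distances grow linearly with
  role difference before the Gaussian/max-minus transforms.

What the generator does **not** emulate: comb geometry and cell contents,
pheromones, weather-driven foraging bouts, queen effects, non-monotone role
reversions, intraday network dynamics, and tag-decoding confusion between
specific ids. Passing tests therefore show the pipeline recovers planted
social structure of this kind; they do not certify performance on real
tracking data, where location-role coupling may be weaker and detection
artifacts richer.

### Problem sizes

The default study conditions are 200 bees over 25 days (≈ 3,400 bee-days;
96 factors). Death-date recovery uses 100 bees over 80 days with a
false-positive floor of 2% of the alive detection rate, and backend
agreement 20 bees; bootstrap comparisons use 128 replicates. These sizes
exercise every code path at full fidelity while keeping a complete run in
the minutes range on one CPU.

## Design choices where the design was open

* Per-day 2-means is applied to the pooled network-age distribution across
  cohorts.
* The orientation check compares mean biological age of the extreme
  percentile groups; only the first dimension is oriented.
* Sign alignment is applied per mode before concatenation.
* The trophallaxis stage-2 classifier is a pluggable callable (default:
  pass-through of the stage-1 logistic probability); the stage-1 gate is
  [0.731, 1.204] cm thorax distance, the head offset 3.19 mm along the body
  axis.
* A single missing frame breaks a proximity run (strict consecutive
  reading of the minimum-duration rule); co-detections on opposite comb
  sides never form proximity events.
* The Gaussian distance similarity includes the exponential,
  d′ = exp(−d²/2γ²): the only reading that yields a similarity in (0, 1].
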