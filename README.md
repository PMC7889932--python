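# netage

**Network age** is a one-dimensional descriptor of an individual's role in an
animal society, computed from its daily position in the group's multimodal
social interaction network. It was developed for fully tracked honey bee
colonies, where workers progress through tasks as they age (temporal
polyethism: nursing → food handling → foraging) but individuals of the same
biological age can occupy very different social roles. Network age makes that
functional position measurable per bee and per day, purely from who interacts
with whom.

The package is for behavioral ecologists and network scientists working with
long-term automated tracking data (honey bees, ants, or any system with
per-individual interaction records), and implements the full method plus a
synthetic colony generator with complete ground truth, so every stage can be
validated without field data.

## The method

For each day *t* and interaction mode *m* (proximity contacts, trophallaxis,
two transforms of mean pairwise distance, and four directed
speed-change-after-contact modes), a nonnegative affinity matrix
*A*⁽ᵐ'ᵗ⁾ is built over the bees alive that day, rank-transformed so that 0 is
the weakest and 1 the strongest affinity (ties share a rank). Each symmetric
matrix is embedded with Laplacian eigenmaps — the leading nontrivial
eigenvectors of *D*⁻¹ᐟ² *A* *D*⁻¹ᐟ², eight dimensions per mode — and each
directed matrix is co-embedded via SVD of the degree-normalized matrix
(bispectral decomposition, separate row and column coordinates). Eigenvector
signs are aligned across days by flipping a day when its Spearman correlation
with the previous day is negative. Concatenation yields per-bee daily
spectral factors **x**_{b,t} ∈ ℝ⁹⁶.

CCA then finds the linear map **w** maximizing the canonical correlation
between the pooled standardized factors and the 4-area task descriptor
(fractions of minute-sampled positions in brood, dance floor, honey storage
and exit areas). The first canonical variate, robust-scaled per day so the
5th/95th percentiles map to 0/40 (so 90% of values fall in [0, 40], a range
comparable to a worker's summer lifespan in days) and sign-oriented to
increase with biological age, is network age. A PCA variant needs no area
annotations, and *targeted embeddings* swap the task descriptor for any
scalar property (e.g. days until death).

Supporting models:

* **Lifetime**: a Bayesian changepoint model of per-bee daily detection
  counts. A bee is alive on days [*e*, *e* + *l*); normalized counts are
  thresholded at *t*, Bernoulli(*p*) while alive and Bernoulli(1 − *p*)
  after, with priors *l* ~ N(35, 50) truncated at 0, *p* ~ Beta(5, 1),
  *t* ~ Beta(25, 1). Death day = *e* + posterior mean of *l* (exact grid
  enumeration by default; a parallel-tempered Gibbs sampler as the MCMC
  backend).
* **Behavior metrics**: circadian power *P* = 1 − SSE_sine/SSE_constant of a
  fixed-frequency 24 h sinusoid fit to velocities over 3-day windows, time of
  peak activity, and mean day (09:00–18:00 UTC) / night (21:00–06:00 UTC)
  speeds.
* **Evaluation**: multinomial/binomial/Gaussian task-prediction models with
  McFadden's pseudo-R² = 1 − ℓ₁/ℓ₀, 128-replicate bootstrap CIs of paired
  score differences, likelihood-ratio χ² tests, a leakage-free
  future-prediction protocol with a persistence null, repeatability
  R = Var_p/(Var_i + Var_p), Ward clustering of developmental trajectories,
  and a per-day 2-means split of the bimodal network-age distribution.

## Worked example

```python
from netage import ColonyConfig
from netage.pipeline import run_colony_pipeline
from scipy.stats import spearmanr

config = ColonyConfig(n_bees=100, n_days=20, seed=42)
colony = run_colony_pipeline(config)
print(colony.results.summary())

merged = colony.network_age.merge(colony.ground_truth.roles, on=["bee_id", "day"])
rho = spearmanr(merged["network_age"], merged["role"]).statistic
print(f"\nSpearman(network age, latent role): {rho:.3f}")
```

prints

```
Network Age Results
==============================================
variant:            cca_task
components:         3
factor columns:     96
rows (bee, day):    1269
orientation sign:   -1
canonical corrs:    0.985, 0.000, 0.000
scaling:            per-day 5th pct -> 0, 95th pct -> 40
network age range:  [-0.66, 41.89]  median 2.36

Spearman(network age, latent role): 0.938
```

The simulated colony has 100 workers whose latent role ρ(b, t) ∈ [0, 1]
(0 = nurse-like, 1 = forager-like) drives their interactions; 1269 bee-days
received factors from the eight interaction modes. The first canonical
correlation (0.985) shows the factors carry nearly all the information in the
spatial task descriptor. The low median (2.4 on the 0–40 scale) reflects a
mostly nurse-like colony, and network age recovers the planted role ordering
with Spearman ρ = 0.94 — the interaction network alone suffices to read off
each bee's functional role.

The `netage` command exposes the same pipeline stage by stage
(`netage simulate | events | networks | embed | fit | transform | lifetimes |
evaluate`); see `netage --help`.

## Layout

```
src/netage/
  config.py        colony configuration for the synthetic generator
  simulate.py      age-structured colony simulator with ground truth
  trajectories.py  velocities, proximity events, trophallaxis stage 1,
                   interaction-effect records
  networks.py      daily affinity matrices and the rank transform
  embeddings.py    spectral/bispectral embeddings and sign alignment
  model.py         NetworkAgeModel / NetworkAgeResults (CCA, PCA, targeted)
  lifetime.py      LifetimeModel / LifetimeResults (Bayesian changepoint)
  behavior.py      task descriptor, circadian and velocity metrics
  evaluation.py    task models, bootstrap, LRT, future prediction,
                   repeatability, clustering, mode split
  pipeline.py      end-to-end colony -> network age pipelines
  cli.py           `netage` command-line interface
docs/methods.md    model assumptions, parameter choices, limitations
```
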