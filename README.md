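# topoccu

Topographic covariates and Bayesian multispecies occupancy models for
camera-trap surveys in terrain-structured landscapes.

Camera traps record which mammal species turn up where, but not which sites
a species actually *uses*: a species can be present and missed. In
mountainous terrain the interesting ecological questions — do floodplains
and gentle slopes concentrate the community? do rugged, sun-exposed slopes
shelter specialists? — therefore need a model that separates **occupancy**
(habitat use, ψ) from **detection** (p), with both allowed to respond to
terrain. `topoccu` provides the full pipeline:

1. **Terrain covariates** from a digital elevation model: slope and
   downslope aspect (Horn's 8-neighbour gradients), the Terrain Ruggedness
   Index (Riley), and clear-sky solar gain (Wh/m²) averaged over twelve
   monthly reference days; values extracted as 100 m buffer means per
   camera site and classified at Jenks natural breaks (exact dynamic
   programming).
2. **Detection histories** from timestamped capture records: consecutive
   records of a species at a site are collapsed into independent events
   with a rolling ≥ 30-minute rule, binned into five-day occasions tiled
   over each deployment, with per-occasion effort (camera-nights) carried
   along and zero-effort occasions masked. Species with more than five
   independent events enter the models; all species count toward richness.
3. **The multispecies occupancy model (MSOM)**, single season, for species
   *s*, site *i*, occasion *j*:

   ```
   z_is  ~ Bernoulli(ψ_is)             logit(ψ_is) = x_i' β_s
   y_ijs ~ Bernoulli(z_is · p_ijs)     logit(p_ijs) = w_ij' α_s
   ```

   with independent Normal(0, variance 1000) priors on all coefficients.
   By default one topographic variable is fitted at a time (intercept +
   class indicators; detection adds standardized log effort). Inference is
   Metropolis-within-Gibbs: exact draws of the latent `z`, adaptive
   per-species block random-walk updates for the coefficient vectors
   against the collapsed (z-marginalized) likelihood, and periodic
   prior-independence refresh steps. Convergence is checked with the
   Gelman–Rubin statistic; effects are *strongly* supported when the 95%
   equal-tailed credible interval excludes zero and *moderately* when only
   the 75% interval does.
4. **Community summaries**: the posterior of the across-species mean of ψ
   per terrain category, plus descriptive tallies (independent events,
   percentage per category, observed species richness).

A synthetic-data module generates DEMs, communities with known
coefficients, and burst-structured photo records, so the whole pipeline is
testable end to end without any field data.

## Worked example

```python
import numpy as np
from topoccu import (
    generate_landscape, make_truth, simulate_survey,
    filter_independent_events, build_detection_history, apply_species_inclusion,
    total_trap_nights, build_design, run_mcmc, MCMCConfig, psi_by_category,
)
from topoccu.community import community_occupancy
from topoccu.msom import psi_draws_for_category

grid, covs = generate_landscape(n_sites=40, seed=1)
truth = make_truth(covs, n_species=8, variable="ruggedness", seed=1)
records, deployments = simulate_survey(truth, covs, n_occasions=12)
print("trap-nights:", int(total_trap_nights(deployments)))

events = filter_independent_events(records, threshold_minutes=30)
print("records:", len(records), "-> independent events:", events.n_events)

included, excluded = apply_species_inclusion(events, min_events=5)
history = build_detection_history(events, deployments, occasion_length=5,
                                  species=included)
spec = build_design(covs, history, "ruggedness")
draws = run_mcmc(spec, history,
                 MCMCConfig(n_chains=3, n_iter=6000, n_burnin=3000, thin=3, seed=1))
print("max R-hat:", round(draws.max_rhat(), 3))

s = psi_by_category(draws, included[0], "low")
print(f"{included[0]} psi(low ruggedness) = {s['mean']:.2f} "
      f"[{s['q2.5']:.2f}, {s['q97.5']:.2f}]")
comm = community_occupancy(
    np.stack([psi_draws_for_category(draws, sp, "low") for sp in included]))
print(f"community psi(low ruggedness) = {comm['mean']:.2f} "
      f"[{comm['q2.5']:.2f}, {comm['q97.5']:.2f}]")
```

Output:

```
trap-nights: 2312
records: 2438 -> independent events: 957
max R-hat: 1.024
species_01 psi(low ruggedness) = 0.80 [0.58, 0.96]
community psi(low ruggedness) = 0.61 [0.48, 0.74]
```

The survey yielded 2,438 photos which the 30-minute rule collapses to 957
independent events. All chains agree (max R̂ = 1.024 ≤ 1.1). The first
species uses low-ruggedness sites with probability 0.80 (95% BCI
0.58–0.96), and the community as a whole — the across-species average ψ —
sits at 0.61 there.

The same pipeline runs from the shell on real inputs (a DEM as ESRI ASCII
grid, records and deployments as CSV):

```sh
topoccu --config config.yml covariates   # terrain covariates + class breaks
topoccu --config config.yml histories    # events, histories, inclusion rule
topoccu --config config.yml fit          # per-variable MSOMs, summaries, R-hat
topoccu --config config.yml report       # community/descriptive tables
```

`topoccu --config config.yml simulate` writes a complete synthetic input
set in the same formats.

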