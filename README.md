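# felidniche

Spatio-temporal niche-partitioning analysis for camera-trap surveys, built
around the question of how sympatric carnivores — the motivating system is
the Bornean felid guild (Sunda clouded leopard, bay cat, marbled cat,
leopard cat, flat-headed cat) — partition habitat, time and prey. It is
aimed at quantitative ecologists with a station table, a detection table and
a stack of environmental rasters.

Three analysis arms share a common detection-processing core (greedy 1-hour
independence filtering, station × species count matrices, detection
frequencies per 100 trap-nights, body-mass ratio tables):

1. **Multi-scale habitat modelling.** Each covariate is summarized by
   circular focal means at radii of 120–7680 m; a univariate logistic scan
   picks the radius with the lowest AIC per covariate; variables with
   univariate p > 0.2 are screened out and |Pearson r| > 0.7 pairs pruned to
   the lower-AIC member; the survivors enter an all-subsets logistic
   regression whose models are combined by Akaike weights
   w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2). Reported per term: the full-average
   coefficient β̄ = Σ w_i β_i, the unconditional SE
   √(Σ w_i [SE_i² + (β_i − β̄)²]), the relative importance Σ w_i over models
   containing the term, and a normal z/p. Occurrence surfaces apply
   p = e^z/(1+e^z) cell-wise.
2. **Temporal activity.** Detection clock times become angles on the 24-h
   circle; activity densities are von Mises kernel density estimates with
   the circular plug-in concentration
   κ* = [3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^{2/5}. Diel-period masses
   (dawn 05–07, day 07–17, dusk 17–19, night 19–05) and the coefficient of
   overlapping Δ = ∫ min(f, g) are computed, using the Δ₁ estimator when the
   smaller sample has < 75 records and Δ₄ otherwise, with smoothed-bootstrap
   confidence intervals and percentile-based classification of each felid's
   overlap profile across candidate species.
3. **Co-occurrence modelling.** Felid presence/absence per station modelled
   on raw candidate-prey detection counts (≥ 20 detections required) plus
   survey effort, through the same all-subsets averaging machinery.

A synthetic-data module generates autocorrelated landscapes, clustered
stations, detections, von Mises activity mixtures and multi-species
communities with known parameters, so the whole chain is testable without
survey data. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Published survey summaries for the Bornean felid guild travel with the
package and feed the arithmetic stages directly:

```python
import numpy as np
from felidniche.datasets import (survey_count_matrix, body_mass_means,
                                 infer_area_effort)
from felidniche.detections import body_mass_ratio_matrix, detection_frequency
from felidniche.synthetic import SyntheticConfig, simulate_activity_times
from felidniche.activity import fit_vonmises_kde, period_mass, DIEL_PERIODS
from felidniche.overlap_inference import smoothed_bootstrap_ci

totals = survey_count_matrix().sum(axis=0)
print(int(totals[["clouded_leopard_pooled", "leopard_cat", "bay_cat",
                  "marbled_cat", "flat_headed_cat"]].sum()))
# 2883       <- independent felid detections across the ten study areas

ratios = body_mass_ratio_matrix(body_mass_means()).ratios
print(ratios.loc["clouded_leopard_males", "bay_cat"])
# 8.7        <- heavier/lighter body-mass ratio of the pair

effort = infer_area_effort("danum_valley",
                           reference_species="clouded_leopard_pooled")
print(round(effort, 1), detection_frequency(39, effort))
# 9689.9 0.402   <- area trap-nights implied by one printed (count, rate)
#                   pair, reproducing the printed leopard-cat frequency

cfg = SyntheticConfig()
cat = simulate_activity_times("nocturnal", 400, cfg, seed=21)
deer = simulate_activity_times("diurnal", 250, cfg, seed=22)
night = period_mass(fit_vonmises_kde(cat), DIEL_PERIODS)["night"]["mass_pct"]
print(round(night, 1))
# 89.9       <- % of the nocturnal species' activity mass in 19:00-05:00

res = smoothed_bootstrap_ci(cat, deer, B=1000, seed=23)
print(f"{res.estimator}: {res.estimate:.3f} ({res.ci_low:.3f}-{res.ci_high:.3f})")
# Delta4: 0.074 (0.045-0.101)   <- nocturnal/diurnal pair barely overlaps
```

## Command-line pipeline

```sh
felidniche all --config config.yaml          # simulate -> habitat ->
                                             # activity -> overlap -> cooccur
felidniche habitat --config config.yaml --seed 7
```

One YAML config holds paths, the seven focal radii and every analysis
threshold; stages write CSV reports, ASCII-grid occurrence surfaces and a
provenance record (config hash, seed, filter survivor counts).

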