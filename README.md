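# relicdna

Simulators and bias statistics for the effect of **relic DNA** —
extracellular DNA and DNA in dead cells — on estimates of microbial
diversity.

DNA-based community surveys sequence the *total* DNA pool: DNA from intact
(viable) cells plus relic DNA left behind by death. Whether that matters
for diversity estimation depends on two things: how large the relic pool
is, and whether its species abundance distribution (SAD) differs from the
intact pool's. This package is for microbial ecologists who want to
simulate those conditions, and to quantify relic-DNA bias in paired
DNase-treated (intact) / untreated (total) sample designs.

It provides:

* **`relicdna.communities`** — lognormal regional species pools (scale
  parameter σ controls evenness) and multinomial community sampling.
* **`relicdna.sampling_model`** — mix intact and relic communities at a
  controlled relic fraction f, rarefy, and measure richness ratios
  S_total/S_intact and Bray–Curtis dissimilarity.
* **`relicdna.process_model`** — a stochastic per-step model: immigration
  (j individuals), birth (I·b), death (I·m + j individuals moved to the
  relic pool), degradation (R·d + j individuals removed), with neutral,
  protection (per-species susceptibilities ~ beta(0.7, 0.7)) and hot-spot
  (abundance-weighted removal) degradation scenarios. Closed forms: the
  relic pool equilibrates at R = m·I/d, so a target relic proportion p is
  reached with d = m/p − m; τ = R/d.
* **`relicdna.bias_metrics`** — relic proportion 1 − intact/total from
  qPCR copy numbers, resampled richness and Simpson's evenness
  (E = (1/Σp²)/S_obs) with total/intact ratios ± SEM, two-sample
  Kolmogorov–Smirnov SAD comparison, and PCoA centroid-distance ratios
  (paired beta-dispersion: > 1 relic DNA inflates beta-diversity,
  < 1 it homogenizes).
* **`relicdna.fixtures`** — synthetic paired intact/total OTU tables with
  known ground truth (mixing fractions, noiseless qPCR copies) for
  validating every statistic without any external data.

See `docs/methods.md` for the models, their assumptions, and numerical
choices.

## Worked example

Run the process model at its reference configuration (4,000-species pool,
intact community of 20,000, j = 2,000, b = m = 0.1) with the decay rate
chosen for an 80% relic pool, under each degradation scenario:

```python
from relicdna import (ProcessParams, ScenarioSpec, bias_from_simulation,
                      decay_rate_for_target, equilibrium_relic_size,
                      run_process_simulation)

d = decay_rate_for_target(0.1, 0.8)           # 0.025
print("predicted equilibrium R:", equilibrium_relic_size(0.1, 20_000, d))

for kind in ("neutral", "protection", "hotspot"):
    rec = run_process_simulation(
        ProcessParams(decay_rate=d, n_steps=2_000, seed=42,
                      scenario=ScenarioSpec(kind=kind))
    )
    bias = bias_from_simulation(rec, seed=43)
    print(f"{kind:10s} relic proportion {rec.tail_relic_proportion:.3f} "
          f"richness ratio {bias['richness_ratio']:.3f} "
          f"Bray-Curtis {bias['bray_curtis']:.3f}")
```

prints

```
predicted equilibrium R: 80000.00000000001
neutral    relic proportion 0.800 richness ratio 1.038 Bray-Curtis 0.292
protection relic proportion 0.800 richness ratio 0.605 Bray-Curtis 0.704
hotspot    relic proportion 0.800 richness ratio 1.234 Bray-Curtis 0.351
```

Every scenario settles at the targeted 80% relic proportion, but only the
SAD-distorting scenarios bias diversity: neutral degradation leaves the
richness ratio ≈ 1 (relic and intact SADs match), protection makes the
relic SAD less even and *underestimates* richness by ~40%, and hot-spot
degradation makes it more even and *overestimates* richness by ~23%. The
Bray–Curtis column shows how far the total pool's composition drifts from
the intact community's.

The same models are available from the shell:

```sh
relicdna process-sim --scenario hotspot --target-proportions 0.8 \
    --steps 2000 --replicates 10 --seed 1 --out hotspot.tsv
relicdna sampling-sweep --seed 1 --out sweep.tsv
relicdna make-fixture --seed 1 --otu-table otu.tsv \
    --sample-sheet samples.tsv --truth truth.tsv
relicdna empirical-bias --otu-table otu.tsv --sample-sheet samples.tsv \
    --depth 10000 --seed 1 --out bias.tsv --centroid-out centroid.tsv
```

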