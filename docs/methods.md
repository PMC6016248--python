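# Methods

## The problem

Cultivation-independent surveys of microbial communities sequence whatever
DNA a sample yields. Part of that DNA is *relic* DNA — extracellular
molecules and DNA inside dead cells left behind when organisms die — and
part is *intact* DNA from viable cells. If the species abundance
distribution (SAD) of the relic pool differs from that of the intact pool,
sampling reads from the combined (total) pool biases diversity estimates.
This package implements two complementary models of that mixture, the
statistics used to quantify the resulting bias, and a synthetic generator
of paired DNase-treated (intact) / untreated (total) samples.

## Sampling model (`relicdna.sampling_model`)

Intact and relic communities are drawn from lognormal regional pools.
A pool over S species holds weights w_i ∝ exp(σ·Z_i), Z_i ~ N(0,1),
normalized to sum to 1; the location parameter is irrelevant after
normalization, so σ is the single evenness knob (σ = 0 is perfectly even;
larger σ concentrates abundance). A community of N individuals is one
multinomial draw with the pool's weights.

`mix_communities` draws round((1−f)·N_total) individuals without
replacement from the intact community and round(f·N_total) from the relic
community (half-away-from-zero rounding; the realized fraction is recorded
because the two roundings need not hit f exactly). The total is rarefied —
subsampled without replacement via a multivariate hypergeometric draw — to
a fixed depth, and bias is summarized as

* richness ratio = S_obs(rarefied total) / S_obs(rarefied intact), both at
  the same depth and with a shared rarefaction seed (identical inputs give
  exactly 1);
* Bray–Curtis dissimilarity of the rarefied total vs intact pools.

Reference configuration: S = 10,000 species, intact community of 10^6
individuals, intact σ = 0.98, relic σ ∈ {0.25, 0.98, 1.8}, mixing fractions
0.01–0.96, rarefaction depth 10,000. The relic community is sampled at the
same size as the intact one from its own pool (only proportions matter
downstream); when σ_relic = σ_intact the two communities share one pool
object, which is the no-bias control. Order of operations is mix first,
then rarefy.

Behaviour: a shared SAD gives a ratio of 1 at every mixing fraction; a more
even relic SAD (σ = 0.25) inflates richness and a less even one (σ = 1.8)
deflates it, with |ratio − 1| growing with the relic fraction. Near a pure
relic mixture the detected richness saturates, so the magnitude plateaus at
the highest fractions; trend checks across the full range should therefore
use a slope statistic rather than strict ordering of adjacent means.

## Process model (`relicdna.process_model`)

A stochastic individual-based model tracked at species resolution. State is
an intact community I and a relic pool R over a shared S-species lognormal
regional pool (σ = 0.98 by default; the sampling model's base value).
Each time step applies, in order:

1. **immigration** — j individuals drawn with replacement from the regional
   pool join the intact community (optionally, a binomial fraction of them
   dies on arrival straight into the relic pool — the poorly-adapted-
   immigrant mode, default off);
2. **birth** — round(I·b) parents drawn with replacement (probability ∝
   abundance) are duplicated;
3. **death** — round(I·m) + j individuals drawn without replacement
   (multivariate hypergeometric) move from intact to relic;
4. **degradation** — round(R·d) + j individuals are removed from the relic
   pool.

The "+j" terms offset immigration so that with b = m the intact community
is stationary. For this to hold the per-capita rates must refer to a single
census: all three counts use the community sizes at the *start* of the step
(`base_size`). Applying them to the running post-immigration/post-birth
sizes instead makes the correction insufficient and the intact community
drains at ≈ I/100 + j/100 individuals per step until it collapses, and the
relic pool equilibrates away from its closed form.

At stationarity the relic balance d·R = m·I gives R* = m·I/d, so a target
relic proportion p = R/(R+I) is reached by d = m/p − m. For small p this
exceeds 1 (p = 0.05, m = 0.1 → d = 1.9); rates above 1 simply mean the pool
turns over faster than once per step and are accepted. During the early
transient at high d, the requested removal (R·d + j) can exceed the pool;
the driver caps removals at the current pool size, which is inert at
equilibrium. The residence quantity τ = R/d is provided verbatim; note it
is dimensionally pool-size × time (a conventional per-capita residence time
would be 1/d).

Degradation scenarios:

* **neutral** — uniform removal (multivariate hypergeometric). The relic
  SAD then tracks the intact SAD and richness ratios stay ≈ 1 at every
  equilibrium proportion. A small residual inflation (≲ 5% at p = 0.9)
  remains because the relic pool integrates a rolling ~1/d-step window of
  death events: temporal averaging smooths snapshot sampling noise and
  retains transient rare species slightly better than any single intact
  census, a property of the model rather than an artifact.
* **protection** — each species gets a degradation susceptibility
  w_s ~ beta(0.7, 0.7), drawn once per run. The U-shape means most species
  are either well protected or fully exposed. Removal probability per
  individual ∝ w_s; protected species accumulate, the relic SAD becomes
  less even, and the total-pool richness is underestimated (ratios ≈ 0.6
  at p = 0.8).
* **hotspot** — removal probability per individual ∝ its species abundance
  (species-level rate ∝ n_s²), mimicking density-dependent degradation in
  structured habitats. Abundant species degrade faster, the relic SAD
  becomes more even, and richness is overestimated (ratios ≈ 1.2 at
  p = 0.8).

Weighted removal is implemented as species-level multinomial batches with
probabilities ∝ n_s·w_s (protection) or n_s² (hotspot), truncated so no
species loses more than it has, with the remainder redrawn from surviving
capacity; this is equivalent to sequential per-individual weighted sampling
at these scales and far faster. If only zero-weight species remain the
residue is removed uniformly (unreachable with beta-distributed weights,
which are almost surely positive).

Bias from a finished run compares total = intact + relic against intact at
a rarefaction depth of min(final intact size, final total size, 10,000),
with a shared rarefaction seed.

Run lengths: the reference runs here use 2,000 steps. The relic pool's
relaxation time is 1/d steps, so 2,000 steps is ≥ 10 relaxation times for
every proportion scanned (p ≥ 0.1); equilibrium statistics average the
final 10% of steps. Runtime is a few seconds per run at S = 4,000,
I₀ = 20,000 on one CPU.

## Bias statistics (`relicdna.bias_metrics`)

* **Relic proportion** = 1 − intact/total from 16S qPCR copy numbers,
  clipped to [0, 1] (assay noise can put intact above total).
* **Resampled alpha diversity** — repeated rarefaction at a fixed depth
  (study convention: 30,000 observations, 1 + 999 resamples), reporting
  mean ± SEM of observed richness or Simpson's evenness
  E = (1/Σp_i²)/S_obs (inverse-Simpson over observed richness; the
  standard ecological definition). Per-sample **diversity ratios**
  (total/intact) carry a first-order (delta-method) SEM.
* **SAD comparison** — two-sample Kolmogorov–Smirnov test on the nonzero
  relative abundances of each pool (absent taxa contribute nothing; the
  zero-handling is this package's documented choice).
* **PCoA / centroid-distance ratios** — all 2n profiles (n totals, n paired
  intacts) are ordinated together by classical metric MDS on Bray–Curtis
  distances of log-transformed relative abundances; the group centroid is
  the mean of the *total* samples' coordinates, and each site's ratio is
  its total sample's Euclidean distance to that centroid over its intact
  sample's distance. Ratios > 1 mean relic DNA inflates beta-diversity,
  < 1 that it homogenizes. Axes with non-positive eigenvalues are dropped
  (warned when the negative part is non-trivial). The log transform is
  log10((x + c)/c) with c the smallest nonzero relative abundance in the
  table — a monotone-equivalent, non-negative form of log10(x + c) chosen
  because Bray–Curtis requires non-negative input; c is deterministic given
  the table.

Two statistical properties of the centroid-distance estimator worth knowing:
the centroid is fitted to the n total samples, so under a pure-noise null
with *independent* pairs the expected ratio is √((n−1)/(n+1)) < 1; and
mixing relic DNA drawn from a pool shared across sites genuinely pulls
totals together (homogenization). The ratio sits at 1 under the null only
when paired samples are compositionally coupled — which is exactly the
situation the paired DNase design produces when relic DNA derives from the
local community (see the fixture's `relic_source="site"` mode).

## Synthetic paired samples (`relicdna.fixtures`)

Per site: an intact community (default 100,000 individuals) from a
lognormal pool; a relic community either from a relic regional pool
(`relic_source="regional"`, default — independent of the site, the
homogenizing case) or resampled from the site's own intact community
(`relic_source="site"` — relic from local neutral death, the no-bias null);
a total community mixed at the site's relic fraction; sequencing emulated
as multinomial read draws (default depth 50,000) from the intact and total
relative abundances; qPCR copies as a linear copies-per-individual readout
(scale 1.0 — only ratios matter) with multiplicative lognormal noise of
CV 0.16, a realistic assay CV (CV 0 recovers the realized mixing fraction
exactly). Ground truth (realized fractions, noiseless copies) is returned
alongside.

What the fixtures do *not* emulate: primer/extraction bias, chimeras,
OTU-clustering artifacts, phylogenetic structure, overdispersed (non-
multinomial) sequencing noise, or cross-ecosystem composition differences.
Tests passing on fixtures therefore validate the statistics' behaviour
under the stated sampling model, not robustness to those real-data
features.

## Numerical choices and edge cases

* All randomness flows through `numpy.random.Generator`; every stochastic
  function takes a seed or generator, and composite runs derive child seeds
  (< 2³¹) from their own generator. Identical seeds give bit-identical
  results.
* Fractional head-counts are rounded half away from zero.
* Ratio denominators of zero (empty intact pool, zero total copies,
  zero intact centroid distance) raise or flag NaN rather than propagate
  infinities; the centroid mean excludes flagged samples.
* Pools reject weights that fail normalization by more than 1e-9;
  communities reject negative or fractional counts.
* Degenerate inputs (zero-size draws, σ = 0 pools, single-species
  communities) are exercised in the test suite.

## Known limitations

* The process model is not spatially explicit; hot spots enter only
  through density-dependent removal weights.
* Phylogenetic (UniFrac-type) distances are consumed only as precomputed
  matrices; no trees are built and no phylogenetic alpha-diversity is
  computed.
* The sampling model's mixing grid spacing and the process model's
  rarefaction depth are configuration choices, not fixed by theory.
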