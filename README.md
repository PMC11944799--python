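# rarecycle

Soil microbial communities split into *abundant* taxa (mean relative
abundance > 0.05%) and *rare* taxa (< 0.001%), and the two tails play
different roles in nutrient cycling. `rarecycle` is a tested, reusable
implementation of the analysis chain used to ask how rare and abundant
sub-communities relate to a soil **multi-nutrient cycling index (MNC)**
across crop types in saline cropland: taxa partitioning, diversity and
permutation statistics, MNC computation, thresholded co-occurrence networks
with topology and robustness, a recursive path model, and random-forest
permutation importance — all exercisable end-to-end on a bundled seeded
synthetic-data generator, with no external downloads.

It is written for microbial ecologists who have an OTU count table
(samples × OTUs with taxonomy), per-sample soil chemistry, and a grouping
factor (here: crop type), and who want the full pipeline reproducible from
one config and one seed.

## The quantities at the core

- **Partition.** An OTU is *abundant* iff its mean relative abundance across
  samples exceeds 5·10⁻⁴, *rare* iff below 10⁻⁵; the remainder is
  *intermediate* and belongs to neither sub-community.
- **MNC.** Each of seven nutrient variables (SOC, TN, TP, TK, Olsen-P,
  Avail-K, NO₃⁻-N) is min-max normalized over all samples jointly,
  `N_or = (X − X_min)/(X_max − X_min)`, and the per-sample index is
  `MNC = (1/n) Σᵢ N_or,i` — a unit-free score in [0, 1].
- **Diversity.** Richness, Shannon `H = −Σ p ln p` (nats) and Pielou
  `J = H / ln S`; Bray–Curtis dissimilarity, non-metric MDS (Kruskal
  stress-1), PERMANOVA (pseudo-F, R², 999 permutations), Mantel tests,
  Kruskal–Wallis, and Duncan's multiple range test with connected letters.
- **Networks.** Per crop and kingdom: keep the top 80% of OTUs by mean
  relative abundance, retain OTU pairs with Spearman |r| > 0.60 and
  p < 0.05 as signed weighted edges, then summarize 17 topology metrics
  (degree, density, Louvain modularity, clustering, assortativity, path
  lengths, positive/negative edge fractions, …) plus *robustness*: the mean
  relative size of the largest connected component after randomly removing
  50% of nodes.
- **Drivers.** A recursive path model on standardized observed variables,
  `salt → {rare/abundant × bacterial/fungal Shannon} → MNC`, estimated by
  per-equation OLS with ML fit statistics (χ²/df, RMSEA); and regression
  forests ranking the seven MNC nutrients by out-of-bag permutation
  importance (%IncMSE) for rare-taxa Shannon diversity.

The synthetic generator emulates the study design the pipeline targets:
41 plots in four crop groups (soybean 10, cotton 11, sorghum 5, maize 15),
per-crop nutrient means/SDs, lognormal species-abundance distributions
populating both classification tails, and a planted causal chain with
standardized effects +0.40 (salt → rare bacterial Shannon), −0.31 (rare
bacterial Shannon → MNC) and +0.47 (rare fungal Shannon → MNC), recorded in
a `truth.json` for parameter-recovery testing.

## Worked example

```bash
python analysis/01_simulate.py   # seeded synthetic study -> results/data/
python analysis/04_mnc.py        # MNC + Duncan letters  -> results/mnc/
python analysis/06_drivers.py    # path model + forests  -> results/drivers/
```

`04_mnc.py` prints the per-crop MNC means with Duncan letters:

```
per-crop MNC means with Duncan letters:
         mean   n letters
sorghum 0.737   5       a
maize   0.629  15       a
cotton  0.395  11       b
soybean 0.291  10       b
```

sorghum plots carry the highest nutrient-cycling index and separate
significantly (different letters) from cotton and soybean. `06_drivers.py`
prints the fitted path model next to the generator's planted truth:

```
  salt -> rare_bact_shannon: +0.162 (p=0.312)  planted +0.40
  rare_bact_shannon -> MNC: -0.238 (p=0.107)  planted -0.31
  rare_fung_shannon -> MNC: +0.464 (p=0.006)  planted +0.47
  chi2/df = 1.73, RMSEA = 0.135
random forest (fungi): top predictors NO3_N (29.2%), TN (20.9%), TK (11.5%)
```

At the study's n = 41 the coefficients are noisy (±0.15 standard error);
the test suite verifies that at n ≈ 500 each planted coefficient is
recovered within ±0.1 across 20 seeds. The full pipeline (every stage, one
seed, one report) runs with

```bash
rarecycle run --out pipeline_out --seed 42
```

and is byte-reproducible: the same config and seed give an identical
`report.json` hash.

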