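# Methods

This note documents the statistical procedures, the synthetic data model
behind the test suite, the defaults that matter, and the known limitations.
It states nothing the tests or `scripts/acceptance.py` do not themselves
compute.

## Analysis pipeline

### Profiles

Counts are first restricted to genes that are taxonomically classified AND
functionally classified (a KO or a CAZy family): comparative analyses on
mixed classified/unclassified sets would conflate annotation coverage with
biology. Gene-level abundance is reads per kilobase (RPK = count /
(length_bp/1000)) rescaled per station to counts per million (CPM), so every
station column sums to 10⁶ exactly. KO / taxon / CAZy profiles are sums of
member-gene **CPM** values (not raw counts — summing counts would
re-introduce gene-length bias across taxa with different mean gene lengths),
re-normalised to 10⁶ afterwards so each level is again a CPM profile. The
re-normalisation after aggregation is this package's choice; both the
pre-rescale conservation identity and the post-rescale column sums are
asserted in the test suite. Stations with zero reads are kept as all-zero
columns with a warning and excluded from dissimilarity analyses.

### Diversity

Rarefaction draws a fixed number of reads without replacement per station
(multivariate hypergeometric) — the standard ecology semantics under which
subsampling can only lose features. Richness and Shannon entropy (natural
log; the conventional unit when no base is specified) are averaged over 99
replicate draws. The default depth is the minimum station total, so every
station qualifies at this data scale; any fixed depth can be passed instead.
The Pearson correlation of mean richness with total mapped reads is the
standard check that diversity patterns are not a sequencing-depth artifact.

### Biogeographic clustering

Bray–Curtis dissimilarities between station columns of the unrarefied CPM
profiles feed Ward.D2 agglomeration: `scipy`'s `linkage(..., "ward")` on the
condensed dissimilarity vector, which applies the Lance–Williams update with
squaring inside the criterion — identical to R's `hclust(method="ward.D2")`
on the same input. The test suite verifies it against a from-scratch naive
Lance–Williams implementation. The cluster number maximises the mean
silhouette width computed directly on the dissimilarities (no embedding);
singleton clusters score 0 by the standard convention, ties resolve to the
smallest k, and a cut that fails to split (all-tied dissimilarities)
likewise scores 0.

Cluster validation compares, per cluster, within-cluster pairwise
dissimilarities against member-to-outgroup dissimilarities with a
tie-corrected Kruskal–Wallis test. Pairwise dissimilarities sharing stations
are not independent, so this test is descriptive rather than exactly
calibrated; the suite checks only that it is strongly significant for
planted structure and not systematically significant for random labels.

Missing environmental covariates are linearly interpolated against transect
order with nearest-value edge filling. Provinces are Ward clusters of
Euclidean distances over z-scored latitude, longitude, temperature, salinity
and chlorophyll a (the standardisation is this package's choice). The
random-forest explanation fits a seeded classifier (default 500 trees) of
cluster labels on temperature, salinity, chla, POC, nitrate, phosphate and
one-hot province (importances of the province dummies are summed back into
one entry); it reports impurity-decrease importances normalised to sum 1 and
out-of-bag accuracy. With ~22 stations OOB accuracy is a coarse statistic;
the planted-signal recovery test therefore uses 30 samples with labels
determined by a temperature threshold and all other covariates pure noise.

### Distance decay

Ordinary least squares of upper-triangle Bray–Curtis dissimilarities on
upper-triangle great-circle distances (haversine on a 6371-km sphere) and on
absolute temperature differences, one fit per profile level and predictor.
A linear model on pairs ignores pair non-independence — that is the standard
descriptive distance-decay regression; a Mantel permutation p-value is
available as a clearly-labelled optional extra. Distance slopes are reported
per km and per 1000 km.

### Thermal niches

A feature's occupancy thermal range is the spread of ambient temperatures
over stations where its abundance reaches at least `frac` (default 0.15) of
its maximum. The statistic is invariant to positive rescaling of the
abundance vector, so the choice of CPM as input is immaterial per feature.
Variants are distinct catalog genes sharing a (taxon_id, ko_id) pair; pairs
enter the analysis when at least `min_variants` variants have nonzero
abundance (zero-abundance variants count toward neither the filter nor the
output). The default `min_variants=10` matches the convention for
catalog-scale data; at the synthetic default of 8 variants per pair the
analyses pass `min_variants=8` explicitly, otherwise no pair can qualify.
Taxon-level rows use the taxon-aggregated profile with the same occupancy
fraction. Summaries (mean, sd, median, IQR) group variants by source taxon
or by BRITE functional category; variants without a BRITE annotation are
excluded with a logged count.

### CAZyme thermal response

CAZy-family-aggregated CPM profiles are min–max scaled to [0, 1] per family
and fit with a Gaussian temperature response a·exp(−(T−μ)²/(2σ²)) + c by
least squares with grid-seeded starts (μ over the observed temperature
range, σ ∈ {2, 5, 10} °C); a concave quadratic is available as an
alternative model and the model used is recorded in the output. Significance
is an F-test against the intercept-only model with Benjamini–Hochberg
adjustment (gate q ≤ 0.05). Because the reported fit is the best of a grid
of nonlinear starts, the null p-value distribution is only approximately
uniform; the suite checks that the 5 % null rejection rate stays near
nominal and that the BH gate controls discoveries under a global null.
Fitted optima outside the observed temperature range (monotone profiles) are
clipped to it and flagged. Significant families are clustered by complete
linkage on Euclidean distances of their normalised profiles (default k = 3,
configurable), and each cluster's mean profile is refit.

### Differential abundance

A deliberately simplified DESeq2-style negative-binomial Wald test on raw
counts aggregated to KO or CAZy level (count models need counts; CPM is not
reused here): median-of-ratios size factors (geometric means over features
with no zero count); per-feature method-of-moments dispersion solving
var(q) = mean(q)/sf + α·mean(q)² on normalized counts with pooled
within-group variance, floored at 10⁻⁸; log₂ fold change on normalized group
means with a 0.5 pseudo-count, computed as a difference of logarithms so a
label swap negates it exactly; delta-method standard error and a two-sided
normal p-value. There is no dispersion shrinkage, fold-change moderation or
outlier filtering, so the test is slightly liberal at small sample sizes
(simulated type-I ≈ 0.06–0.08 at nominal 0.05 with 8+8 samples); calibration
is established by simulation, not by agreement with any external tool.
Fold-change bins for significant features: 0–2 no or weak difference, 2–4
intermediate, > 4 strong; non-significant features always bin as "none".

## Synthetic transect generator

The generator is the test bed: it emulates the statistical shape of a
basin-scale surface-ocean metagenomic survey and returns the planted truth.
It is a stand-in — no claim is made that it is a fitted model of any real
data set.

**Stations.** Latitudes evenly spaced over (−62°, 47°); temperature is a
smooth unimodal function of latitude peaking near the equator with
asymmetric arms (southern end ~1 °C polar water, northern end ~12 °C
temperate drift water), spanning ≈ 1–28 °C, plus 0.3 °C measurement noise.
Chlorophyll a and POC rise toward temperate/high latitudes; annual-mean
nitrate and phosphate are anti-correlated with temperature but carry
substantial (≈ 30 %) multiplicative noise because they represent
climatological means, not same-day measurements — this decoupling is what
lets a random forest separate the true thermal driver from its nutrient
proxy. A survey-style pattern of missing covariate entries (chla 1, POC 2,
nitrate 4, phosphate 2) exercises interpolation.

**Taxa and regimes.** 50 taxa are split round-robin over three thermal
regimes (centers 4 / 14.5 / 25 °C, within-regime center sd 1.8 °C). Each
taxon has a Gaussian temperature envelope with width σ_t ~ U(3, 13) °C plus
a cosmopolitan floor ~ U(0.35, 0.9) of peak (taxa do not vanish outside
their niche), a latitude affinity (Gaussian, σ = 80°), and a regime affinity
damping it to 0.75 outside its own regime — partial, not total, regional
turnover, as real provinces show. Baselines are lognormal(0, 0.5) scaled by
the square root of relative niche breadth: generalists dominate, which is
what makes gene-level turnover outrun taxon-level turnover, as in real
basins where the dominant clades span the gradient.

**Variants.** Each KO is carried by ≈ 35 % of the taxa, stratified so every
regime contributes at least two carriers — the planted functional
redundancy. Every (taxon, KO) pair carries 8 variants with sub-niche widths
σ_v = 0.3 σ_t (nested within ± 2 σ_t of the taxon center by construction)
and optima spread evenly over the niche core intersected with the sampled
0.5–28.5 °C domain. Each variant also has a latitude ecotype preference
(Gaussian, σ = 30°) centered on a randomly chosen hemisphere branch of the
temperature curve where its optimum occurs — ecotypes evolve in situ, and
this is what breaks the hemispheric thermal mirror so that geographic
distance decay exists at all levels — plus a small cosmopolitan floor
~ U(0.01, 0.05) of peak.

**CAZy guilds and annotation loss.** 5 % of genes get one of 18 CAZy
families whose planted optima sit on a 3 / 15 / 25 °C grid, with genes
joining the family nearest their own optimum (a 2 °C assignment kernel).
The 5 % is a deliberate scale-up of the real catalog's sub-percent CAZyme
fraction: at ~6 000 genes the family-level analysis would otherwise be
empty. 30 % of genes lose taxon and/or KO labels in the catalog (the truth
keeps them), emulating incomplete annotation.

**Sampling.** Expected relative abundance of a gene at a station is
baseline × regime affinity × latitude affinity × envelope × variant
response × gene length (length emulates read mapping, so RPK normalisation
is exercised non-trivially); counts are multinomial with 2 × 10⁵ reads per
station, so column sums are exact and all randomness derives from one seed.

**What it does not emulate.** No sequence content, no read-level errors, no
assembly or annotation artifacts, no co-varying nutrient limitation or
seasonal dynamics, no compositional interactions between taxa beyond the
shared multinomial. Passing tests demonstrate that the analysis code
recovers planted structure of this kind at this scale — not that real data
contain such structure.

## Known limitations

- **Occupancy-range width recovery is resolution-limited.** The rank
  correlation between estimated variant ranges and planted sub-niche spans
  reaches ≈ 0.5–0.65 at the default scale, and a noise-free oracle (the same
  estimator on expected counts) caps near 0.66 — ranges of variants with
  optima near the 1–28 °C domain edges are truncated, and 22 stations
  resolve temperature only to 1.3–2.5 °C. The estimator is unbiased about
  *which* features are narrow or wide on mid-domain optima (oracle ≈ 0.76
  there) but cannot rank-resolve spans comparable to the sampled domain.
- The Kruskal–Wallis cluster validation and the pairwise OLS decay fits
  ignore the dependence between station pairs (deliberately, as descriptive
  statistics).
- The differential test is intentionally minimal; for real inference at
  small n a shrinkage estimator (e.g. DESeq2 proper) should replace it.
- OOB accuracy of the cluster-explanation forest is noisy below ~30
  stations; importances are more stable than accuracy there.
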