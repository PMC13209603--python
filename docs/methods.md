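# Methods

This note documents the statistical procedures, the tunable parameters
and their defaults, what the synthetic generators emulate (and do not),
and the numerical conventions the implementation pins down.

## Feature scoring

A functional feature is the summed relative abundance of a declared
genus set; matching is case-insensitive and exact (no fuzzy matching —
a silent mis-aggregation is worse than a logged warning, which is what a
member genus missing from the table produces). Descriptor features are
the Shannon index (base 2 by default, the upstream amplicon toolchain's
convention; natural log selectable) and phylum ratios
(Bacillota/Bacteroidota shipped). A zero denominator in a phylum ratio
yields a flagged infinity that is excluded from reference fitting and
classified at the flagged (high) extreme rather than crashing.

Of the 32 shipped features, only the methane genus set
(Methanosphaera, Methanobrevibacter, Methanobacterium, Methanosarcina,
Methanococcus, Methanospirillum) and the pathogen screen
(Clostridioides, Enterococcus, Klebsiella, Morganella, Salmonella,
Shigella) are authoritative; the other rosters are literature-plausible
editorial placeholders, shipped as editable YAML so a curated
configuration can replace them without code changes. Which features
count as beneficial (flagged when scarce) versus prejudicial (flagged
when excessive) is likewise configuration; the shipped defaults are
editorial except where the flagging direction is unambiguous (e.g.
lipid degraders are flagged in excess).

## Depth normalization

Counts are normalized to the depth of the shallowest sample. The
published description ("a standard of sequence number corresponding to
the sample with the fewest sequences") is ambiguous between rarefaction
and rescaling, so both are implemented: `subsample` (default) draws
without replacement via the multivariate hypergeometric distribution —
standard practice for amplicon counts and support-preserving by
construction — and `rescale` multiplies and rounds with
largest-remainder correction so row sums match exactly, breaking
remainder ties by genus name for determinism.

## Reference fitting and classification

Per feature, the reference law is a fitted normal when Shapiro–Wilk
does not reject normality at α = 0.05, otherwise the empirical CDF;
both can be forced. Empirical percentiles use midpoint ranks,
`100·(#below + ½·#equal)/n`, which keeps in-range values off the 0/100
boundaries. Fitting requires at least 20 finite values (percentiles are
unstable below that) and rejects constant references.

Classification intervals: moderate = [2.5, 25] (beneficial) or
[75, 97.5] (prejudicial); high = [0, 2.5) or (97.5, 100]. The printed
bands share endpoints, so a convention is required: interval endpoints
(2.5, 25, 75, 97.5) belong to the **moderate** band. This is pinned by
tests. Only one tail is flagged per feature by default; a `both` policy
(union of the two rules, severity maximum at overlaps) exists for
features where either extreme is meaningful, and `none` marks purely
informational features.

Reference cohorts are screened for outliers before fitting: samples
whose first-two-principal-component scores (each axis standardized by
its own SD) lie more than `k_sd` = 3 units from the centroid are
dropped. The published pipeline states only that PCA was used to remove
outliers; the two-component, 3-SD rule is this package's declared
default, not a reconstruction. Under a Gaussian cloud about 1% of
samples exceed the cutoff, so a homogeneous reference loses at most a
sample or two; removing more than 20% is treated as a batch problem and
requires an explicit override. Whether normalization precedes outlier
screening is configurable; the default is normalize first.

## Cohort statistics

Prevalence counts moderate and high calls together, ranked descending
with alphabetical tie-break. Two binomial CIs are implemented: plain
Wald and the modified Wald (Agresti–Coull) interval
`p̃ ± z√(p̃(1−p̃)/(n+4))`, `p̃ = (x+2)/(n+4)`, both clamped to [0, 1]
with z = 1.959964 at 95%. The source analysis cites the modified Wald
method, but every printed interval it reports is reproduced exactly
(to one decimal in percent, at n = 200) by the *plain* Wald formula and
not by the modified one; the reproduction tests therefore use `wald`,
and both methods remain available. One printed interval triple
(29.3–42.7 attached to three different proportions) is arithmetically
inconsistent and treated as a copy error, excluded from reproduction.

Clustering standardizes feature columns (constant columns dropped),
applies Ward's minimum-variance linkage to Euclidean distances, and
selects k among the candidates by silhouette; Calinski–Harabasz and
Dunn (minimum between-cluster distance over maximum cluster diameter)
are computed on the same scaled matrix and disagreements are logged —
the published analysis validated all three indices without stating an
arbitration rule, so silhouette arbitrates here. Cluster separation is
tested by PERMANOVA on the same distances.

PERMANOVA uses the distance sum-of-squares partition
(R² = SS_among/SS_total, pseudo-F = (SS_among/(k−1))/(SS_within/(N−k)));
the permutation p-value comes from scikit-bio with the add-one
convention `(1 + #{F_perm ≥ F_obs})/(1 + n_permutations)`, so the floor
at 999 permutations is 0.001 (random permutation sampling can redraw an
F-tied relabeling, so the floor is attainable but not guaranteed).
PERMDISP follows the spatial-median formulation (scikit-bio,
`test="median"`). Per-feature cluster contrasts are two-sided Wilcoxon
rank-sum tests with Benjamini–Hochberg adjustment across features;
a feature constant across both clusters gets p = 1.

## Paired (before/after) analysis

Chao1 is implemented from its closed forms — classic
`S_obs + F1²/(2·F2)` and bias-corrected `S_obs + F1(F1−1)/(2(F2+1))`,
the latter used on request or whenever F2 = 0 — and cross-checked
against scikit-bio. Chao1 requires counts; relative tables can be
rescaled by an explicit depth, with a logged caveat about approximate
rare-taxon counts. Paired deltas are tested two-sided with Wilcoxon
signed-rank (zero deltas excluded per the standard convention; an
all-tie comparison reports p = 1); a paired t-test is selectable — the
published p-values name no test, and signed-rank matches the
non-parametric usage elsewhere in that analysis. Bray–Curtis,
`Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`, feeds classical PCoA (axes restricted to positive
eigenvalues, negative eigenvalues reported) and the PERMANOVA/PERMDISP
pair on batch labels; treating the 2×97 samples as independent in the
permutation ignores pairing, which mirrors the published usage and is
noted where it applies.

## Nutrigenetic rule engine

Panel variants (up to 300, in 7 fixed categories and up to 39
subcategories) are read from YAML; genotypes from VCF via cyvcf2,
matched by rsID then by position. Dosage is the risk-allele count in a
called genotype; uncalled genotypes are missing, and a record whose
alleles cannot represent the configured risk allele is reported as a
mismatch and left missing — never silently strand-flipped. The
subcategory score is Σ(weight·dosage)/Σ(2·weight) over informative
variants; the label comes from strictly increasing thresholds over one
of the two label sets (risk-graded or valence — which set applies is
per-subcategory configuration, since the nine labels are listed as one
pool). A subcategory whose missing-call fraction exceeds
`max_missing_fraction` (default 0.34) is non-informative. The
production label rules are not published; this additive engine with a
demonstration rule file is the package's own design, and every label
records the rule version that produced it. Cohort allele frequencies
are compared to a reference population by per-variant two-sided Fisher
exact tests on 2×2 allele-count tables (no test is named in the source;
Fisher is the declared choice) with BH adjustment, significant at
adjusted p < 0.05.

## Biomarkers, adherence, reports

Biomarkers are optimal inside the reference range, borderline within a
margin of 0.1× the range width outside it, critical beyond — the
borderline margin has no published numeric definition, so it is a
configurable fraction surfaced in every report. The shipped analyte
ranges are conventional textbook values, marked non-authoritative.
Adherence aggregation sums the three bands at or above 25% (the four
bands must total 100 ± 0.5). Reports render deterministically to
Markdown or JSON; every non-neutral call resolves to exactly one
recommendation text (explicit entry, else the per-label default
template) and an unresolvable key is an error. PDF typography is out of
scope; structured Markdown/JSON is the output.

## Synthetic data: what it emulates, and what it does not

The generators stand in for undeposited study data; their defaults are
the study conditions where stated and realistic choices where not.

* **Reference cohort** (default n = 194, 120 genera, depths uniform in
  30–50k): per-genus log-normal intensities (genus locations
  N(0, 1.5²), per-sample noise SD 0.6) normalized to the simplex, then
  a multinomial read draw — heavy-tailed compositions like real genus
  tables. A `uniform` (flat Dirichlet) law is available for null
  experiments.
* **Percentile planting** rescales a feature's member genera
  multiplicatively in a template sample (the reference sample nearest
  the feature median) and renormalizes, which lands the feature value
  exactly on the requested empirical quantile. Renormalization leaks
  into other features (shrinking the rest of the simplex); this is
  accepted and visible in the worked example. Unreachable percentiles
  (ties at the extremes) warn and return the nearest achievable value.
* **Paired design** (default 97 pairs, 66% increasing, 20 species
  added, pool 300 genera): core genera receive a uniform mixture floor
  (0.25) so that at the simulated depths every occupied genus is always
  detected — unplanted pairs therefore tie exactly on richness, and the
  share of pairs with increased Chao1 equals the planted fraction.
  Both collections of a pair perturb the same base composition with
  independent per-genus log-normal noise (SD 0.6), so Shannon deltas
  are exchangeable between collections: the Shannon paired test is a
  true null (its rejections occur at the nominal rate, which is why the
  acceptance check evaluates the rejection rate over 10 replicate
  designs rather than a single draw). Planted pairs add novel genera
  as singleton/doubleton reads, raising Chao1 by at least the planted
  count while moving Shannon negligibly. What this does *not* emulate:
  real longitudinal compositional drift, depth confounding between
  batches, or taxa dropping below detection — so passing tests show the
  estimator and test machinery behave correctly under the planted
  ground truth, not that a real one-month intervention produces these
  effect sizes.
* **Genotypes** are Binomial(2, f) per sample and variant — exact
  Hardy–Weinberg equilibrium, written as minimal VCF v4.2 with the risk
  allele as ALT. The frequency-comparison experiments use 214 reference
  chromosomes (the 1000 Genomes Iberian sample) and variant frequencies
  uniform in [0.1, 0.9]; linkage disequilibrium, genotyping error, and
  array-specific missingness are not modeled.

## Problem sizes and numerical conventions

The test and acceptance experiments run at the study's stated sizes
where feasible (194-sample references, 97 pairs, 357×300 genotype
cohorts) and use 199–999 permutations and 10–200 replicates for the
calibration experiments — sizes at which every stochastic check is
stable across seeds. All randomness flows through explicitly seeded
`numpy.random.Generator` instances; identical specs and seeds give
byte-identical outputs. Known limitations: cluster memberships and
distance-based statistics of the original cohorts are not reproducible
(the data are not deposited), multimodal references are not modeled
(no mixture fitting), and the genus rosters and rule thresholds shipped
as defaults are demonstrations, not clinical content.
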