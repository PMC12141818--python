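# Methods

This note documents the models and procedures implemented in
`mitocoherence`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Indices

All indices are computed per sample from TPM-like abundances and averaged
when a subject contributes several samples of the same tissue (mirroring
the replicate-averaging rule used for proteomic feature tables).

- **mtDNA%**: mtDNA-encoded transcripts as a percentage of all transcripts.
- **mito-nDNA% and named-set percentages**: mtDNA transcripts are removed
  first, and the set total is expressed as a percentage of the remaining
  (nuclear) transcriptome.  This two-step normalization matters: mtDNA
  transcripts can exceed half of a sample's transcriptome in brain and
  heart, so percentages taken on the whole transcriptome would couple every
  nuclear index to mitochondrial content mechanically.  The ISR index is
  the *summed* percentage of the four genes (ATF4, ATF5, DDIT3, GDF15)
  rather than a mean of per-gene percentages; for small sets on a common
  denominator the two differ only by a constant factor, and the summed form
  is the direct set-share reading.
- **Proliferation score**: arithmetic mean of KI67, TOP2A and RRM2 in raw
  TPM-like units, without log transform.  Tissue-level proliferation is the
  mean over the tissue's retained samples.

Percentages are scale-free; the proliferation score scales linearly with
global rescaling of a profile.

## Eligibility rules

Samples are filtered at RIN ≥ 5.5 (inclusive) with cell lines removed;
samples with missing RIN are retained only when the cutoff is 0, failing
safe toward exclusion.  Tissue pairs need ≥ 10 shared subjects.  A tissue is
retained only if it forms eligible pairs with strictly more than 50% of the
other retained tissues; because removing one tissue can disqualify another,
the rule is iterated to a fixed point, which is well defined and
order-independent.  Shared-subject counts are taken after sample filtering.

## Coherence structure

Pairwise coherence is the Spearman rank correlation of a feature across the
subjects observed in both tissues of a pair, with mid-ranks for ties and a
two-sided p-value from the t approximation on n−2 degrees of freedom
(|r| = 1 yields p = 0).  Pairs with fewer than 3 complete subjects or zero
rank variance are skipped and logged.  Multi-feature analyses (e.g. the
five enzymatic features) compute one correlation per pair per feature and
pool them.

Summaries report, per pair class (brain–brain, body–body, brain–body) and
overall: the median r, counts, percent positive/negative, percent
significantly positive/negative at uncorrected two-sided p < 0.05, and the
percent not statistically different from zero (p ≥ α).  No multiple-testing
correction is applied in these descriptive breakdowns; that is a deliberate
mirror of the descriptive, uncorrected convention for this analysis and is
flagged here as a limitation.  Histograms use fixed bins of width 0.1 on
[−1, 1] for reproducibility.  The coherence network draws an edge wherever
r ≥ 0.2 (mean over features when several contribute to a pair); node degree
is the incident-edge count.  Layout is considered presentation, not
analysis, and is out of scope.

## Regulators and proliferation

Within-tissue association profiles are per-tissue Spearman correlations of
a regulator percentage with a mitochondrial index, over tissues with at
least `min_n = 10` complete subjects (the same threshold as the pair rule).
Profiles of different regulators are compared by Spearman correlation
across common tissues.  The proliferation analysis computes per-tissue
coupling r(mtDNA%, mito-nDNA%) and correlates it — across tissues, one
point per tissue — with the tissue-level proliferation score, again by
Spearman.  The hypothesis encoded here: dividing tissues dilute their
mitochondria every cell cycle and must transcribe both genomes in a
coordinated way, so proliferative tissues should show tight positive
coupling, while post-mitotic tissues can hold abundant mtDNA transcripts
with comparatively low nuclear biogenesis expression.

## Clustering

Subjects complete on a selected tissue panel are described by log₂ ratios
of an index for every unordered tissue pair, z-scored per feature.  Log
ratios make the features symmetric and scale-free; orientation flips only
negate a feature, and after standardization k-means results are
orientation-invariant.  k-means uses k-means++ seeding, Lloyd iterations
and the best of `n_restarts = 10` starts, deterministic given a seed; k
defaults to 3, and a WCSS/silhouette report across candidate k is emitted
for transparency since no principled k is forced by the data model.
Cluster structure is characterized by PCA variance fractions (eigenvalues
of the feature covariance), a two-way fixed-effects ANOVA of the index on
cluster, tissue and their interaction with type II sums of squares (the
design is near-balanced and type II is invariant to factor order), Hedges'
g per cluster pair within tissue using the small-sample correction
J = 1 − 3/(4·df − 1), and clinical enrichment: percent positive per cluster
among non-missing subjects, z-scored across the k cluster values with the
population (n-denominator) SD.

## The synthetic cohort generator

The generator exists so that every stage has a recoverable target.  Per
subject, a standard-normal latent trait z (systemic investment propensity)
and an archetype label; per subject–tissue, the mtDNA fraction on the
log-odds scale:

    logit(f_mt) = logit(mu_t) + lambda_t * z + shift(archetype, t) + eps,
    eps ~ N(0, sigma_t^2).

Modelling on the log-odds scale keeps fractions in (0, 1) at any noise
level.  The nuclear-mito fraction is drawn around nu_t with the same noise
scale through a Gaussian copula of Pearson strength p_t (the proliferation
parameter) with the mtDNA latent; this is the simplest mechanism that makes
the within-tissue mtDNA↔nuclear coupling exactly p_t and hence monotone in
proliferation.  A consequence worth knowing: the nuclear fraction inherits
the subject trait only through that copula, so its inter-tissue coherence
is attenuated by p_s·p_t relative to the mtDNA fraction — the coherence
dial λ acts directly on mtDNA%, and analyses demonstrating planted
coherence use that index.  Archetype shifts are applied to both fractions
so that planted subgroups are recoverable from either index.

Regulator and ISR genes receive a latent with within-tissue correlation
beta_t to the nuclear-mito latent; their raw abundances are multiplied by
exp(0.5·latent)/(1 − f_nuc).  The second factor cancels the compositional
shrinkage of the non-mito share of the nuclear transcriptome, so beta_t is
the planted association itself rather than beta_t plus a closure artifact
(with it, beta = 0 tissues are genuinely null).  Proliferation genes scale
with p_t.  Gene-level abundances are log-normal within each class
(between-gene SD 1, within-sample SD 0.2) and rescaled exactly so class
sums hit the drawn fractions and each sample totals 1e6 — index recovery is
therefore exact to machine precision, and gene-level dispersion affects no
class-sum index.  RIN is normal (mean 7.5, SD 1.2, clipped to [1, 10]);
tissues are dropped per subject with a per-tissue missingness probability;
clinical binaries are Bernoulli with archetype-dependent probabilities.

The analytic oracle: between tissues s and t the latent Pearson correlation
is lambda_s·lambda_t / sqrt((lambda_s²+sigma_s²)(lambda_t²+sigma_t²)), and
because the logistic transform is monotone, the Spearman expectation is the
bivariate-normal form (6/π)·arcsin(rho/2) exactly.

Defaults are chosen to resemble the human multi-tissue setting: a 12-tissue
panel (5 brain regions with mtDNA fractions near 0.55 and trait loading
0.5; heart, muscle, adrenal, colon, adipose, liver, whole blood with
fractions 0.05–0.5, low loadings, and proliferation parameters spanning
0.05–0.8), and gene counts of 37 mtDNA, 1133 nuclear-mito and 18,000 other
genes.  The enzymatic-cohort generator mirrors a 27-animal, 22-tissue panel
(17 brain regions sharing loading 0.5, 5 idiosyncratic body tissues) with
five log-normal activity features sharing the subject trait.

**What the generator does not emulate**: read-level artifacts, postmortem
or batch effects, realistic gene–gene co-expression beyond class structure,
non-Gaussian trait distributions, or tissue-specific RIN biases.  Passing
recovery tests therefore shows the *statistical machinery* is correct and
calibrated — not that real tissues satisfy the latent-trait model.

## Planted-archetype conditions

The phenotyping demonstration plants three archetypes (muscle-high,
brain-high, balanced) over a four-tissue panel at equal mixing proportions,
with investment shifts of 1.5 units on the log₂ inter-tissue ratio scale
against a within-cluster ratio-feature noise SD of 0.5 units (logit shift
1.18, tissue noise sigma 0.28) — i.e. discriminating features separate
adjacent centroids by three within-cluster SDs.  This is the joint reading
of "1.5-unit separation" and "0.5-unit within-cluster noise" as one
condition; because ratio features of a shared panel are correlated (they
share tissue noise), the effective Mahalanobis separation is smaller than a
naive per-feature count suggests, and recovery at these settings is
approximately 90–95% label agreement at n = 120.  Clinical variables use
archetype probabilities (0.8, 0.2, 0.2), (0.1, 0.7, 0.1) and a flat
(0.4, 0.4, 0.4) control.

## Numerical choices and problem sizes

- Spearman r/p via `scipy.stats.spearmanr`; k-means via scikit-learn
  (`algorithm="lloyd"`); ANOVA via statsmodels `anova_lm(typ=2)`; network
  via networkx; PCA fractions from `numpy.linalg.eigvalsh` on the feature
  covariance, clipped at zero and normalized.
- Degenerate inputs raise typed errors: zero totals, non-positive fold-range
  means, k outside [2, n], sets containing mtDNA genes; undefined
  correlations (n < 3, zero rank variance) are skip-and-log signals rather
  than hard failures inside pair loops.
- Verification runs use reduced gene counts (tens to hundreds of "other"
  genes) because every tested quantity is a class-sum index that is
  independent of gene count; cohort sizes follow the conditions stated for
  each check (n = 2,000 subjects for coherence recovery, 500 for regulator
  signs, 200 for proliferation, 120 for clustering, 1,000 pairs at n = 50
  for null calibration).  Coherence-recovery checks average five replicate
  two-tissue cohorts because a single Spearman estimate at n = 2,000 has a
  Monte Carlo SE of ~0.02, comparable to the ±0.03 agreement band; the
  mean of five replicates estimates the expectation with SE ~0.01 while
  leaving each cohort at the stated size.

## Known limitations

- The external mouse-cohort validation requires a measurement table
  distributed as journal supplementary material; it is not redistributed
  here, and the corresponding tests report the data as unavailable unless
  the table is placed under `data/`.
- Whether ratio features should be standardized before k-means is a
  genuinely open choice; we standardize (scale-free, orientation-invariant)
  and note that unstandardized clustering can weight tissue pairs with
  larger ratio variance more heavily.
- Summaries use uncorrected p-values by design; any inferential use of the
  significance breakdowns should apply its own error control.
- Pearson correlation is available as a flagged alternative in the library
  (`pairwise_structure(..., method="pearson")`; `expected_pair_correlation`
  returns both expectations) but headline outputs are Spearman-only.
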